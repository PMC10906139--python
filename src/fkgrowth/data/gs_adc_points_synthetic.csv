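gs,adc_ratio
2.0,0.98
6.0,0.70
7.0,0.55
8.0,0.45
9.0,0.37
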
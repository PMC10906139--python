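# fkgrowth

Imaging-informed biomechanistic forecasting of prostate cancer growth
during active surveillance (AS).

Most newly diagnosed prostate cancers are low- or intermediate-risk and are
managed by periodic monitoring (mpMRI, PSA, biopsy) rather than immediate
treatment. Monitoring schedules are population-based; they cannot
anticipate when an individual tumor will progress. `fkgrowth` implements a
patient-specific alternative: longitudinal apparent-diffusion-coefficient
(ADC) maps are converted into normalized tumor-cell-density maps, a
reaction–diffusion growth model is calibrated to each patient's scans, and
the personalized simulation yields spatiotemporal forecasts, agreement
metrics, and model-based biomarkers feeding a logistic risk classifier.
A synthetic-cohort generator makes the entire pipeline runnable without
patient data. The intended audience is researchers in mathematical
oncology and image-based tumor forecasting.

## Model

ADC decreases as tumor cellularity increases. Each ADC map is mapped to a
normalized tumor cell density N̄ ∈ [0, 1] (cell density over the tissue
carrying capacity θ):

    N̄(x, t) = (ADC_h − ADC(x, t)) / (ADC_h − ADC_min),

where ADC_h is the mean ADC of healthy prostate tissue and
ADC_min = 0.25 · ADC_h is the minimum intratumoral ADC (the lower asymptote
of a hyperbolic-tangent fit of ADC ratio against Gleason score, also
provided in `fkgrowth.imaging.GsAdcModel`). Values are truncated to [0, 1].
Tumor cores are segmented at ADC < 70 % ADC_h (equivalently N̄ > 0.4)
and expanded by a metric margin so the segmentation border reaches
near-healthy ADC.

Growth follows the Fisher–Kolmogorov equation on the prostate domain Ω
with zero-flux boundary conditions (organ-confined disease):

    ∂N̄/∂t = ∇·(D ∇N̄) + ρ N̄ (1 − N̄),   ∇N̄·n = 0 on ∂Ω,

with tumor cell diffusivity D (mm²/day) and net proliferation rate ρ
(1/day). The patient-specific pair (D, ρ) minimizes the relative-L²
misfit between simulated and measured density maps at the follow-up scan
times (the first scan is the initial condition), solved by
bound-constrained Gauss–Newton in log-parameter space over
D ∈ [10⁻⁶, 10], ρ ∈ [10⁻⁶, 1], starting from D = 5·10⁻³, ρ = 2·10⁻³.

Model–data agreement uses the tumor volume V_T and total cell volume V_N
on the region Ω_T = {N̄ ≥ 0.15} (cohort Pearson and Lin concordance
correlations), plus local DSC, RMSE, PCC and CCC. Six candidate
biomarkers — V_P, V_T, V_N, mean density V_N/V_T, total tumor index
N_T = V_N/V_P, and mean proliferation activity
A_p = ⟨ρ N̄ (1 − N̄)⟩_{Ω_T} — are compared between Gleason 3+3 and ≥ 3+4
subgroups (exact Wilcoxon tests) and feed uni-/bivariate logistic
classifiers with trapezoidal-rule ROC analysis.

## Worked example

Generate a noiseless synthetic cohort, calibrate one patient, and run the
fitting–forecasting scenario (fit on scans 1–2, validate on scan 3):

```bash
fkgrowth synth-cohort --n-patients 3 --grid-size 48 --spacing 1.5 \
    --noise-sigma 0 --dt 1 --seed 42 --out demo_cohort
fkgrowth calibrate --cohort demo_cohort --patient P00 --out calib.json
```

```
Fisher-Kolmogorov growth model — Gauss-Newton calibration
============================================================
scans fitted:        2 (of 3; scan 1 = initial condition)
prostate volume:     56.30 cc
D   (mm^2/day):      1.4649e-03   (se log D:   0.000251)
rho (1/day):         3.9776e-03   (se log rho: 7.17e-05)
relative-L2 misfit:  1.320889e-04
iterations:          5   converged: True
```

This patient was generated with D = 1.4697·10⁻³ mm²/day and
ρ = 3.9765·10⁻³ 1/day: the fit recovers them to 0.3 % and 0.03 %. A
misfit of ~10⁻⁴ means the simulated density maps explain all but ~1 % of
the measured maps' relative L² norm.

```bash
fkgrowth run-scenario --scenario fitting_forecasting \
    --cohort demo_cohort --out demo_out
```

prints the cohort summary, e.g. for the held-out third scan

```
"scan_3": {
  "v_n": {"ccc": 0.9998, "pcc": 1.0000},
  "v_t": {"ccc": 0.9998, "pcc": 1.0000}
}
```

i.e. the forecast tumor volumes concur with the (model-generated, hence
self-consistent) measurements across the cohort. Per-patient agreement
rows land in `demo_out/agreement.csv`, biomarker panels in
`biomarkers.csv`, the classifier and risk trajectories in
`classifier.json`/`risk.csv`.

The same stages are available as a library, statsmodels-style:

```python
from fkgrowth import TumorGrowthModel
model = TumorGrowthModel(series, spacing=1.5, dt=1.0)  # series: ScanSeries
result = model.fit()
print(result.summary())
forecast = result.simulate([t_next])                    # density forecast
```

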
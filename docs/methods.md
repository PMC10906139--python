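# Methods

## Imaging model

The state variable is the normalized tumor cell density
N̄(x, t) ∈ [0, 1], the ratio of tumor cell density to the tissue carrying
capacity θ. ADC and N̄ are related linearly,
N̄ = (ADC_h − ADC) / (ADC_h − ADC_min), truncated so ADC ≥ ADC_h maps to 0
and ADC ≤ ADC_min maps to 1. Two constants parameterize the conversion:

| parameter    | meaning                                   | default |
|--------------|-------------------------------------------|---------|
| `adc_h`      | mean ADC of healthy prostate tissue       | estimated from a healthy ROI (synthetic data: 1.0, ratio units) |
| `ratio_min`  | ADC_min/ADC_h, lower asymptote of the GS–ADC tanh model | 0.25 |
| `core_ratio` | tumor-core threshold as a fraction of ADC_h | 0.70 |

The 0.70 threshold corresponds to N̄ = 0.4 under the conversion. A
hyperbolic tangent f(GS) = 0.625 − 0.375·tanh(slope·(GS − midpoint)) maps
the continuous Gleason scale (0–2 = healthy/pretumoral) to the ADC ratio;
its asymptotes are pinned at 1.0 and `ratio_min` and only slope and
midpoint are fitted by least squares. The packaged
`data/gs_adc_points_synthetic.csv` is a synthetic stand-in for
literature-derived GS-specific mean ADC ratios (the sources tabulate means
per GS group; the file reproduces the qualitative shape: monotone decrease
with a high-GS plateau).

Tumor segmentation is hierarchical: a gross mask (upstream input), the
core (ADC strictly below `core_ratio`·ADC_h inside the gross mask,
following the stated "less than"), and the final mask = core dilated by a
Euclidean ball and clipped to the gross mask. The dilation ball uses
voxel-center distance, which is reproducible and matches the 3×3×3 to
5×5×5-voxel kernels of interactive margin tools at typical spacings. The
margin is either a fixed length or `"auto"`: grow from 2 mm in 1-mm steps
until every gross-mask voxel left outside the final mask has converted
density below 0.02 (ADC within 1.5 % of healthy), capped at 12 mm.
Compact tumors settle at 2–4 mm; diffusion-dominated tumors with wide
low-density halos receive larger margins. The design intent is that the
segmentation border sits at near-healthy ADC, so the measured density map
loses no meaningful signal; with a fixed small margin, diffuse synthetic
tumors had their halos clipped, which biased calibration.

Density conversion is applied wherever the map is evaluated (inside the
final tumor mask; zero elsewhere). Scalar maps are resampled trilinearly,
masks nearest-neighbor. Registration is assumed done upstream: all of a
patient's volumes share one grid.

## Growth model and solver

∂N̄/∂t = ∇·(D∇N̄) + ρN̄(1−N̄) on the prostate mask Ω with ∇N̄·n = 0 on
∂Ω; the initial condition is the measured density map of the first scan.

* Space: 7-point finite-volume Laplacian on the masked voxel grid; fluxes
  across faces leaving Ω are omitted, which enforces zero flux exactly
  (discrete row sums vanish, so pure diffusion conserves total cell
  volume to rounding).
* Time: backward Euler, Δt = 1 day by default, Newton–Raphson per step to
  a relative residual of 1e-8 (max 25 iterations), with an explicit-Euler
  predictor.
* Linear solves, by regime:
  - D = 0: the per-voxel backward-Euler logistic update is a scalar
    quadratic solved in closed form (exact).
  - ρ = 0: one exact sparse LU solve of the constant operator
    (I − ΔtD·L); this path keeps total mass conserved to ~1e-13 over
    thousands of steps.
  - physiological regime (‖ΔtD·L + Δtρ·diag‖ ≤ 0.5, which holds for the
    calibrated parameter ranges at millimetre spacings): Neumann-series
    iteration — a few sparse matvecs per Newton step, no factorization.
    The inexact-Newton forcing term never requests more accuracy than the
    outer Newton iteration can absorb.
  - otherwise (large D or ρ probed by the calibration box): defect
    correction preconditioned by the diffusion-only LU, or an exact
    factorization of the full Jacobian when the reaction perturbation is
    too strong to contract.
* States are clipped to [0, 1] only within a 1e-6 solver tolerance;
  larger excursions raise an error. Very aggressive parameter/step
  combinations (e.g. ρΔt ≳ 1 at the corner of the admissible box) can
  make the discrete scheme lose positivity; such points are reported as
  solver errors and treated as infeasible (infinite misfit) by the
  calibration and the grid-search oracle.

Accuracy against closed forms (asserted in the tests): D = 0 logistic
growth matches the analytic solution to ≤ 1e-3 over 1000 days at
Δt = 1 day; ρ = 0 conserves mass to 1e-10 relative over 1000 steps; the
1-D traveling front speed matches 2√(Dρ) to within 5 % when measured by
regressing front position over a late time window (the front approaches
its asymptotic speed like ~1/t, so early windows underestimate it).

## Calibration

J(D, ρ) = Σ_{i≥2} ∫_Ω (N̄_mod(x, tᵢ) − N̄_meas(x, tᵢ))² dx /
∫_Ω N̄_meas(x, tᵢ)² dx, the relative-L² misfit over the whole prostate at
the fitted scan times; scan 1 is the initial condition and is never
fitted. The normalizer is per scan; voxel volume cancels.

Gauss–Newton runs in (log D, log ρ) to respect the four-decade admissible
box [1e-6, 10] × [1e-6, 1] (projection onto the box after each step):
forward-difference Jacobian (step 1e-3 in log-parameters, differenced
backwards at a bound or on solver failure), normal equations with a 1e-12
ridge, step-halving line search (≤ 10 halvings; infeasible trial points
count as no descent), convergence when the relative objective decrease
falls below 1e-6, at most 50 iterations; non-convergence is flagged, not
raised. Initial guess D = 5e-3 mm²/day, ρ = 2e-3 1/day. Approximate
standard errors of the log-parameters come from the Gauss–Newton
covariance σ²(JᵀJ)⁻¹. A 20×20 log-spaced grid search over the same box
serves as a brute-force oracle in the tests.

## Metrics and biomarkers

Ω_T = {N̄ ≥ 0.15}. V_T = |Ω_T| and V_N = ∫_{Ω_T} N̄ dx, reported in cc.
Local RMSE/PCC/CCC are evaluated on the union of measured and simulated
Ω_T at the evaluation time — the support is not stated by the protocol;
the union avoids inflating agreement with shared empty background while
covering both footprints. DSC of two empty regions is defined as 1
(perfect agreement of absence). CCC uses n−1 denominators consistently;
Lin's inequality |CCC| ≤ |PCC| is property-tested.

Biomarkers at a time point: V_P (prostate volume), V_T, V_N,
mean density V_N/V_T, total tumor index N_T = V_N/V_P, and mean
proliferation activity A_p = (1/V_T)∫_{Ω_T} ρN̄(1−N̄) dx (1/day), which
is maximal where N̄ = 0.5 and vanishes at 0 and 1. Empty Ω_T zeroes all
tumor markers.

Wilcoxon rank-sum and signed-rank tests use exact enumeration (midranks
for ties) for combined sizes ≤ 12 — C(12,6) assignments / 2¹² sign
patterns — and a tie-corrected, continuity-corrected normal approximation
above. Two-sided p is twice the smaller tail, capped at 1, matching
common statistical-toolbox conventions at small n.

Logistic risk classifiers (1 or 2 markers, to avoid overfitting at n = 16
observations) are fitted by IRLS; quasi-separation is detected when the
standardized coefficient norm exceeds 30, in which case coefficients are
capped and flagged rather than diverging. ROC curves sweep the distinct
scores (plus +∞); AUC is trapezoidal; the optimal operating point is the
ROC vertex nearest (0, 1), ties broken toward higher sensitivity. The
classifier is trained and evaluated on the same cohort (no partition), a
deliberate mirror of the small-cohort design and a known limitation.
Risk trajectories apply the fitted classifier to biomarker panels along a
simulated density trajectory; the first crossing of the optimal-point
threshold is reported as the predicted progression time.

## Synthetic cohorts

The generator emulates the study's data structure so every stage runs
without patient data: ellipsoidal prostates (fixed 1.15 : 1 : 0.85 axis
ratios, volume solved by bisection to within 2 % of the request, range
18.5–67.3 cc), a focal tumor seeded as a compactly supported smooth bump
(radius 4–7 mm, peak density 0.7–0.9; the exact-zero tail means the first
scan's measured map captures the whole tumor), true (D, ρ) drawn
log-uniformly from 5.35e-4–5.35e-3 mm²/day × 7.8e-4–5.2e-3 1/day (the
envelope of the calibrated patient ranges), three scans with interscan
gaps uniform in 0.5–2.6 years, ADC-ratio maps obtained by inverting the
density conversion with ADC_h ≡ 1 (the pipeline only ever uses ratios)
plus optional additive Gaussian noise (default σ = 0.02, truncated to
(0, 1.2]), gross masks dilated 3 mm from the density > 0.02 support, and
Gleason-like labels: a scan is higher-risk (3+4) when the true A_p
exceeds 4e-4 1/day, a cutoff near the cohort median that makes the label
learnable from the markers. Everything is drawn from one seeded
generator, so cohorts are bit-reproducible.

What the generator does not emulate: prostate zonal anatomy and the
urethra, registration error, Rician noise, scanner/protocol variation,
biological model mismatch (real tumors do not follow Fisher–Kolmogorov
exactly), and histopathology sampling error in Gleason labels. Passing
self-consistency tests therefore demonstrates the correctness of the
inverse machinery — not clinical-scale forecast accuracy, whose headline
cohort values depend on patient MRI that is not redistributable.

## Scenario drivers and problem sizes

`global_calibration` fits all scans and evaluates at the same scans
(representation); `fitting_forecasting` fits scans 1–2 and validates the
forecast at scan 3 (prediction). Outputs (agreement rows, biomarker
panels, calibration records, classifier, risk trajectories) are written
with fixed float formatting, so identical inputs reproduce identical
bytes.

The packaged synthetic study runs 10 patients on 48³ grids at 1.5 mm
spacing with Δt = 1 day; generator-mechanics tests use 32³ grids at
2–2.5 mm with shorter gaps, and the grid-search oracle runs on a compact
two-scan instance (10³ grid, Δt = 4 days) because the 20×20 brute force
costs ~400 forward solves. Noiseless cohorts are used wherever
self-consistency is asserted.

## Known limitations

* The Fisher–Kolmogorov front homogenizes intratumoral heterogeneity, so
  late-horizon local agreement degrades even in principle; the model
  carries no mechanical coupling, vascularity, or spatially varying
  carrying capacity.
* Backward Euler is first-order in time; Δt = 1 day is well within the
  accuracy needed for month-scale dynamics but the traveling-front speed
  carries an O(Δt, h) bias (kept under 5 % at the tested resolutions).
* The classifier stage has no train/test split and small-n separation is
  common; capped coefficients keep probabilities defined but AUC values
  on separated data are optimistic.
* The adaptive segmentation margin assumes the gross mask generously
  covers the tumor halo; with tight gross contours the density map is
  truncated at the gross boundary regardless of margin.
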
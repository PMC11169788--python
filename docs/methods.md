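# Methods

`cmrquant` implements the quantitative chain of a contrast-enhanced cardiac
MRI study of amyloid cardiomyopathy: first-pass perfusion signal → ΔR1 →
model-independent deconvolution → myocardial blood flow (MBF); multi-timepoint
T1 → gadolinium partition coefficient λ_Gd → extracellular volume fraction
(ECV); surrogate myocardial work efficiency (MWE) from routine hemodynamics;
and a cohort inference layer. Because patient data of this kind are not
publicly depositable, every stage is driven and verified by synthetic-data
generators with known ground truth.

## Signal model and ΔR1 conversion

The saturation-recovery gradient-echo readout is modeled as the ideal
single-parameter form

    S(R1) = S0 · (1 − exp(−TS · R1)),

with all flip-angle/readout corrections collapsed into one effective
saturation delay TS (default 0.1 s, config). This is a deliberate stand-in
for the full sequence-specific conversion: the monotone signal↔R1 mapping is
the property the downstream chain depends on, and TS is exposed so a
calibrated effective delay can be supplied. S0 is calibrated per region
(arterial input and each of the 16 AHA segments separately) from the mean of
the first `n_baseline` pre-contrast frames (default 5) together with the
region's native T1 (tissue default 1232 ms, blood 1900 ms); automatic
bolus-arrival detection is deliberately not used for calibration. ΔR1 is the
per-frame inverted R1 minus the native rate; a frame at or above S0 raises a
saturation-clipping error naming the frame. Units are centralized: R1 in 1/s,
native T1 inputs in ms, TS in s.

## Deconvolution and MBF

Tissue ΔR1 is the convolution of the arterial input ΔR1 with the tissue
impulse response h(t); by the central volume principle the amplitude of h is
tissue blood flow. h is represented on a cubic B-spline basis (12 knot sites,
60% packed into the first 10 s where the amplitude lives) and estimated by
penalized least squares with a second-order difference penalty on the spline
coefficients; the regularization weight λ is selected by GCV over a log grid
10⁻³…10³ (an L-curve corner criterion is available). The convolution matrix
uses trapezoidal quadrature on the frame grid; tissue and AIF must share the
grid exactly (a resampling utility is provided, resampling is the caller's
job). An integer bolus-arrival delay (0…`max_delay_frames`) can be estimated
by grid search on the regularized fit residual and applied to the AIF.

After the linear solve, the solution is refined at the selected λ under a
physiological shape constraint (default `shape="monotone"`): h is required to
be non-negative and non-increasing, which is true of every residue function
(the microvascular transit leaves a monotone washout). The constraint is
implemented by re-parameterizing the spline coefficients as cumulative sums
of non-negative increments and solving the penalized problem with NNLS; by
the B-spline derivative property non-increasing coefficients give a
non-increasing curve. This refinement exists because sampled data carry no
information about the AIF between frames: with curves sampled at ~0.8 s the
unconstrained spline estimate oscillates near t = 0 and overstates the
amplitude by 10–16%, while the constrained estimate is accurate to ~2% on
noiseless data. `shape="nonneg"` and `shape="none"` remain available; the
unconstrained solve is the right tool when the target kernel is not monotone
(e.g. a pure scale-plus-delay spike).

Flow is read off as

    MBF [ml/min/g] = 60 · max{ h(t) : t ≤ 20 s } / ρ,   ρ = 1.05 g/ml,

with the window configurable. Blood and tissue relaxivities are assumed equal
so they cancel in ΔR1 space. Global MBF is the unweighted mean of the 16
segmental values; segments that fail conversion are collected as warnings and
excluded from the mean.

## Partition coefficient and ECV

For each segment, λ_Gd is the unweighted OLS slope of tissue R1 on blood R1
across the pre-contrast, 10-min and 20-min timepoints; using three points
rather than the pre/post pair lowers the slope variance (verified as a
Monte-Carlo property; the variance ratio is ~0.97 at the default washout
schedule, the gain depends on the blood-R1 spread). ECV = (1 − Hct)·λ_Gd with
a per-subject hematocrit; ECV is stored as a fraction and rendered as percent.
The global ECV is the unweighted mean over all valid segments, with a logged
count when segments are missing.

## Hemodynamics and surrogate MWE

MAP uses the one-third pulse-pressure rule DBP + (SBP − DBP)/3 (the source
analyses use MAP without printing a formula). Cardiac output is CMR stroke
volume × heart rate; external work EW = CO·MAP; surrogate MWE = EW / LV mass
in mmHg·L·min⁻¹·g⁻¹ ("mmHg L/g/min" elsewhere is the same unit). The
rate–pressure product index is SBP·HR/10⁴ and workload-normalized MBF is the
per-subject ratio MBF/RPP. BSA is an input column; the Du Bois formula is a
logged fallback when only height/weight are present.

## Cohort inference

* **Tertiles**: cuts at the 1/3 and 2/3 type-7 sample quantiles,
  left-open right-closed intervals; missing values excluded with a count.
* **Trend tests**: OLS of the outcome on the tertile score 1–3, two-sided
  t-test on the slope. A constant outcome short-circuits to p = 1 rather
  than testing a zero slope against a zero standard error.
* **Correlations**: pairwise-complete Pearson r with t-distributed p,
  cells with < 3 pairs marked missing.
* **Stepwise AIC**: bidirectional search minimizing AIC, forced terms
  (age, sex in the study design) never dropped.
* **Mediation**: linear X→M→Y decomposition with a direct path; a from OLS
  M~X, b and c′ from OLS Y~X+M; indirect = a·b and total = c′ + a·b hold
  exactly by construction. Percentile bootstrap (nonparametric case
  resampling, 2000 replicates default, mandatory seed) gives CIs and SEs;
  standardized coefficients are computed on z-scored variables and effects
  are also rescaled per 5-unit ECV change. The saturated model has zero
  degrees of freedom, hence RMSEA = 0 by construction; a reduced model
  dropping the direct path carries one df whose misfit χ² is the
  likelihood-ratio statistic n·ln(RSS_r/RSS_f), from which RMSEA follows.
  Note that "RMSEA < 0.05" for a one-df model is only a high-probability
  event at large n (the central χ²₁ exceeds the threshold with probability
  ~0.27 at n = 92 but ~0.01 at n = 2000); the property tests use large n.
* **Mixed models**: REML random-intercept models via statsmodels MixedLM;
  the segmental model has segmental ECV and RPP as fixed effects with a
  subject random intercept and an optional nested slice intercept (the
  exact three-way stratification of the source analysis is ambiguous;
  nested subject/slice is the default, wall class optional). Boundary
  cases (between-group variance ≈ 0) can defeat gradient-based
  optimizers, so the fit falls back through bfgs → powell → nm until one
  converges; at the boundary the fixed effects coincide with OLS, and on
  balanced one-way designs the REML components match the ANOVA
  method-of-moments forms.
* **Base-to-apex**: slice-level LMM with basal reference plus paired
  t-tests between slice levels, Holm-adjusted. Zero-variance paired
  differences (identical slices) return p = 1.
* **Holm**, **logistic LGE~ECV** (IRLS via statsmodels Logit, separation
  detected and reported rather than silently fit), and **exact two-sample
  t power** from the noncentral t distribution complete the layer.

## Synthetic-data generators

All generators are pure functions of (parameters, seed).

**Perfusion**: the arterial input is a gamma-variate in ΔR1 units
(peak 4 s⁻¹ at t₀ + αβ; defaults t₀ = 4 s, α = 2.5, β = 1.5 s, optional
recirculation bump), matching a compact first-pass bolus at rest. Tissue
ΔR1 is the continuous convolution of the AIF with a flow-scaled residue —
exponential exp(−t·F/λ_p) with distribution volume λ_p = 0.5, or Fermi —
computed on a 10× oversampled grid and sampled at the frame grid (60 frames
at 0.8 s, the one-heartbeat cadence of a multi-slice acquisition). Curves
are mapped through the saturation-recovery model with per-region S0 and
degraded with Gaussian noise whose sd is the region's baseline signal
divided by the stated SNR (the MRI image-SNR convention). Gaussian rather
than Rician noise is used; at the SNRs exercised the Rician floor is
negligible. What passing recovery tests shows is that the estimator chain
is correct under this generative model; real data add motion, partial-volume
contamination near the apex, T2* and inflow effects, and AIF saturation,
none of which are modeled.

**T1/ECV**: blood R1 follows a pre/10-min/20-min washout schedule
(0.526, 1.75, 1.30 s⁻¹); tissue R1 sits on a line with the requested λ_Gd,
intercept pinned so the pre-contrast point is the native tissue rate, plus
Gaussian noise.

**Cohort**: ECV (%) ~ N(46, 10²) truncated to (20, 70); rest MBF =
1.2058 − 0.0073·ECV + ε_m (ε_m sd 0.197); MWE = 5.359 − 0.0732·ECV +
1.86·MBF + ε_y (ε_y sd 1.39). These constants — all in
`data/cohort_defaults.yaml`, never in code — are calibrated so the marginals
match the published cohort (MBF 0.87 ± 0.21, MWE 3.61 ± 1.68, tertile means
0.97/0.85/0.81) and the per-5%-ECV effects equal −0.366 (direct) and −0.068
(mediated by MBF, 16% of the total). Hemodynamic columns (pressures, HR,
LV mass, volumes) are drawn at the published marginals and then back-solved
so that CO·MAP/mass reproduces the generated MWE exactly row-wise; draws
giving infeasible values have their residuals redrawn above a small floor
(0.05), and this positivity constraint slightly attenuates the realized
direct path (≈ −0.33 to −0.35 per 5% across seeds) relative to the nominal
coefficient — an inherent property of a linear-Gaussian structural model
with a positive outcome. The segment table adds segmental ECV scatter
(sd 3%), a segment-level ECV effect of −0.003 per 1% with an RPP effect,
and base-to-apex increments (+0.05 mid, +0.10 apical) in the two upper ECV
tertiles. The subject random intercept of the segment model is the
subject's MBF residual ε_m, which is independent of ECV by construction;
using the full subject MBF would correlate the intercept with the regressor
and bias the segment-level fixed effect toward the steeper subject-level
slope. LGE is Bernoulli with logit slope ln(1.55) per 1% ECV centered at
41.5%; NYHA is an ordinal cut of a noisy −MWE latent at the published class
frequencies; a standardized mediation generator produces (x, m, y) triples
with exact unit variances for path-recovery studies.

## Numerical choices and degenerate inputs

Time grids must match to 10⁻⁹ s; a flat AIF (peak below 0.05 s⁻¹) is
rejected as uninformative; an all-zero tissue curve short-circuits to
MBF = 0. Tertile stratification refuses fully tied samples. The logistic
model refuses single-class and completely separated data. Mediation requires
≥ 10 complete cases and non-degenerate variances. The problem sizes used
throughout the test-suite and the acceptance script — 50-seed noise studies,
100-replicate recovery studies, cohorts of n = 92 — were chosen as the
smallest sizes at which the Monte-Carlo error is comfortably below the
property margins being checked.

## Known limitations

The effective-TS signal model is a stand-in for the sequence-specific
conversion; the basis/penalty/λ-selection of the deconvolution are this
package's choices, since the validated source method does not publish them;
whether "amplitude" is the maximum of h or an early plateau average is
likewise unpublished (maximum used, window configurable). Pixel-wise flow
maps, stress perfusion, dual-bolus AIF correction, MOLLI fitting of raw
inversion-recovery images, and survival analysis are out of scope. The
cohort generator reproduces the published statistical structure, not
patient data; agreement of downstream estimates with published cohort
values demonstrates calibration, not reproduction.
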
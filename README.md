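# cmrquant

Quantitative cardiac MRI analysis for interstitial (amyloid) cardiomyopathy
studies: rest myocardial blood flow from first-pass perfusion, extracellular
volume from multi-timepoint T1 mapping, a surrogate for myocardial work
efficiency from routine hemodynamics, and the cohort-level inference that
ties them together. It is written for imaging scientists and biostatisticians
who need a tested, reproducible implementation of this chain — and, because
patient data of this kind cannot be redistributed, every stage ships with a
synthetic-data generator carrying known ground truth.

## What it computes

**Myocardial blood flow.** Segmental first-pass signal curves are converted
to relaxation-rate changes with the saturation-recovery model
S = S0·(1 − e^(−TS·R1)), S0 calibrated per region from pre-contrast frames.
The tissue ΔR1 curve is the convolution of the arterial input with the
tissue impulse response h(t); h is estimated model-independently on a cubic
B-spline basis by penalized least squares (GCV-selected regularization,
physiological monotone shape constraint), and by the central volume
principle

    MBF = 60 · max h(t) / ρ   [ml/min/g],  ρ = 1.05 g/ml.

**Extracellular volume.** Per segment, the gadolinium partition coefficient
λ_Gd is the OLS slope of tissue R1 on blood R1 across pre-contrast, 10-min
and 20-min maps, and ECV = (1 − Hct)·λ_Gd.

**Surrogate myocardial work efficiency.**
MWE = CO·MAP / LV mass [mmHg·L·min⁻¹·g⁻¹], with CO from CMR stroke volume
and heart rate and MAP = DBP + (SBP − DBP)/3.

**Cohort inference.** ECV-tertile stratification with linear trend tests,
pairwise Pearson matrices, stepwise-AIC multivariable models with forced
covariates, a bootstrap mediation decomposition of the ECV→MWE effect into
a direct path and a path mediated by MBF (indirect = a·b, total = c′ + a·b),
random-intercept mixed models for segmental MBF and the base-to-apex
gradient, Holm adjustment, a logistic LGE~ECV model, and exact noncentral-t
power.

## Worked example

Simulate a perfusion dataset with a known flow of 1.0 ml/min/g at image
SNR 40, then quantify it:

```sh
$ cmrquant simulate-perfusion --seed 3 --mbf 1.0 --snr 40 --out curves.csv
wrote curves.csv
$ cmrquant quantify-mbf --curves curves.csv --out mbf.csv
global MBF = 1.089 ml/min/g
```

The global estimate is the mean over the 16 AHA segments; `mbf.csv` holds
the per-segment flows with the chosen regularization weight and fit
residual, plus a `GLOBAL` row. A synthetic T1 dataset generated with
λ_Gd = 0.7667 at hematocrit 0.40 comes back at the configured ECV:

```sh
$ cmrquant simulate-t1 --seed 1 --lam 0.7667 --noise-sd 0.02 --out t1.csv
$ cmrquant quantify-ecv --t1 t1.csv --hct 0.40 --out ecv.csv
global ECV = 46.0%
```

A full synthetic cohort (n = 92) exercises the inference layer:

```sh
$ cmrquant simulate-cohort --seed 1 --out cohort
$ cmrquant compute-mwe --cohort cohort/cohort.csv --out cohort_derived.csv
$ cmrquant analyze-cohort --cohort cohort/cohort.csv \
      --segments cohort/segments.csv --seed 1 --out report
{
  "rest_mbf": { "slope": -0.0585, "p": 0.0182, "n": 92 },
  "mwe":      { "slope": -0.9485, "p": 4.2e-08, "n": 92 },
  ...
}
```

Both MBF and MWE decline across ECV tertiles (negative trend slopes with
p < 0.05), `report/mediation.json` decomposes the ECV→MWE effect (for this
seed: −0.45 direct and −0.08 mediated per 5% ECV, i.e. ~14% of the total
effect runs through blood flow), `report/lmm_segmental.json` shows the
segment-level ECV effect on MBF (−0.0034 per 1% here), and
`report/lge_logistic.json` the LGE odds ratio per 1% ECV. A single
`cmrquant run-pipeline --seed 1 --out run/` wires simulate → quantify →
analyze into one bundle with a manifest; reruns with the same config are
identical.

## Layout

- `src/cmrquant/signal_model.py` — saturation-recovery signal ↔ R1
- `src/cmrquant/perfusion.py` — regularized deconvolution, segmental MBF
- `src/cmrquant/tissue_mapping.py` — λ_Gd and ECV
- `src/cmrquant/hemodynamics.py` — MAP, CO, EW, MWE, RPP, BSA indexing
- `src/cmrquant/cohort_stats.py` — the inference layer
- `src/cmrquant/synthetic.py` — generators (calibration in `data/cohort_defaults.yaml`)
- `src/cmrquant/io.py`, `pipeline.py`, `cli.py` — CSV dialects, run bundle, CLI

See `docs/methods.md` for the model assumptions, parameter defaults, what
the generators do and do not emulate, and known limitations.
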
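# renal-ivim

Quantitative analysis of multi-b renal diffusion-weighted MRI for the
detection of early chronic kidney disease (CKD), built for imaging
scientists who want a tested, scriptable version of the standard
three-model cortical analysis: signal models, fitters, a synthetic study
cohort, and the group-level statistics that turn fitted parameters into a
diagnostic readout.

## The models

The normalized signal decay S(b)/S0 of a cortical region over diffusion
weightings b (s/mm²) is described three ways:

* **Monoexponential** — `S(b)/S0 = exp(−b·ADC)` with the apparent
  diffusion coefficient ADC.
* **Biexponential (IVIM)** —
  `S(b)/S0 = f·exp(−b·ADC_fast) + (1−f)·exp(−b·ADC_slow)`, separating
  capillary pseudo-diffusion (ADC_fast, weighted by the perfusion
  fraction f) from true tissue water diffusion (ADC_slow).
* **Stretched exponential** — `S(b)/S0 = exp(−(b·DDC)^α)` with the
  distributed diffusion coefficient DDC and the intravoxel heterogeneity
  index α ∈ (0, 1] (α = 1 is homogeneous Gaussian diffusion).

Renal function is summarized by the ID-MS-traceable MDRD estimate
`eGFR = 186·SCr^−1.154·age^−0.203·(0.742 if female)` (serum creatinine
converted from μmol/L to mg/dL), and patients split at
eGFR 90 mL/min/1.73 m² into preserved ("high eGFR") and reduced
("low eGFR") function groups. Biopsy damage is carried as a
semi-quantitative score: glomerular (0–12) + tubulointerstitial (0–9) +
vasculopathy (0–6).

The ADC comes from a log-linear least-squares fit over all 13 b-values
(0–1000 s/mm²); the IVIM and stretched models are fitted by bounded
nonlinear least squares with a segmented initialization and a
deterministic multistart. A seeded generator synthesizes whole study
cohorts (demographics, creatinine consistent with eGFR, cortical
parameters, Rician-noise ROI signal curves, two simulated readers,
biopsy scores), and the statistics module provides the full analysis
plan: Shapiro–Wilk screening, Mann–Whitney / Kruskal–Wallis + Dunn,
Spearman with Bonferroni adjustment, ICC(2,1) inter-reader agreement,
and ROC with DeLong confidence intervals and Youden-optimal thresholds.

## Worked example

```bash
python examples/fit_worked_examples.py
```

refits noiseless signals synthesized from the two illustrated patients'
printed cortical values and prints, e.g. for the preserved-eGFR patient:

```
== preserved-eGFR patient (95 mL/min/1.73 m2)
  ADC      true 2.33  fitted 2.3300  (1e-3 mm2/s)
  ADCslow  true 1.75  fitted 1.7500
  ADCfast  true 26.50  fitted 26.5000
  f        true 0.29  fitted 0.2900
  DDC      true 3.12  fitted 3.1200
  alpha    true 0.64  fitted 0.6400
```

i.e. every printed parameter is recovered exactly from clean data. The
other examples show the synthetic cohort (`generate_cohort.py`), the
diagnostic ROC table (`diagnostic_performance.py` — on the default
cohort α, f and ADC_fast reach AUC ≈ 0.99/0.97/0.94 for control-vs-CKD
while DDC and ADC_slow stay near 0.80/0.70), and the noise sensitivity of
the biexponential fit (`noise_sensitivity.py`).

The same pipeline is scriptable from the shell:

```bash
renal-ivim generate --seed 1 --out cohort/
renal-ivim fit --signals cohort/signals.csv --out fitted.csv
renal-ivim analyze --cohort cohort/ --fitted fitted.csv --out report/
renal-ivim reproduce --seed 1 --out run/   # all three + summary
```

All outputs are plain CSV/JSON and byte-identical across reruns with the
same seed.

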
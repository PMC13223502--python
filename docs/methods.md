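# Methods

## Signal models and units

Three normalized descriptions of multi-b diffusion signal decay are
implemented (`renal_ivim.models`):

* monoexponential `exp(−b·ADC)`;
* IVIM biexponential `f·exp(−b·ADC_fast) + (1−f)·exp(−b·ADC_slow)`;
* stretched exponential `exp(−(b·DDC)^α)`.

Diffusion coefficients are stored in mm²/s and displayed in
10⁻³ mm²/s (the reporting convention of renal DWI); `f` and `α` are plain
fractions even where clinical tables label them "(%)". All models are
evaluated on S(b)/S(0): S0 is a normalization, not a display parameter
(an optional free-S0 fit exists in the fit configuration). The
acquisition scheme is the 13-weighting protocol
b = 0, 10, 20, 30, 50, 70, 100, 150, 200, 400, 600, 800, 1000 s/mm².
The published excitation-count (NEX) list has 12 entries for 13
b-values; the default scheme assigns them to the first 12 weightings and
reuses the final value (8) for b = 1000. NEX enters only the noise model
(and optional fit weighting), so this convention is configurable and
benign.

The MDRD eGFR uses the mg/dL-based coefficients; serum creatinine input
in μmol/L is divided by 88.4 first. This is required for dimensional
consistency: applying the coefficients to μmol/L directly yields eGFR
values two orders of magnitude too small relative to the creatinine and
eGFR scales the formula is meant to connect.

## Fitting

* **ADC**: weighted log-linear least squares over all usable (positive)
  signal points; non-positive samples are excluded with a warning. A
  slope below 10⁻⁷ mm²/s is flagged `degenerate`.
* **IVIM**: segmented-then-refine. A log-linear fit restricted to
  b ≥ 200 s/mm² (where perfusion has decayed) gives ADC_slow and, via its
  intercept, f; a one-dimensional bounded fit gives ADC_fast; a full
  three-parameter bounded nonlinear least-squares refinement follows,
  started from a deterministic 3×3 grid around the segmented estimate
  (f × {0.5, 1, 1.5}, ADC_fast × {0.5, 1, 2}); best residual sum of
  squares wins, ties to first-found. A "free" strategy (fixed global
  start grid, no segmented stage) is available in the configuration.
* **Stretched**: two-parameter bounded fit started from the log-linear
  slope and α ∈ {0.55, 0.75, 0.95}.

The refinements use scipy's trust-region reflective least-squares solver
— the bounded variant of the classic Levenberg–Marquardt problem; plain
LM cannot honor parameter boxes. Bounds encode renal-tissue
plausibility: ADC_slow ∈ [0.1, 3.0]×10⁻³, ADC_fast ∈ [3, 100]×10⁻³,
DDC ∈ [0.1, 5.0]×10⁻³ mm²/s, f ∈ [0, 1], α ∈ (0.01, 1]. The disjoint
ADC_slow/ADC_fast boxes enforce ADC_fast > ADC_slow by construction.
Convergence tolerances are 10⁻¹⁰ (relative step, cost and gradient),
max 500 iterations per parameter. Fits are unweighted by default
(weighting is unstated in the emulated protocol); inverse-variance NEX
weighting is available via `FitConfig(nex_weighting=True)`. There is no
randomness anywhere in fitting.

Noiseless curves synthesized from parameters inside the bounds are
recovered to solver precision (≪ 1%), verified for all printed
worked-example values and against a dense 50³ grid-search oracle (the
fitted RSS never exceeds the grid minimum).

### Precision under noise

With Rician noise at SNR 20 (per-b σ = (1/SNR)/√NEX) the biexponential
fit of a typical preserved-function parameter set
(f = 0.29, ADC_slow = 1.75×10⁻³, ADC_fast = 26.5×10⁻³) achieves a median
absolute relative error of ≈ 10% for f and ≈ 5% for ADC_slow, but
≈ 26% for ADC_fast. This is not a solver defect: the Cramér–Rao bound
for this scheme and noise level implies ≳ 21% median error for any
(near-)unbiased three-parameter estimator, and an oracle fit with f and
ADC_slow held at truth still shows ≈ 29% because the likelihood in
ADC_fast is strongly right-skewed (the fast compartment has decayed by
b ≈ 100 s/mm², so high ADC_fast values are weakly constrained). The
central estimate is nevertheless median-unbiased (≈ 1% bias), and errors
shrink monotonically with SNR. This quantifies the well-known
instability of pseudo-diffusion estimates and matches the motivation for
low-b-dense acquisition schemes.

## Synthetic cohort

The generator (`renal_ivim.cohort`) emulates a three-group early-CKD
study: 19 healthy controls, 33 CKD patients with eGFR ≥ 90, 28 with
eGFR < 90, each contributing 6–9 cortical ROIs of 35–50 mm². Defaults
are the emulated study conditions and are not meant to be tuned.

* **Marginals.** Group-conditional parameter distributions are
  log-normal matched to the published median and interquartile range
  (σ = ln(q75/q25)/(2·z₀.₇₅)); the perfusion fraction, published as
  mean ± SD, is truncated normal on [0, 1]; α is capped at 1. eGFR
  marginals are log-normal matched the same way, truncated at the
  90-unit grouping boundary for patients so drawn labels are consistent
  by construction. Creatinine is inverted exactly from the drawn eGFR,
  age and sex through the MDRD formula. Age is truncated normal per
  group; sex is Bernoulli with the published group ratios.
* **Coupling.** One latent severity per subject (standard normal) feeds
  a Gaussian copula: parameter quantiles load negatively on severity
  (loading 0.6), eGFR negatively (0.7), biopsy-score latents positively
  (0.6). The copula leaves every marginal exactly intact while
  producing the expected correlation structure (Spearman ρ ≈ +0.6–0.75
  between perfusion markers and eGFR, ≈ −0.5 with tubulointerstitial
  score at 10× sample size). The loadings were calibrated once to this
  reported regime.
* **Scores.** Each component (glomerular/tubulointerstitial/
  vasculopathy) is a rounded, range-clipped normal latent whose
  group-level mean and SD reproduce the published medians and IQRs
  (e.g. glomerular medians 2 vs 5 for preserved vs reduced eGFR; total
  ≈ 5 vs 11); the reduced-function group stochastically dominates
  componentwise.
* **Signals.** Each ROI's curve is the forward model plus Rician
  magnitude noise: complex Gaussian perturbation of scale
  (1/SNR)/√NEX_b, single-draw (the multi-excitation average is folded
  into the scale rather than simulated draw-by-draw). Default SNR 50 at
  b = 0 per excitation, a realistic 3-T abdominal figure. ROI-to-ROI
  biological variation is median-preserving log-normal jitter (3%).
* **Measurement channels.** One physical curve cannot carry
  independently anchored parameters for all three models at once — a
  control-range perfusion fraction (f ≈ 0.34) would force the *lowest*
  fitted α, inverting the published group ordering of α. Since the
  emulated vendor pipeline outputs six parameter maps, each model is
  treated as its own measurement channel: per ROI, one curve per model
  is synthesized from that model's true parameters (`signals.csv` has a
  `model` column) and the fit stage applies the matching fitter. This
  is the main idealization of the generator: real data would derive all
  six parameters from a single acquisition, with cross-model
  constraints the synthetic study does not represent. Passing
  regime tests therefore validate the pipeline's statistics and
  estimators, not the physical joint behavior of the three models.
* **Readers.** Two simulated radiologists re-place every ROI; this is
  modeled as independent multiplicative jitter (scale 2%) per ROI,
  reader and parameter, applied before averaging over the subject's
  ROIs. Zero jitter gives identical readers (ICC = 1); the default
  reproduces the reported excellent-agreement regime (ICC ≈ 0.95–1.0).

Everything descends from a single integer seed through one generator
stream; regenerating with the same configuration is bit-identical.

## Statistics

Presentation follows a Shapiro–Wilk screen at α = 0.05 (mean ± SD if all
groups normal, median (IQR) otherwise; the same screen selects one-way
ANOVA + Welch t-tests vs Kruskal–Wallis + Dunn). Dunn's pairwise z uses
the tie-corrected rank variance; pairwise p-values are Bonferroni-
multiplied by the number of pairs and capped at 1. Mann–Whitney is exact
(enumeration) when n₁·n₂ ≤ 400 and tie-free, tie-corrected asymptotic
otherwise. Spearman correlations are Bonferroni-adjusted within one
family per target column (default family size = number of parameters,
recorded in the output so alternative conventions are auditable).
Inter-reader agreement is ICC(2,1) — two-way random effects, absolute
agreement, single measures — the standard choice for interobserver
reproducibility of continuous measurements (computed via pingouin,
F-based 95% CI). ROC analysis reports the empirical AUC (equal to
U/(n₁n₂) by construction), a DeLong 95% CI and p-value against
AUC = 0.5, and the Youden-optimal threshold with a `≤` decision rule for
markers lowered by disease (ties broken toward the first threshold on
the sorted path). A constant input vector is classified non-normal with
a `degenerate` flag rather than erroring, so degenerate synthetic
columns don't abort a report.

The report builder assembles demographics, parameter comparisons,
pathology comparisons, correlations, ROC and ICC tables with the same
row/column semantics as the emulated study's tables; eGFR correlations
use all subjects, score correlations patients only.

## Known limitations

* No spatial modeling: ROIs are abstract signal collections; no NIfTI
  volume path, no partial-volume or motion effects.
* Multi-excitation averaging is approximated by a single Rician draw at
  reduced σ; at very low SNR the exact average of magnitudes has a
  slightly different distribution.
* The per-model measurement-channel design (above) means cross-model
  consistency of a single physical signal is out of scope.
* Biopsy scores model only component ranges and their group-level
  distributions, not the underlying sub-item rubric.
* The pipeline's group sizes (19/33/28) imply sizable sampling noise in
  group medians; close medians (e.g. DDC in control vs preserved-eGFR
  groups) can occasionally invert for an unlucky seed — a property of
  the emulated design, not of the estimator.
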
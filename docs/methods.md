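# Methods

## The analysis problem

A GC-IMS measurement of a faecal headspace is a matrix of ion currents over
GC retention time (seconds, one axis) and IMS drift time (milliseconds, the
other).  Analyte compounds appear as localised peaks; every spectrum also
carries the reactant-ion peak (RIP), a drift-time ridge produced by the
ionisation source itself and present regardless of the sample.  Group
differences (e.g. coeliac disease in remission vs refractory coeliac
disease) are expected as intensity shifts at a subset of peak locations,
driven by gut-microbiota-dependent VOC abundances.  The cohorts of interest
are very small (tens of samples) while the maps have 10³–10⁴ pixels, so the
central statistical hazards are selection leakage and overfitting; the
pipeline is organised around avoiding the first and measuring the second.

## Preprocessing

Three steps, in order, each a pure function of the input map(s):

1. **Crop** to a caller-supplied rectangle in physical units.  No universal
   default exists — the informative region depends on the GC program and
   drift-tube geometry — so the window is a required configuration
   parameter; the synthetic generator exports a window matched to its own
   peak placement.  The window must retain the RIP ridge, because step 3
   uses it as the registration landmark.
2. **Noise threshold**: values below a threshold become exactly zero,
   everything else passes unchanged (idempotent by construction).  The
   threshold is either explicit or estimated as `median + 3·MAD` of a
   caller-designated background window known to contain no analyte signal.
   The MAD is the raw median absolute deviation (unscaled); the factor 3 on
   an unscaled MAD corresponds to ≈4.4 σ for Gaussian noise, a deliberately
   conservative cut so that surviving pixels are overwhelmingly signal.
3. **Baseline realignment**: drift-time registration plus baseline removal,
   the two dominant instrumental disturbances in drift-tube IMS.  Each
   sample's RIP position — the drift bin maximising the retention-averaged
   intensity — is shifted by an integer number of bins onto the cohort
   median RIP bin (or an explicit reference).  Vacated bins are zero-filled;
   wrapping would fabricate signal.  Then, per retention row, the 5th
   percentile is subtracted and negatives are clipped at zero.  Applied
   shifts are recorded in each chromatogram's provenance metadata.  A flat
   map (no detectable RIP) gets a warning and zero shift rather than an
   arbitrary one.

After preprocessing, each map is flattened row-major (retention outer) into
one row of a samples × pixels feature matrix; one feature per retained
pixel, no peak calling.  This is the simplest featurisation consistent with
selecting "the k most discriminatory features" in a pattern-recognition
pipeline, and it keeps the feature→coordinate mapping invertible.
Intensity normalisation (e.g. to RIP depletion) is deliberately not
applied; it is a config extension point.

## Cross-validated classification

Folds are stratified (with a 7-sample minority class, unstratified 10-fold
splits can lose a class from a training set) and deterministic given the
seed; `k = n` degrades to leave-one-out.  Within each fold, and using the
training rows only:

* every pixel is scored by a two-sided Wilcoxon rank-sum test between the
  two groups — the vectorised scorer uses the normal approximation with tie
  correction and 0.5 continuity correction, since after thresholding most
  background pixels are exactly zero and ties are pervasive;
* features are ranked by (p ascending, |median difference| descending,
  pixel index ascending) — the deterministic three-level key makes selected
  sets reproducible across runs and platforms — and the top 100 kept;
* features are standardised on the training rows and the classifier is
  fitted, then calibrated probabilities are emitted for the held-out rows.

Classifier defaults (fixed, not searched): lasso logistic regression
(liblinear, C = 1, large `intercept_scaling` so the intercept is effectively
unpenalised), random forest (200 trees), Gaussian-process classifier (RBF
kernel, unit length scale), RBF-SVM (C = 1, `gamma="scale"`) with Platt
sigmoid calibration fitted within the training fold, and a 32-unit
single-hidden-layer perceptron (α = 0.01).  All are seeded; a fixed
(config, seed) pair reproduces byte-identical outputs.

The scalar `ranksum_pvalue` helper used for reporting switches to the exact
permutation distribution for small untied samples (as mainstream
statistical software does) and falls back to the corrected normal
approximation otherwise; at the cohort sizes involved the two differ by at
most a few hundredths.

## Performance metrics

All computed from pooled out-of-fold probabilities. AUC is the normalised
Mann–Whitney statistic (ties ½), identical to the trapezoidal area under
the empirical ROC.  The 95% CI is DeLong's structural-component estimate
with a normal interval clipped to [0, 1]; at AUC exactly 0 or 1 the
variance degenerates and the interval collapses to the point estimate with
a flag.  Significance of discrimination is the two-sided rank-sum test
between the two groups' probabilities — by the U-statistic identity this
tests exactly AUC = ½, and it is invariant to any monotone transform of the
probabilities.  p-values are reported at full precision and rendered
`<0.001` below that.  The reporting cutoff maximises Youden's J over
observed probabilities with ties broken toward the lower cutoff
(rule: probability ≥ cutoff ⇒ positive); the positive class is the
first-named group of a comparison.  This metric definition set is
self-consistent with the published CD-vs-RCD row: exhaustive search shows
exactly one confusion matrix at n = 13/7 (TP = 11, FN = 2, TN = 6, FP = 1)
rounds to sens 0.85 / spec 0.86 / PPV 0.92 / NPV 0.75, and the
operating-point routine returns precisely those values on any probability
vector inducing it.

## Exact cohort statistics

Fisher's 2×2 exact test uses the two-sided probability-mass rule: the
p-value sums hypergeometric probabilities of all tables with the observed
margins whose probability is ≤ the observed one × (1 + 10⁻⁷); the relative
tolerance guards against floating-point misclassification of equal-mass
tables and matches the convention of mainstream statistical software.
The Fisher–Freeman–Halton r×c generalisation enumerates the full
margin-conditioned family depth-first with a cell-by-cell feasibility bound
and a 10⁷-table budget (a 30-subject 3×2 table enumerates in well under a
millisecond; the budget turns pathological inputs into an explicit error
rather than a hang).  The enumerated multivariate-hypergeometric masses sum
to 1 within 10⁻⁹.  Kruskal–Wallis uses the tie-corrected H with the
chi-square approximation (df = groups − 1).  The baseline-characteristics
report applies Kruskal–Wallis plus pairwise rank-sum tests to continuous
covariates and the Fisher–Freeman–Halton plus pairwise Fisher tests to
dichotomous ones, echoing medians/IQRs and counts.

## The synthetic generator

Per sample: `RIP ridge + Σ analyte peaks + smooth baseline + white noise`,
then an integer drift-bin jitter.  Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| grid | 120 × 110 over 0–360 s × 5–15 ms | 6-min GC program; typical drift window |
| RIP | 7.0 ms, amplitude 500 | dominant ridge, early drift times |
| peak drift FWHM | centre / 75 | drift-tube resolving power 75 |
| peak retention σ | 5 s | a few GC bins, typical column broadening |
| peaks | 30, amplitudes U(50, 150) | tens of detectable compounds per sample |
| discriminatory peaks | 5, ×4 in the case group | sparse multiplicative microbiome-driven shifts |
| biological CV | 0.3 (log-normal, unit mean, per peak per sample) | compound-level abundance variation |
| baseline | ≤10, smooth sinusoid product | slow background drift |
| noise σ | 3 | detector noise well below analyte amplitudes |
| jitter | ±2 drift bins, uniform integer | instrumental drift, exercises realignment exactly |

Peak layout derives from the cohort seed; each sample draws from an RNG
substream keyed by (seed, sample index), so cohorts are bitwise
reproducible and independent of generation order.  Under effect size 1 the
generator is exchangeable across groups.

What the generator does *not* emulate: RIP depletion coupling (real RIP
intensity drops where analytes ionise), peak tailing, retention-time drift,
chemically realistic VOC libraries, and inter-compound correlation beyond
the shared per-peak amplitude factor.  Passing tests therefore demonstrate
that the pipeline recovers planted multiplicative effects and respects its
own null on data with this structure — not that the published cohort's
effect sizes are reproducible, which would require the undeposited samples.

## Behaviour under the null, honestly stated

With 13-vs-7 cohorts, within-fold selection of 100 pixels and 10-fold CV,
the pooled out-of-fold AUC under a true null is *over-dispersed*: its
median sits near ½, but individual replicates regularly fall outside
[0.25, 0.75], and the rank-sum p on pooled probabilities (which treats them
as i.i.d. across folds) is anti-conservative — around 25% of null cohorts
reach p < 0.05 instead of the nominal 5%.  Control experiments in the test
suite show this is a property of the protocol at this sample size (it
occurs with purely independent Gaussian features and with block-correlated
ones alike, and worsens as the effective feature pool grows), not of the
generator.  The mechanism is classical: a held-out sample's own extreme
pixels influence which features the remaining samples select, producing
systematic anti-prediction of outliers.  Practical implication: at this
cohort scale, small out-of-fold p-values should be interpreted against a
simulation-calibrated null (which this package can generate), not against
the nominal uniform distribution.

## Problem sizes and runtime

The default grids and cohort sizes are chosen so the entire test suite and
the reproduction script each run in tens of seconds on a single CPU: unit
tests use 30–60-bin grids; the parameter-recovery study runs 20 seeds × 2
effect sizes at the full 120 × 110 default grid (~0.5 s per cohort through
the complete pipeline).

## Known limitations

* Pixel features only; no peak detection, deconvolution or retention-index
  calibration against ketone standards.
* Realignment is integer-bin and drift-axis only; sub-bin drift and
  retention drift are not corrected.
* The Fisher–Freeman–Halton implementation is exhaustive; tables whose
  margin family exceeds the budget need a Monte-Carlo variant that is
  deliberately not provided.
* No multiple-testing correction of per-pixel p-values — the pipeline uses
  them as ranks, never as significance claims.
* Binary comparisons only, mirroring the three pairwise study contrasts; no
  multiclass model, repeated CV or hyperparameter search.
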
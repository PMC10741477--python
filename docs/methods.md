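# Methods

## Dose–response model

Percent inhibition at log10 dose `x` follows the four-parameter logistic
(4PL) `y(x) = bottom + (top − bottom)/(1 + 10^(slope·(L − x)))` with
`L = log10(IC50 µM)`. `top` and `bottom` are percent-inhibition asymptotes,
`slope` the Hill coefficient. By construction `y(L) = (top + bottom)/2`.

Two control-scaling modes are supported. DSRT mode scales to both plate
controls, `inh = 100(neg − s)/(neg − pos)`; negative-only mode (used for
temozolomide-style assays normalised to DMSO alone) reports
`inh = 100 − 100·s/neg`. Inhibition outside [0, 100] is kept and flagged,
never clipped: clipping truncates the noise distribution asymmetrically and
biases the fitted asymptotes.

### Fitting

Least squares (scipy TRF) with an analytic Jacobian. Defaults: `bottom`
fixed at 0 (an inhibition baseline; freed only on request), `top` bounded
[0, 120] to tolerate noisy over-inhibition, `slope` ∈ [0.1, 10], IC50
within [c_min/100, c_max·100]. Initialisation is deterministic — `top` at
the maximum observed inhibition, IC50 at the dose nearest half-maximal
response, slope 1 — so a refit of the same table is bit-reproducible.
With fewer than 4 distinct doses the parameter count degrades gracefully
(bottom fixed; at 2 doses the slope is fixed at 1); fewer than 2 distinct
doses is an error.

Curves whose observed response spans < 5 percentage points are flagged
degenerate, not fitted, and score DSS = 0. This floor avoids fitting pure
noise on inactive drugs.

A second optimisation stage with machine-precision tolerances runs only
when the first stage ends with a small but non-zero residual
(1e−16 < SSE < 1e−4). This is the signature of a steep curve responding
only at the edge of the dose window, where the least-squares valley is
extremely flat and the optimiser otherwise stalls short of the exact
solution; the polish restores exact round-trips on noiseless input without
slowing the (noisy) common case.

### DSS

With `A` the closed-form integral of `(y(x) − t)` over the part of the
window where the curve exceeds the activity threshold `t` (default 10%),
computed from the antiderivative
`∫ dx/(1 + 10^(s(L−x))) = ln(1 + 10^(s(x−L)))/(s·ln 10)` (evaluated with
`logaddexp` for overflow safety), the score family is

* `dss1 = 100·A/((100 − t)·Δx)` — normalised area, 0–100;
* `dss2 = dss1/log10(top)` — default; penalises partial-efficacy curves and
  rescales to 0–50 (a full-inhibition curve scores exactly 50);
* `dss3 = dss2·(x_max − x_1)/Δx` — additionally weights by the fraction of
  the window above threshold.

The variant is a config knob because the upstream screening literature uses
all three; every internal test validates the closed form against numeric
trapezoid integration rather than against any external implementation.
Curves with `top ≤ t` score 0, as do degenerate fits. The normalised AUC
(`∫y dx / (100·Δx)`) and the fitted IC50 are reported alongside.

Missing culture × drug cells propagate as missing everywhere; nothing is
imputed.

## Heterogeneity statistics

* **sDSS** — `DSS − mean(reference DSS)` per drug, reference mean over
  non-missing values.
* **Responders** — drugs with DSS ≥ 10 (inclusive) in at least one culture
  of the group of interest; the pipeline uses the multiregional group, the
  threshold marking a moderate-to-strong response.
* **Correlation** — pairwise Spearman over drugs shared by each culture
  pair (pairwise deletion; pairs sharing < 3 drugs are left missing with a
  warning).
* **Variance F-tests** — per drug, `F = var_inter/var_intra` with
  (n_ref − 1, n_mr − 1) degrees of freedom, upper-tail p (the alternative is
  strictly "more variable between tumors than within"), Benjamini–Hochberg
  across tested drugs. Zero intra-tumor variance with positive inter-tumor
  variance gives F = ∞, p = 0; drugs with both variances zero or fewer than
  two values per group are skipped and listed.
* **ΔDSS/ΔSD** — `ΔDSS = mean_tumor − mean_ref`,
  `ΔSD = SD_ref − SD_tumor` (so positive ΔSD = intratumorally homogeneous).
  Exact zeros are routed to "nonspecific"/"heterogeneous" — the
  conservative side, since a tie is no evidence of specificity or of
  homogeneity; the rule is recorded in the output metadata.
* **Clustering** — Euclidean distance, complete linkage by default; rows
  and columns are sorted lexicographically before linkage so equal-distance
  merges break ties deterministically; trees are exported as Newick with
  cophenetic branch lengths.
* **PCA** — complete-case drug selection first (any missing culture drops
  the drug), then `log2(value + 0.01)`, centering, full SVD. DSS is
  floored at 0 so the transform is defined; negative input is an error.

## Expression dispersion mixture

Filters run in order and record one reason per gene: QC-failed flag,
all-zero TPM, mean TPM < 1 (strict, so a gene at exactly 1.0 is kept).
Filtering is idempotent.

Dispersion is the natural log of the cross-sample SD of raw TPM (n−1
denominator). The SD of raw TPM rather than of log-TPM is the literal
definition used; the log base only shifts component parameters, not the
classification, and is configurable. Zero-SD genes get a −∞ sentinel,
are excluded from fitting, and end up unclassified with a recorded reason.

The two-component Gaussian mixture on log-SD is fitted by EM written
in-package: deterministic initialisation (component means at the k interior
quantiles, pooled SD, equal weights), convergence when the log-likelihood
gain drops below 1e−8 (max 1000 iterations), components reported in
ascending mean order for identifiability. If a component collapses
(vanishing variance or weight), the fit restarts from seeded jittered means
up to 5 times. sklearn's GaussianMixture is used in the test suite as an
independent cross-check, never as the implementation.

Genes are homogeneous when the posterior of the low-dispersion component is
≥ 0.998 (inclusive — "at least" a 99.8% credibility), heterogeneous when the
high-dispersion posterior is, otherwise unclassified; thresholds ≤ 0.5 are
rejected because the labels would overlap. The four labels (with
"filtered") always partition the gene set. On unimodal (null) data the
2-component MLE converges to two heavily overlapping components; no point
then reaches the 0.998 posterior, so nothing is spuriously classified —
this is the tested null behavior.

Signature scoring is generic over user-supplied gene sets: per-gene
z-scores (sample SD, ddof = 1) of `log2(TPM + 0.01)` across samples,
averaged over the set per sample; constant genes score z = 0 with a
warning, and set coverage is reported.

## Synthetic cohort generator

The generator emulates the study design the statistics assume, with every
quantity seeded and reproducible.

**Screen.** Defaults: 7 multiregional + 14 reference cultures, 115 drugs,
5 log-equispaced doses spanning 0.4–250 µM, 16 negative and 8 positive
control wells per plate, 5% multiplicative log-normal well noise
(unit-mean; plates measure luminescence, so noise is proportional).
Ground truth is planted on the DSS scale: drug-level mean scores are
gamma-distributed (shape 1.2, scale 4 — most drugs weakly active, ~30% of
drugs reaching DSS ≥ 10 in at least one multiregional culture, matching the
responder fraction reported for GSC panels); the multiregional cultures
share one tumor-level offset per drug (SD = inter_sd) and scatter around it
with intra_sd = 2; reference cultures scatter with inter_sd = 4. Targets
below 0.01 DSS count as inactive and get a flat zero-response curve. For
each active target the generator fixes top = 100, bottom = 0, slope = 1 and
solves for the IC50 reproducing the target DSS exactly by 1-D root finding
(DSS is continuous and strictly decreasing in log IC50 wherever positive),
so the planted intra/inter variance ratio is exact on the score scale.
Well signals are `neg_mean·(1 − inh/100)`; the positive-control level
defaults to 0 (complete kill), which makes both scaling modes exact
inverses of the generator — with zero noise the whole pipeline round-trips
to machine precision. Requesting intra_sd > inter_sd warns (it inverts the
study premise) but runs, for null simulations.

**Expression.** Per gene a component label is drawn (10% heterogeneous),
a true log-SD from N(0, 0.5) or N(4, 0.5) — components 8 pooled SDs apart —
and TPM values log-normally with that SD around a mean equal to the SD
divided by a per-gene CV drawn uniformly from [0.2, 0.8]. Tying the mean to
the SD keeps tails moderate, which matters because with 7 samples the log of
the sample SD carries irreducible noise of about 1/√(2(n−1)) ≈ 0.29; at
extreme CVs the sample SD of a log-normal is biased far downward and the
planted components would smear together, which is a property of small-sample
SD estimation, not of the classifier. QC-failed (2%), all-zero (5%) and
low-expression (10%, mean < 1) genes are planted to exercise every filter.

**What the generator does not emulate** — and hence what passing tests do
not show about real screens: plate spatial/edge effects, drug-class
correlation structure across the panel, mean–variance coupling of
luminescence beyond a constant CV, culture-specific fitness differences,
mixed-quality dose series (all drugs share one dose range), and any
mutation- or pathway-level link between the expression and drug-response
layers. Recovery results bound algorithmic error only.

## Problem sizes and runtime

The default end-to-end pipeline (21 cultures × 115 drugs × 5 doses,
2415 curve fits, plus 5000 genes × 7 samples) completes in about a minute
on one CPU. Simulation-based calibration uses 1000 replicates of the
115-drug screen for the F-test (type-I error and power), 500 curves for
noisy IC50 recovery, 1000 random parameter sets for the integration oracle,
and 50 replicate cohorts for variance-ratio recovery; these sizes give
Monte-Carlo standard errors well below the margins being tested.

## Known limitations

* The DSS variant actually used by any given external screening platform is
  not standardised; results across variants are monotonically related but
  not numerically identical, so cross-study DSS comparisons should fix the
  variant and threshold.
* With 5 doses, IC50s outside the tested window are extrapolations; the fit
  bounds keep them finite but their variance is large (the noisy-recovery
  benchmark conditions on IC50 inside the window for this reason).
* The F-test assumes approximate normality of DSS within groups; planted
  truth is normal by construction, real DSS distributions are floor-censored
  at 0, which makes the test conservative for weakly active drugs.
* EM on the dispersion mixture fits two components regardless of the true
  number; with unimodal data the fit is a valid MLE but its component
  parameters are not individually interpretable (only the absence of
  confident classifications is).
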
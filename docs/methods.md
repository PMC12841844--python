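# Methods

This note records the statistical model behind `fourway`, the defaults and
why they were chosen, and the limits of what the test suite demonstrates.

## Design and rationale

The target design is a 2×2 factorial — surgery (Sham / RYGB) × diet (Chow /
HFD), five animals per cell — in which one cell (Sham-HFD) can carry a
strong phenotypic confound (body weight) that distorts a joint factorial
model. The pipeline therefore treats the design as four independent
two-group contrasts and reconstructs factorial structure set-theoretically:
same-direction significance intersections define treatment-common and
diet-common genes, a sign-opposition rule against the obesity-signature
contrast defines reversal genes, and the interaction-like "RYGB-specific
HFD" set is an adjusted-p filter of the within-RYGB diet contrast after
subtracting the diet-common set. Because intersections of unadjusted p <
0.05 calls have no analytic null, overlap sizes are validated by stratified
label permutation.

## Negative-binomial DE core

Counts are modeled as NB with variance μ + αμ² (α the dispersion, the
convention of mainstream RNA-seq tools). The core is deliberately simple —
downstream set logic consumes only p, adjusted p, and LFC sign/magnitude —
and makes no claim of numerical parity with DESeq2-class tools:

* **Normalization** — median-of-ratios size factors over genes with positive
  geometric means. The estimator is scale-free (a global rescaling of all
  columns leaves factors unchanged); scaling one of *n* columns by *c*
  scales its factor by c^((n−1)/n), i.e. by *c* relative to the others.
* **Dispersion** — per-gene method-of-moments on normalized counts,
  `max(0, (pooled within-group variance − μ̄)/μ̄²)`, pooled over all four
  groups (16 residual df at the design's scale). A mean–dispersion trend
  α(μ) = a0 + a1/μ is fit by iteratively reweighted least squares with
  weights 1/(α(μ) + 1/μ)², because the moment estimates' sampling sd scales
  with (α + 1/μ) and an unweighted fit is dominated by noisy low-mean genes
  (on simulation truth it overestimated a0 ~3× and underestimated a1 ~2×).
  The per-gene estimate is the **arithmetic** weighted average
  0.75·trend + 0.25·raw. An earlier log-space average was rejected: the raw
  moments are zero-truncated, so log averaging needs an arbitrary floor for
  zeros and its geometric mean is biased low, which measurably inflated null
  type-I error (~0.060 vs ~0.051 for the arithmetic form at the design's
  sample size). The strong trend weight reflects the very low residual df
  per gene.
* **Wald test** — group-mean LFC with a 1e-8 pseudo-mean floor; SE from the
  NB Fisher information at the fitted means, `log2(e)·sqrt((1/μ̂_t + α)/n_t +
  (1/μ̂_r + α)/n_r)`; two-sided normal p-values. Genes with all-zero counts
  across a contrast are flagged untested and excluded from the BH
  denominator. Direction for set classification always comes from the MLE
  LFC; shrunk LFCs (ridge posterior mean under a zero-centered normal prior,
  prior sd = 95th percentile of |LFC| when "auto") are for reporting and
  heatmaps only, so shrinkage can never flip or zero a gene's direction.

Measured calibration under the simulator's global null (12,000 genes, 4×5
samples): type-I error 0.049–0.054 across seeds at nominal 0.05; power ≥
0.99 for LFC = 2 at base mean 500, α = 0.01, n = 5/group.

## Permutation validation

The overlap statistic counts genes significant (unadjusted p < α) in both
relevant contrasts with the same nonzero LFC sign — identical to the
directional-intersection rule, so observed and null statistics are exactly
comparable. Labels of the validated factor are shuffled uniformly and
independently per iteration within the strata of the other factor (identity
allowed, repeats possible); an exhaustive mode enumerates all
C(10,5)² = 63,504 within-stratum assignments at the design's scale. The
empirical p-value is the add-one estimator (#{null ≥ observed}+1)/(N+1),
bounded below by 1/(N+1).

Every iteration re-estimates the per-gene dispersions under the permuted
grouping — a full DE re-run. This is not optional: a gene whose chance
between-group difference is large under one labeling has, conditional on the
data, a smaller within-group variance under that same labeling, so reusing
observed-grouping dispersions inflates the observed statistic relative to
the null (measured rejection 0.55 at nominal 0.05). The "fast" backend
reuses only the two-parameter global dispersion trend across iterations
(the trend cannot couple individual genes to the labels); the "full" backend
refits it each time. Measured null calibration (fast backend, 200 global-null
datasets, N = 99): rejection 0.075 at nominal 0.05, p-values near-uniform.

A structural property of this null at five samples per group: permutations
that align ≥ 4/5 of the labels in both strata (or both complements — sign
agreement survives a double flip) occur with ~2% probability and attenuate a
planted LFC only to ~0.56×. When planted effects are strong (|LFC| ≥ 1.5 at
base mean ≥ 200 with inbred-mouse-scale dispersion), such relabelings retain
essentially the whole overlap, so the null carries an atom within
false-positive noise of the observed statistic and the empirical p cannot
reliably reach its 1/(N+1) floor; it does remain ≪ 0.05. With weaker or
sparser signal (see the README example) the floor is reached.

## Synthetic data

The simulator emulates the motivating study's scale: four groups × 5
samples, ~12,000 expressed genes. Defaults: log-normal baseline means
(meanlog 4.0, sdlog 1.5 — median ≈ 55 counts with a realistic dynamic
range); dispersion trend α(μ) = 0.01 + 1/μ (asymptotic α = 0.01 matches the
canonical biological CV ≈ 10% for genetically identical mice, the 1/μ term
the shot-noise excess of weakly expressed genes); planted |LFC| uniform on
[1, 2] with random sign (reversal genes get opposing surgery/diet signs);
2% surgery-common, 5% diet-common, 1% reversal, 1% interaction-only genes;
mean-centered log-normal library-size factors (sdlog 0.1). The Sham-HFD
confound is exposed as a dial (`confound_shift`, a global log2 shift, plus
optional dispersion inflation) and defaults to 0 because no quantitative
magnitude is established; confounding experiments must set it explicitly.

What the simulator does **not** emulate: per-gene dispersion scatter around
the trend, gene-length/GC effects, count outliers, batch structure, or
correlated co-expression modules. Passing tests therefore demonstrate
correctness of the machinery and calibration under a well-specified NB
model, not robustness to real-data pathologies (DESeq2-class tools carry
outlier handling this core deliberately omits).

## Preprocessing

CPM uses raw column totals; the low-expression filter keeps genes with CPM ≥
threshold (inclusive) in ≥ k samples, computed against the library sizes of
the matrix it is handed (pass the parent totals to keep CPM stable across
filtering; the filter is idempotent either way since refiltering only raises
CPM). The noise/signal transition is estimated two ways, both documented
reconstructions with exposed knobs: (a) per-gene SNR (mean/sd of CPM),
smoothed by a local-mean smoother (span 0.3) along mean log2 CPM, reported
as the region where the smoothed curve crosses and stays within ±25% of the
threshold (default 2); (b) the valley of a Silverman-bandwidth KDE of pooled
log2(CPM + 0.25), reported as the contiguous region within 10% of the valley
minimum between the two largest modes. A unimodal pooled density raises a
degenerate-distribution error; if only the SNR curve fails to cross, the
density estimate is still returned.

## Enrichment post-processing

Signal is this package's own definition: sqrt(max(strength, 0) ·
min(−log₁₀FDR, 16)) — the geometric mean of effect size and capped
significance, monotone in both. Printed signal values from external tools
are accepted as inputs but never recomputed to match. Redundancy reduction:
average-linkage clustering on member-set Jaccard distance cut at 0.5, then a
within-cluster union-find merge of labels whose normalized token sets (lower
case, punctuation/stop words stripped, crude plural folding; stop-word list
versioned in `fourway.enrichment`) have Jaccard similarity ≥ 0.8.
Representatives maximize signal with ties broken by smaller FDR then term
id, which also makes clustering invariant to input order.

The iterative top-N selection is a reconstruction of an under-specified
procedure: bisection finds the smallest per-contrast rank fraction whose
top lists share ≥ N genes, then trims to exactly N by mean rank. (Stated as
"largest percentile", the procedure would be satisfied by the whole ranking
whenever the universe exceeds N; the smallest-fraction reading is the one
consistent with trimming.) The heatmap transform is log2(count/size-factor
+ 1) with row centering/unit-variance scaling (sd with n−1), Euclidean
complete-linkage row ordering, and the fixed column order ShamChow,
RYGBChow, ShamHFD, RYGBHFD. The ~27%-style coverage statistic divides by
the union of all supplied terms' members (a per-term average is the other
defensible reading).

## Problem sizes used by the test suite

Calibration tests run at the study's design scale (4×5 samples) with
12,000-gene global-null matrices, 200 permutation runs of N = 99, a
10,000-gene type-I check, 10-seed recovery at 4,000 genes, and N = 1,000
for the planted-signal permutation; the whole suite completes in under two
minutes on one core.

## Known limitations

* The Wald test uses a normal reference at n = 5 per group; measured type-I
  error is accurate at α = 0.05 but tail behavior below α ≈ 10⁻³ is
  untested.
* BH adjustment is computed over all tested genes of a contrast before any
  set subtraction; the alternative (adjust after exclusion) changes the
  RYGB-specific set slightly and is recorded in the provenance field.
* Reversal membership requires the obesity contrast itself to be significant
  (p < α), not merely opposite-signed.
* No Cook's-style outlier handling, no independent filtering of the BH
  denominator, no GLM designs beyond two-group contrasts.
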
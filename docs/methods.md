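# Methods

## Count model and normalization

Counts are modelled per gene as negative binomial with mean
`μ = N_eff · exp(xᵀβ)` and variance `μ + φμ²`, where `N_eff` is the
effective library size (raw library size × TMM factor) entering as an
offset, `x` the treatment-coded design for the two crossed factors with
interaction, and φ the dispersion. TMM factors use the standard doubly
trimmed weighted mean of M-values: trim fractions 0.30 on M and 0.05 on A,
precision weights from the asymptotic binomial variance, reference sample
chosen by upper-quartile closeness to the mean, and rescaling to unit
geometric mean. Log expression for PCA is `log2(CPM + 0.5)` on effective
library sizes; the constant prior keeps values finite, makes rows constant
when counts are proportional to effective sizes, and is invariant under
joint rescaling of counts and library sizes.

## Dispersion

The default dispersion is a single common φ maximizing the sum over genes
of the Cox–Reid adjusted profile likelihood
`ℓ_g(φ; β̂_g) − ½ log det(Xᵀ W X)` under the full model, optimized on the
log scale over [1e-6, 10]. A `"moderated"` mode maximizes, per gene,
`APL_g(φ) + w · mean_g' APL_g'(φ)` on a log-spaced grid (prior weight
w = 10) — a weighted-likelihood shrinkage toward the common value that is a
deliberate simplification of tagwise empirical-Bayes schemes. A fixed
scalar φ can be supplied for oracle tests.

## Tests

The interaction is tested per gene by a likelihood-ratio test of `~A*B`
against `~A+B`, referred to χ² with `(a−1)(b−1)` degrees of freedom; main
effects compare the additive model to single-factor models. Per-gene fits
use iteratively reweighted least squares vectorized across genes (shared
design matrix, batched normal equations, η clipped at ±50, convergence at
1e-10 on η). With 12 samples the χ² reference is known to be mildly liberal
(observed null rejection ≈ 0.055–0.065 at α = 0.05 in the package's own
calibration simulations); an F reference with residual degrees of freedom
overcorrects to ≈ 0.02–0.03, so the conventional χ² is kept. All-zero genes
are flagged untested and excluded from the FDR denominator; the explicit
mean-count rule is applied only in the DEG filter, after testing.

Pairwise comparisons use the conditional NB exact test: counts are scaled
to the geometric-mean effective library size, summed per group and rounded;
conditional on the total `t`, the group-1 sum follows a beta-binomial with
shape parameters `n_i/φ`, evaluated through the pmf-ratio recurrence (one
multiplication per support point), which stays accurate for arbitrarily
small φ where lgamma-difference formulas lose all precision. The two-sided
p-value sums the probabilities of outcomes no more likely than the observed
one (relative tie tolerance 1e-7, matching the usual exact-test
convention); as φ→0 with equal offsets this reproduces the conditional
binomial exact test, which the test suite checks exhaustively for totals
≤ 50. logFC is log2 of group pseudo-count means with a 0.5 prior, so a gene
that is zero everywhere reports p = 1, logFC = 0.

BH adjustment is the standard step-up (statsmodels); strict inequalities
are used throughout the DEG filter exactly as stated: `FC > 2`,
`FDR < 0.05`, both group means `> 2`.

## Differential profiles and consensus k

Profiles are built from genes with interaction FDR < 0.2 (at least two
required): entry = `logFC · (−ln p)` per pairwise contrast, each column
divided by its sample SD (ddof 1). Columns with zero SD are left unscaled
with a warning. Because any change of logarithm base rescales a column by a
constant, the SD-normalized matrix is invariant to the choice of bases;
this is asserted to 1e-10 in the tests.

For each k in an inclusive range (default 2..20), ten independent seeded
k-means runs are compared pairwise with the co-clustering distance
`d = 1 − ½(|P_A∩P_B|/|P_A| + |P_A∩P_B|/|P_B|)`, computed from the label
contingency table in O(n + K²). Identical partitions give d = 0 regardless
of label names; partitions sharing no co-clustered pair give d = 1. The
all-singleton edge case (possible only at k = n) is defined as d = 0 when
both runs are all-singleton and d = 1 otherwise, with a warning. The
selected k is the largest with mean pairwise distance strictly below the
tolerance (default 1e-5); when no k qualifies the selection is `None` and
the curve is still reported. The consensus labelling at the selected k is
the sweep run with minimal within-cluster sum of squares, ties broken
toward the earliest initialization.

k-means itself is Lloyd's algorithm (scikit-learn, `n_init=1`, `tol=0`,
cap 300 iterations) with a per-run seed derived stably from
`SeedSequence([base_seed, k, init_index])`. Initialization is k-means++ by
default. Plain random-row initialization is available (`init="random"`),
but it makes the reproducibility statistic nearly useless on well-separated
data: the probability that k random rows cover all G planted clusters is
G!/G^G (≈ 9% at G = 4), Lloyd cannot migrate centroids across widely
separated clusters, so the ten runs land in differing local optima and no k
passes the 1e-5 rule. k-means++ concentrates initial centroids on distinct
clusters, making each run find the same optimum whenever the structure is
real — which is precisely what the reproducibility criterion is meant to
detect. This choice is the package's own; it preserves the "ten random
initializations" semantics since k-means++ seeding is itself random.

## Assay quantification

Array: level = mean of the duplicate spots minus the mean negative-control
density, clamped at zero (densities cannot support negative abundance;
clamping is the one deliberate nonlinearity and is exercised by tests).
Group comparison uses the pooled-variance Student's t by default because
that is the named test; Welch is behind a flag. Fold-change of a
zero-control analyte is reported as infinity with an `undefined` flag
reserved for 0/0.

qPCR: ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the
calibrator group's *mean* ΔCt (per-sample, so an SEM is defined); relative
expression is 2^−ΔΔCt, summarised per group as mean ± SEM. Noise-free
round-trips through the simulator recover planted ratios to 1e-12.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
any particular dataset: per-gene NB counts with log-uniform baselines
(default e^μ between 5 and 500), log-uniform library sizes (0.8–1.2 M,
which exercises TMM nontrivially), a scalar or gamma-distributed φ (default
0.1, a typical cell-line value), and planted effects: a configurable
fraction of null genes (default 0.7) and the rest assigned to G clusters
whose log2-effect templates are distinct sign/axis patterns of magnitude 2
on the (main A, main B, interaction) coefficients. Ground truth (labels,
per-contrast log2FC, dispersions, library sizes) is returned alongside.
Per-gene draws use deterministic SeedSequence sub-streams, so results do
not depend on gene order. Profile fixtures place G centroids at
±separation on distinct axes (at most 2 × n_contrasts representable) plus
isotropic noise. Spot panels add background and Gaussian noise to planted
levels, with background-only negative-control rows; Ct tables shift the
target Ct by −log2(relative expression) around a reference-implied value.

What the simulations do *not* capture: gene–gene correlation, trended
mean–dispersion relationships, outlier samples, composition shifts beyond
what random library sizes induce, and array saturation. Passing tests
therefore certify the statistics and their implementation, not performance
on any real dataset.

## Problem sizes and determinism

Calibration simulations use 1000 genes × 12 samples; recovery sweeps use
200-gene profile sets over k ∈ [2, 8] with 10 initializations and 25–50
replicate seeds — sizes at which every Monte-Carlo check is stable yet the
whole suite runs in well under a minute per property. Every stochastic
stage takes an explicit seed; the pipeline driver fans a single run seed
out to stages via sha256, records all seeds in the manifest, and reruns
with identical configuration produce byte-identical outputs (checksummed).

## Known limitations

- The common-dispersion default understates per-gene dispersion
  heterogeneity; the moderated mode is a coarse grid-based shrinkage, not a
  full empirical-Bayes treatment.
- The χ² LRT reference is mildly liberal at three replicates per cell (see
  above); quasi-likelihood F-tests are deliberately out of scope.
- The exact test rounds library-size-equalized sums to integers rather than
  interpolating quantiles.
- The reproducibility rule's 1e-5 threshold demands *exact* agreement of
  k-means runs; on noisy profiles it frequently selects a small k or none.
  That strictness is inherent to the statistic, not a defect of the
  implementation.
- Interaction logFC for designs with more than 2×2 levels reports the first
  interaction coefficient only (the LRT uses all of them).
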
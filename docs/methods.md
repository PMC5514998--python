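# Methods

## The comparative model

The package treats the tissues of one organism the way comparative
biology treats species: tissue mean expression profiles are not
independent observations, because related cell types share expression by
descent from common progenitor states. The hierarchical structure is
summarized by a tissue tree built from the expression data itself, and
every downstream test accounts for it.

For one gene, let `y` be the vector of per-tissue mean log2 expression
and `x` the vector of log10 cellular turnover (days). The regression

    y = b0 + b1 * x + eps,   eps ~ N(0, sigma^2 * V(theta))

is fitted by generalized least squares (PGLS), where `V` is one of three
evolutionary covariance structures on the tree:

* **BM** (Brownian motion): `V[i, j] = C[i, j]`, the shared root-to-MRCA
  path length. Variance grows with depth; covariance with shared history.
* **Pagel's lambda**: off-diagonal entries of `C` scaled by
  `lambda in [0, 1]`. `lambda = 0` is tip independence, `lambda = 1` pure
  BM; intermediate values attenuate the phylogenetic signal.
* **Stationary Ornstein-Uhlenbeck**: `V[i, j] = exp(-alpha * d[i, j])`
  with `d` the patristic distance and unit diagonal (the stationary
  variance `sigma^2 / 2 alpha` is absorbed into `sigma^2`). Valid on
  non-ultrametric trees; `alpha` is bounded to
  `[1e-4, 50 / mean root-to-tip depth]` for identifiability.

`sigma^2` is profiled out by maximum likelihood (`rss_gls / n`); the
scalar model parameter is maximized by bounded Brent search (bracket
tolerance 1e-7, both interval endpoints always evaluated so boundary
optima such as `lambda = 1` are exact). Standard errors use the unbiased
`rss_gls / (n - 2)`; the slope is tested two-sided on the t distribution
with `n - 2` degrees of freedom. All solves go through a Cholesky factor
of `V` (never an explicit inverse), with a one-shot diagonal jitter of
`1e-8 * mean(diag)` if factorization fails.

## Covariance selection is decoupled from the slope test

Models are compared by AIC (`2k - 2 logL`, `k` counting regression
coefficients, `sigma^2` and the covariance parameter); AIC rather than
raw likelihood because BM is nested inside the lambda family.

A critical design point: in the genome-wide scan, the covariance model
for each gene is selected from the gene's *marginal* distribution — an
intercept-only ML fit — and only then is the slope tested by GLS under
the selected covariance (`models.select_covariance`). Selecting on the
regression likelihood instead couples model choice to the very
hypothesis being tested: a null gene whose chance alignment with the
(tree-structured) trait is best "explained" under a near-independence
covariance (OU at the upper `alpha` bound, or `lambda = 0`) gets both
selected and tested under that covariance, which is the classic
spurious-regression failure of OLS between two autocorrelated variables.
On null simulations (2,000 genes, 21 tissues, no planted signal) the
coupled procedure produced a mean false-discovery proportion of ~0.85 at
q <= 0.05; the decoupled procedure is calibrated (fraction of p < 0.01
is ~0.010) and yields zero null discoveries in the same simulations.
The coupled fit remains available as `fit_model` + `select_model` for
parameter-recovery work.

The per-gene p-values are plug-in values: the uncertainty of the
selected `lambda`/`alpha` is not propagated, which leaves a mild
anticonservative tail (~1.2% of null p-values below 0.01 instead of 1%)
that the q-value step absorbs in practice. Exact uniformity holds when
the fitted family matches the generating process (BM scanned under BM),
and the test suite checks calibration in that regime.

## Multiplicity

Storey q-values: `pi0 = min(1, #{p > 0.5} / (0.5 m))`, step-up
`q_(i) = min_{j >= i} pi0 * m * p_(j) / j`. If the `pi0` estimate
degenerates to zero the procedure falls back to Benjamini-Hochberg
(`pi0 = 1`). Untestable (constant-expression) genes carry NaN p-values
and are excluded from the FDR universe; p-values are clamped below at
1e-300 to avoid underflow. Default significance cutoff q <= 0.05.

## The tissue tree

Distances between tissues are `1 - Pearson` correlation of mean log
expression across genes (Spearman by option). The tree is built by
neighbor joining (Studier-Keppler Q criterion) with two deterministic
conventions: among equal-minimum Q values the lexicographically smallest
taxon-label pair is joined (platform-independent output), and negative
branch-length estimates are clamped to zero with the deficit transferred
to the sibling edge so the pair's path length is preserved
(Kuhner-Felsenstein). NJ reconstructs any additive distance matrix
exactly — the module's primary test oracle. The unrooted NJ tree is
midpoint-rooted, since the covariance structures need a root; bootstrap
supports come from resampling genes with replacement and counting
recovered unrooted bipartitions (default 1,000 replicates, giving ~0.01
Monte-Carlo error on supports).

## Phylogenetic ANOVA

Group-vs-rest differential expression uses the observed one-way F
statistic on tissue means, with the null distribution generated by
simulating the gene under BM on the tree (rate estimated per gene by
intercept-only ML) and recomputing F per simulation:
`p = (1 + #{F_sim >= F_obs}) / (1 + n_sim)`, `n_sim = 999` by default
(p resolution 0.001). On a star tree this reduces to the classical
F-test, which the tests verify. A parametric alternative (`method="gls"`,
a group indicator tested by GLS under BM covariance) is provided.
Constant genes are assigned F = 0, p = 1.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Tree**: a time-calibrated pure-birth (Yule) tree — exponential
  waiting times, unit birth rate — whose terminal edges are jittered by a
  multiplicative lognormal factor (sd 0.15), then rescaled to mean
  root-to-tip depth 1. The jitter makes trees mildly non-ultrametric, as
  empirical NJ expression trees are, while keeping tip depths in a
  modest band (~0.9-1.2) so every tissue carries comparable phylogenetic
  variance — which is what keeps simulated replicate correlations in the
  range reported for real biological replicates (see below).
* **Trait**: one BM realization at the tips, linearly rescaled to span
  log10(2) to log10(32850) — the 2-day (monocyte) to 32,850-day (neuron)
  human turnover range. It is mean-centred before entering the signal
  term so the baseline stays the intercept.
* **Expression**: each null gene is one draw from
  `MVN(baseline_mean, sigma2 * V(tree))`; each signal gene adds
  `beta * x` with `|beta|` uniform in `slope_range` and random sign.
  Defaults: 21 tissues, 2,000 genes, `sigma2 = 0.25` and baseline 6 on
  the log2 scale (typical expressed-gene magnitudes), model BM.
* **Replicates**: each tissue column is expanded into `n_replicates`
  samples (default 3, mirroring the ~153 samples / 21 tissues of the
  real compendium) plus i.i.d. N(0, 0.1^2) log-scale noise. At these
  defaults the within-tissue Pearson correlation is
  `sigma2 * depth / (sigma2 * depth + 0.01)` ~ 0.95, comfortably above
  the 0.90 reproducibility bar reported for real replicates.

What the generator does *not* emulate: count overdispersion and
library-size effects (values are generated directly on the normalized
log scale), tissue-specific noise levels, correlated gene modules
beyond the tree structure, and any misspecification of the tree used by
the scan (the scan sees the true simulated tree in the acceptance runs).
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness of the biology.

## Preprocessing

Raw counts are normalized as counts-per-million followed by
`log2(x + 1)`; pre-normalized matrices bypass this. Replicate QC reports
the minimum within-tissue pairwise Pearson correlation (threshold 0.90;
single-sample tissues are flagged, not failed). Gene filtering keeps
genes strictly above `min_expr` in at least `min_frac_tissues` of
tissues, computed on tissue means. The packaged turnover table ships the
21 human tissues with germ layer and turnover in days; the trait is
log10-transformed by default because turnover spans four orders of
magnitude and a linear-scale regression would be dominated by the two
longest-lived tissues.

## Problem sizes and determinism

Simulation-based checks use 2,000 genes x 21 tissues for scan-level
properties (FDR over 20 seeds, replicate QC), 400-600 genes for
ANOVA-level properties, and 50-60 replicate genes for parameter
recovery — sizes at which the Monte-Carlo error of each assertion is
small relative to its tolerance. Every stochastic component takes an
explicit seed (numpy `default_rng`), stage sub-seeds are derived by
fixed offsets, and a pipeline re-run under one config reproduces every
output file bit-identically (floats are written as `%.17g` and read back
with round-trip parsing).

## Known limitations

* Plug-in p-values (no propagation of covariance-parameter uncertainty);
  mild tail anticonservativeness quantified above.
* The lambda/OU/BM families are weakly identifiable at n = 21 tissues,
  and essentially unidentifiable on near-ultrametric trees (OU mimics
  BM); "selected model" labels should be read accordingly.
* The leave-tissues-out robustness run rebuilds the tree on the reduced
  tissue set (a full pipeline re-run); pruning the original tree is
  available but not the default.
* Measurement-error ("lambda + error") models, REML, and multi-optimum
  OU are out of scope.
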
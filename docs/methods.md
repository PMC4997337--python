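# Methods

`microgrove` re-creates, as a tested library, the statistical workflow of a
birth-cohort 16S gut-microbiome study: equal-depth resampling of an OTU
count table, alpha/beta diversity, single- and multi-factor PERMANOVA with
covariate selection, per-taxon zero-inflated negative-binomial (ZINB)
differential abundance, covariate-overlap networks, and latent-class
profiling of maternal factors. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
cohort generator does and does not emulate.

## Representative rarefaction

A single rarefaction is a multivariate-hypergeometric subsample (without
replacement) of one sample's counts to a fixed depth, so each taxon's
marginal expectation is `depth * count / total`. Because one draw can be an
outlier when rare taxa dominate, `n_draws` vectors are drawn per sample
(default 100) and the retained vector is the one minimizing the mean
Euclidean distance to the other draws. Decisions the procedure leaves open
and how we fixed them:

* distances are computed on raw rarefied **counts** (all draws share one
  depth, so proportions would only rescale every distance by the same
  constant — the argmin is unchanged);
* ties in mean distance (e.g. identical draws when the total equals the
  depth) resolve to the lowest draw index, making results reproducible;
* samples whose totals fall below the depth are dropped with a warning, not
  scaled up.

The default depth (202,367 reads) is the cohort minimum of the motivating
study; synthetic runs rarefy to the simulated cohort minimum instead.

## Diversity measures and tests

Richness is the count of taxa present; Pielou's evenness is Shannon entropy
(natural log) over `ln(richness)`, undefined (NaN) for single-taxon
communities; Faith's PD is the branch length of the union of root-to-tip
paths of observed taxa. A root edge with positive length is treated as
ancestral to every tip (this matches the widely used implementations; it
never affects unweighted UniFrac toy values because such a branch is shared
whenever both communities are non-empty).

Association tests follow the declared factor kind: exact-capable
Wilcoxon rank-sum for binary factors, Kruskal-Wallis for three or more
levels, Spearman (midranks, two-sided) for continuous. Missing values are
omitted pairwise; a factor constant after omission is reported untestable
rather than dropped silently.

Per-family richness-vs-age trends use a log-link count regression of
within-sample family richness on age in months, reported as
`100*(exp(beta)-1)` percent change per month. The regression family is
negative binomial (counts plausibly overdispersed) with a Poisson GLM
fallback when dispersion estimation fails; families that fail both are
flagged and excluded from the BH family.

## UniFrac and PERMANOVA

Unweighted UniFrac is unique branch length over union branch length of the
two presence sets; weighted UniFrac is the branch-length-weighted L1
distance between per-branch relative-abundance totals, reported raw
(non-normalized) by default with a normalization switch. Both are computed
from a cached edge-by-tip incidence matrix, so whole-cohort distance
matrices are a few dense matrix products.

PERMANOVA uses the Gower decomposition `G = -1/2 J D^2 J`; the SS explained
by a design is `tr(HG)` with `H` the hat projection, and
`pseudo-F = (SS_f/df_f)/(SS_res/df_res)`. Single-factor tests drop samples
with missing values and permute sample identities, with
`p = (1 + #{F* >= F}) / (1 + n_perm)` (the +1 keeps p away from 0); an
exhaustive mode enumerates all distinct relabellings for exact small-sample
tests. Marginal (type III) tests compute each term's SS as the drop in
explained SS when the term leaves the full model, and permute the distance
matrix rows/columns simultaneously — the default behaviour of the
implementation the study used; residual permutation is a known alternative
and is deliberately not implemented. Model fit is reported as R² and the
Ezekiel adjustment `1 - (1-R²)(n-1)/(n-m-1)` with `m` the model degrees of
freedom.

Missing data in multi-factor models: continuous factors are mean-imputed,
categorical factors gain an explicit `missing` level (all levels contribute
indicator columns). Repeated measurements of one construct are collapsed
before selection with pairwise VIFs (`1/(1-R²)`, threshold 2.5): two
redundant measurements keep the one closest to stool collection; three keep
the two furthest apart, re-check, and fall back to the closest-to-stool
one. For categorical members the R² uses indicator codings and both
regression directions, taking the larger VIF (the conservative reading of
"indicator contrasts"). Groups with more than three members raise — the
rules are defined for at most three. Timepoints order as pregnancy (-4.5
months relative to birth), delivery (0), neonatal visit (1), infant visit
(6).

Backward elimination drops one term per iteration — the largest marginal p,
ties broken by smaller marginal SS — until every term has p below alpha.
An empty final model is a legitimate outcome. Final-model column-wise VIFs
are computed and logged as a stability check.

## Differential abundance

Each taxon (after removing taxa with under 5 total reads) is fitted with a
ZINB: intercept-only inflation, the covariate entering the count mean only
(`log mu = b0 + b1 x`) — the simplest model consistent with the study's
description. Significance is the two-sided Wald test of `b1`; direction is
`sign(b1)`. No depth offset is used because inputs are rarefied to equal
depth. The fit falls back to a plain negative binomial when the ZINB
optimizer does not converge, yields non-finite standard errors, or pushes
the inflation probability onto its boundary (within 1e-6); the fallback is
recorded per taxon. Multi-category covariates are first reduced by fixed
rules (income >= $80k, education >= bachelor's, married indicator, African
American vs other, any indoor pets). BH adjustment runs across tested taxa
only. Genus summaries rank genera with at least 5 significant taxa by
direction consistency (`max(n_up, n_down)/n_sig`), then count, then name —
the lexical tie-break is ours, for determinism.

## Factor networks

The overlap of two factors is the Jaccard proportion of their significant
taxon sets (`|A∩B|/|A∪B|`, 0 for an empty union). We read the ambiguous
phrase "overlapping significant OTUs among all significant OTUs between the
two factors" as the union: it is symmetric, bounded in [0,1], and yields a
single number per pair; the sum-of-sizes alternative is noted and easy to
swap in. The 80th-percentile adjacency threshold is rank-based — exactly
`ceil(0.2 * n_pairs)` edges when overlaps are distinct, ties included — so
the statement "20% of all possible connections" holds exactly in the
no-ties case, which interpolation-based percentiles would break. Edge
correlations dispatch on declared kinds: Pearson, point-biserial, or phi
(chi-square p with 1 df, no continuity correction, matching the textbook
phi formula).

## Latent class analysis

K-class mixture over J categorical items, fitted by EM from random
Dirichlet starts (default 20; the study does not report its start
strategy), tolerance 1e-7 on the log-likelihood, class labels canonicalized
by descending prevalence. `n_params = (K-1) + K * sum_j (L_j - 1)`;
`aBIC = -2 loglik + n_params * ln((n+2)/24)`. Model choice: parametric
bootstrap LRT of K vs K+1 (`p = (1 + #{boot >= obs}) / (1 + B)`), choosing
the smallest K whose test is non-significant, alongside the aBIC minimizer.
"Significant" is `p <= alpha`: at the bootstrap resolution floor
`1/(B+1)` — exactly 0.05 at the default B=19 — a floor p must still count
as a rejection or the procedure has no power at alpha = 0.05. Inside the
bootstrap test, the observed and bootstrap models are fitted with an
identical protocol (same starts, same tolerance, default 1e-4): optimizing
the observed fit harder than the replicates biases the observed LRT upward
relative to its bootstrap reference and inflates rejection. The LRT
differences that matter are orders of magnitude larger than the tolerance.

Rows with any missing item are dropped before fitting (complete-case).
Measurement invariance across a binary grouping compares shared-rho /
free-pi against fully group-specific models with a chi-square LRT,
`df = (G-1) * K * sum_j (L_j - 1)`. Profile assignment is
maximum-posterior, ties to the lowest class index; per-class mean maximum
posteriors quantify classification error. The profiles' added value in the
composition model is the marginal-PERMANOVA increment `delta R^2` of the
class term added to the final multi-factor model.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, at desk scale by
default (300 samples in two age strata, 400 taxa in 25 families, 24
covariates, three latent classes):

* ages uniform in each stratum's observed range (0.5–4.6 and 5.6–10.6
  months);
* three latent maternal classes (prevalences 0.48/0.38/0.14) drive six
  categorical items with the observed-cohort item-response pattern, and
  shift the continuous covariates slightly;
* repeated measurements (BMI at two timepoints; smoke exposure in pregnancy
  and at the neonatal visit) hit a target correlation (default 0.7) via a
  shared latent draw (continuous) or probabilistic copying (binary);
* counts are gamma-Poisson (NB, dispersion theta = 2) gated by structural
  zeros, with factor effects entering the log mean on designated taxon
  blocks; the age trend enters the structural-zero probability so expected
  family richness is exactly multiplicative in age — this keeps the
  trend-recovery tests well-posed;
* per-sample library depth is drawn lognormal and counts multinomially
  resampled to it (switchable off for tests that need the raw ZINB layer).

What it does **not** emulate: read-level error, chimeras, compositional
coupling between taxa beyond the shared depth, phylogenetic signal in
effect placement (effect blocks are contiguous tip blocks, which are
clade-like but not exact clades), or item missingness patterns. Passing
recovery tests therefore demonstrates correctness of the estimators under
the assumed models, not robustness to real-data violations of them.

## Problem sizes used in the automated checks

Calibration suites use 500 null replicates (PERMANOVA at 30 samples, 199
permutations; ZINB Wald at n=300) and 60 bootstrap-LRT null replicates at
n=200 with B=19. Recovery suites use n=2000 for the ZINB slope, n=1000 for
LCA parameters, 12 cohort-scale (n=1258) replicates for class-count
selection, n=300 for the family trend, and 40 replicates for
backward-elimination retention. These sizes are the package's own
desk-scale choices; the generator's distributional settings are fixed
independently of them.

## Known limitations

* The marginal-test permutation scheme (raw distance shuffling) is one of
  several defensible choices; reduced-model residual permutation can differ
  in small samples.
* The ZINB inflation component is intercept-only; covariate-dependent
  inflation is not modelled.
* Pairwise class comparisons in profile reports use complete cases per
  item, so denominators vary across items.
* The exhaustive PERMANOVA mode enumerates label rearrangements and is
  only practical below ~10 samples.
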
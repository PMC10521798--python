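# Methods

This note documents the statistical procedures implemented in `plaquenet`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Count model and preprocessing

Bulk libraries tag transcript molecules with one of B = 4096 unique
molecular identifier (UMI) barcodes. With `t` true molecules of a gene the
expected number of *distinct* barcodes observed is `B(1 − e^(−t/B))`, so the
raw barcode count `r` saturates as expression grows. Inverting gives the
correction applied to every entry:

    corrected = −B · ln(1 − r/B)

which is strictly increasing and convex, equals 0 iff `r = 0`, and is
undefined at `r ≥ B` (raised as an error — a physical impossibility under
the sampling model). The generator's forward map rounds to integer counts;
the round trip therefore recovers true counts only up to the rounding
half-step propagated through the correction's slope `B/(B − r)`. Because the
slope is increasing in `r`, the bound must be evaluated across the rounding
interval: the tests use `|error| ≤ 0.5 · B/(B − r − 1/2)`.

Quality control keeps samples with ≥ 10 000 detected genes (count > 0) and
≥ 18 000 total reads (both inclusive at the boundary), and genes with mean
count strictly above 1 per sample. Sample filtering uses the raw counts
(library-level properties), gene filtering the corrected counts; order is
correction → sample filter → gene filter → normalization. Depth
normalization scales every sample to the **median** sample depth (the target
is arbitrary up to a constant; the median is scale-stable), followed by
`log(1 + x)` in natural base (downstream correlations are base-invariant).

## Signed network

Similarity is the biweight midcorrelation: deviations from the median are
scaled by 9·MAD (raw median absolute deviation, no Gaussian consistency
constant — the canonical biweight tuning), weighted by Tukey biweights
`w = (1 − u²)² · 1{|u| < 1}`, and the weighted deviations are correlated.
When a vector's MAD is zero the biweight is undefined and the pair falls
back to the Pearson correlation (logged). The implementation is vectorised
(the transform is per-vector), with fallback rows overwritten by Pearson
values at the pair level. Missing values are rejected upstream; there is no
pairwise-complete handling.

Signed adjacency `a_ij = ((1 + cor)/2)^β` maps anticorrelation to ~0 rather
than folding it onto positive correlation. Increasing β weakly decreases
every off-diagonal entry.

### Soft-threshold selection

For each power on the grid (default 2..30) the whole-network connectivity
`k_i = Σ_{j≠i} a_ij` is computed and a scale-free fit index derived.
Connectivities are grouped into **10 equal-occupancy (quantile) bins**; the
empirical density of each bin — occupancy divided by (total count × bin
width) — is regressed on the bin's mean connectivity on log10–log10 scale,
and R² is reported only when the slope is negative (a flat or increasing
degree distribution is not scale-free, so its fit counts as 0). Density
rather than raw occupancy is regressed because with equal-occupancy bins the
occupancy is constant by construction and carries no information; the
density is the quantity whose power-law decay defines scale-free topology.
The chosen power is the lowest grid power with R² ≥ 0.8 and median
connectivity < 100; if none complies the selection raises (near-independent
data has no scale-free regime) rather than silently falling back.

### Topological overlap and module detection

TOM is computed with the diagonal zeroed inside the sums and the result's
diagonal set to 1; entries are clipped to [0, 1] and symmetrized against
floating-point drift. Correctness is pinned by a triple-loop brute-force
oracle on random instances up to 12 nodes at 1e−12.

Modules come from average-linkage hierarchical clustering of `1 − TOM`.
The tree cut is adaptive rather than a fixed-height cut: merge heights are
sorted, gaps within 25 % of the largest gap qualify as candidate cut
points, and the `deep_split` sensitivity (0–4, default 3) selects among
them from the highest qualifying gap (coarse, few large clusters) to the
lowest (fine, many small clusters). In the planted-structure regime there
is one dominant gap — between within-module merges and the
background/between-module merges — and every sensitivity cuts there.
Clusters below `min_cluster_size` (default 20) fall into the grey bin,
excluded from all downstream statistics. An optional PAM-like step
reassigns grey genes to the module with the highest mean TOM when that
affinity reaches half the module's internal mean TOM; it is off by default
because planted-recovery evaluation counts forced assignments of background
genes as errors. This cutter is deliberately *not* a re-implementation of
any particular dynamic tree-cut heuristic; its contract is planted-partition
recovery (adjusted Rand index ≥ 0.8 on the default design), which it meets
with ARI = 1.0 on 10/10 seeds. Modules are named by descending size from
the conventional color vocabulary, with ties broken by the smallest member
gene so the partition is invariant to gene order.

Eigengenes are the first right singular vector of the per-gene standardized
module expression, returned with zero mean and unit variance and
sign-oriented so the mean correlation with the module's genes is
nonnegative; variance explained is `s₁²/Σsᵢ²`. Constant genes are dropped
from the decomposition. Trait association is Pearson r with the Student
asymptotic two-sided p on `n − 2` degrees of freedom.

## Stratified connectivity and the bias test

Network activity per stratum is intramodular connectivity computed on the
**module-restricted** adjacency (each stratum's own correlation of the
module's genes, at the shared β) — not genome-wide connectivity. The bias
test is the two-sided **unpaired** Student t test over the two per-gene
connectivity sets (a paired option is exposed; the two differ little since
the gene lists are identical), with the biased flag requiring significance
*and* higher mean connectivity in the focal stratum. A
Benjamini–Hochberg-adjusted column is emitted for transparency but the flag
uses the per-module p, matching the per-module reporting convention.

**Known property — anti-conservativeness.** All genes' connectivities
within one stratum share that stratum's realized factor and correlation
fluctuations, so the per-gene dispersion used by the t test underestimates
the variance of the difference in means and the test rejects too often
under the null (empirically ~0.13–0.40 false-flag rate at nominal α = 0.05
depending on β, module size and sample size, versus ~0.025 expected). A
paired test inherits the same defect because the shared fluctuation shifts
all paired differences together. The test is provided as specified because
it is the field's reporting convention for stratified connectivity plots;
per-module bias p-values should be read as descriptive strength-of-contrast
measures, not calibrated error rates. The power side is excellent: the
planted 1.5× loading contrast is flagged in 10/10 seeds.

## Directed networks and key drivers

Within a module, a directed acyclic graph is obtained by a greedy
score-based search over DAGs: the local score of a node given its parents
is the Gaussian log-likelihood with BIC penalty `(log n)/2` per free
parameter (`|parents| + 1`); the forward phase repeatedly adds the
acyclicity- and degree-respecting edge (per-node cap 100) with the largest
positive score gain, then the backward phase deletes edges while the score
improves. Per-target delta caching makes the search O(edges) per step. The
search is validated by exhaustive-DAG score equivalence on 2- and 3-node
problems and by chain/noise structure recovery — not by clone-identity to
any equivalence-class search implementation. Any undirected ambiguity is
resolved deterministically; key-driver analysis uses undirected
neighborhoods (default depth 1), so orientation cannot affect it.

A candidate's observed statistic is the hypergeometric upper-tail
enrichment (−log10 p) of module genes among its neighbors; the null
permutes module-membership labels over the gene universe with the topology
fixed; `p = (1 + #{null ≥ observed})/(n_permutations + 1)`. At the default
20 permutations the p floor is 1/21 ≈ 0.048, which makes the
Benjamini–Hochberg FDR resolution coarse (logged as a warning); the
permutation count is configurable upward. Rankings sort by FDR, then
statistic descending, then gene name, and are bit-reproducible given the
seed.

## Prioritization

Overlap with a reference set and GWAS-locus enrichment both use the
one-sided hypergeometric upper tail `P(X ≥ k)` with the universe equal to
the genes that entered network construction (overridable). Locus gene sets
come from interval overlap of BED-like loci (0-based half-open) with a gene
coordinate table in the same convention. The criteria thresholds (bias,
overlap, GWAS each at α = 0.05 by default) are configuration, not
constants. Criteria met map deterministically to tiers: 0 none, 1 yellow,
2 orange, 3 red.

## Single-cell module scores

Genes are placed in 24 equal-occupancy bins by mean expression across
cells; for each set gene 100 control genes are drawn from its bin (without
replacement when the bin allows, with replacement and a log message
otherwise); the per-cell score is mean set expression minus mean pooled
control expression. The score is location-invariant, zero on uniform
matrices, and invariant to gene/cell order (ties and sampling pools are
canonicalized by gene name). Input normalization is the caller's
responsibility; scores are comparable only within one normalization.

## Histological vulnerability score

Four binary indicators — moderate/heavy macrophages, no/minor collagen,
no/minor SMCs, fat ≥ 10 % (inclusive) — are summed to 0 (most stable) … 4
(most vulnerable). Category strings are whitelisted case-insensitively;
free text is rejected.

## Synthetic data: what it emulates and what it does not

Each module has one latent factor per sample; gene `g` with loading `λ_g`
is `λ_g f + sqrt(1 − λ_g²) ε`, so genes have unit variance and module pairs
have population correlation `λ_i λ_j` — closed-form truth for every
recovery test. Defaults mirror the matched two-sex cohort at round numbers:
150 samples per stratum, 5 modules × 60 genes on 300 background genes, base
loading 0.6, one hub per module at loading 0.9, and a 1.5× stratum-A
loading multiplier (clipped at 1, with a warning) as the planted sex
effect. Per-gene loadings are scattered uniformly ±0.15 around the base
because real modules have heterogeneous membership strength; that
heterogeneity is also what gives the connectivity distribution the heavy
tail that the scale-free criterion detects (with constant loadings the
distribution is bimodal and no power complies). Tests that need the exact
closed form set the spread to ~0.

Also provided: the exact inverse UMI saturation map; traits
`r·z(f) + sqrt(1 − r²)·noise` with exact population correlation `r`;
linear-Gaussian structural-equation data from user DAGs (unit noise,
topological evaluation); and negative-binomial single-cell counts
(dispersion φ = 0.5, variance `μ + φμ²`) where cell-type programs multiply
module-gene means.

Not emulated: batch effects, library-size heterogeneity beyond NB noise,
ambient RNA, non-Gaussian bulk expression, overlapping modules,
between-module correlation, and realistic gene-gene causal structure inside
factor modules. Passing recovery tests therefore demonstrates correctness
of the algorithms under the factor model, not performance on real tissue.

## Problem sizes and numerical choices

Recovery and calibration tests run at the default design (600 genes × 150
samples per stratum, 10–200 replicates), chosen as the scale at which the
planted effects are unambiguous while the full suite completes in well
under a minute; oracle-equality tests use ≤ 12-node matrices (TOM), ≤ 60
observations (bicor) and ≤ 25-gene universes (hypergeometric enumeration),
exhaustively where enumeration is feasible. Tolerances: 1e−12 for algebraic
oracle equality, 1e−10 for decomposition equality up to sign; symmetric
matrices are symmetrized after floating-point operations and correlations
clipped to [−1, 1]. Degenerate inputs (zero-MAD genes, constant traits,
empty graphs, all-grey partitions) raise or warn explicitly rather than
propagating NaNs; every stochastic routine takes an explicit seed and is
reproducible bit-for-bit.
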
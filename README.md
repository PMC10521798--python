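# plaquenet

Sex-stratified weighted gene-coexpression network analysis of atherosclerotic
plaque transcriptomes: count correction and quality filtering, signed network
and module inference, stratified-connectivity ("network activity")
comparison between sexes, permutation key-driver analysis, three-criterion
module prioritization, single-cell module scoring, and histological plaque
vulnerability scoring — with a synthetic-data module that plants known
modules, hubs and sex effects so every stage can be validated against ground
truth.

## Who this is for

Researchers analysing bulk RNA-seq from diseased vascular tissue (or any
two-stratum cohort) who want to ask: *which coexpression modules are more
tightly wired in one stratum than the other, which genes drive them, and do
those modules map onto disease-relevant gene sets, GWAS loci and tissue
phenotypes?*

## The model

**Network.** Pairwise gene similarity is the biweight midcorrelation
(bicor), a median/MAD-based robust correlation. The signed adjacency is

    a_ij = ((1 + bicor_ij) / 2) ** beta

with the soft power `beta` chosen as the smallest integer in 2..30 whose
connectivity distribution fits scale-free topology with R² ≥ 0.8 while the
median connectivity stays below 100. Adjacency is smoothed into the
topological overlap matrix (TOM),

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),   l_ij = Σ_u a_iu a_uj,

and modules are detected by average-linkage clustering of `1 − TOM` with an
adaptive tree cut (deepSplit 3, minimum module size 20). Unassigned genes go
to the grey bin, which is excluded from all downstream statistics. Each
module is summarized by its eigengene (first principal component over
samples), which can be correlated with clinical traits (Pearson r, Student
asymptotic p).

**Sex bias.** A module's activity per stratum is its genes' intramodular
connectivity `kIM_i = Σ_{j∈module} a_ij`, computed from each stratum's own
expression at the shared `beta`; a two-sided unpaired Student t test
compares the paired connectivity sets and the module is flagged biased when
the focal stratum is significantly higher.

**Key drivers.** Within each module, a greedy BIC-scored search (forward
edge additions, backward deletions, per-node degree cap 100) orients a
directed acyclic graph; a key driver is a node whose network neighborhood is
enriched for module genes, with significance from label permutations
(default 20, p floor 1/21) and Benjamini–Hochberg FDR < 0.1.

**Prioritization.** Modules earn one point each for sex bias, significant
hypergeometric overlap with a reference gene set, and enrichment for genes
in GWAS loci; 1/2/3 points map to yellow/orange/red tiers.

**Histology.** Plaques are scored 0–4 by summing four binary vulnerability
indicators: moderate/heavy macrophages, no/minor collagen, no/minor smooth
muscle cells, and fat content ≥ 10 %.

## Worked example

```python
from plaquenet import (CoexpressionNetwork, SimulationDesign,
                       generate_two_strata_expression)
from plaquenet.diffconn import StratifiedConnectivityTest

# two strata of 150 samples, 5 planted modules of 60 genes + 300 background;
# stratum A (the focal stratum) has 1.5x stronger module loadings
expr_f, expr_m, truth = generate_two_strata_expression(SimulationDesign(seed=1))

results = CoexpressionNetwork(expr_f).fit()
print(results.summary())
```

```
Signed coexpression network
===========================
genes: 600, samples: 150
soft power beta: 14 (selected on grid)
modules: 5 (grey bin: 300 genes)
  turquoise         60 genes   var.explained 0.791
  blue              60 genes   var.explained 0.798
  brown             60 genes   var.explained 0.836
  yellow            60 genes   var.explained 0.796
  green             60 genes   var.explained 0.751
```

All five planted modules are recovered exactly (the 300 background genes
land in grey), and the selected power 14 is the lowest grid power meeting
both scale-free criteria on this synthetic cohort. Testing the planted
connectivity bias:

```python
bias = StratifiedConnectivityTest(expr_f, expr_m,
                                  results.partition.modules,
                                  beta=results.power).fit()
print(bias.round(4).to_string(index=False))
```

```
   module  mean_k_a  mean_k_b       t   p  fraction_a_higher  biased  p_bh
turquoise   18.8275    0.4963 11.7372 0.0                1.0    True   0.0
     blue   18.3878    0.2881 12.2934 0.0                1.0    True   0.0
    brown   21.0841    0.7506 14.4215 0.0                1.0    True   0.0
   yellow   18.0095    0.4942 12.0434 0.0                1.0    True   0.0
    green   14.4275    0.2791 10.4607 0.0                1.0    True   0.0
```

Every module's mean intramodular connectivity is far higher in the focal
stratum (`mean_k_a` vs `mean_k_b`), every gene sits above the identity line
(`fraction_a_higher = 1.0`), and all five planted sex-biased modules are
flagged — as they should be, since the generator boosted stratum-A loadings
by 1.5x.

The same analysis is available from the shell:

```bash
plaquenet simulate --seed 1 --out sim/
plaquenet netbuild --expr sim/expr_a.tsv --out net/
plaquenet diffconn --expr-a sim/expr_a.tsv --expr-b sim/expr_b.tsv \
    --modules net/modules.tsv --beta 14 --out bias.tsv
plaquenet run-all --config config.yaml --out results/
```

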
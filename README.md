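# frontassembly

Community-ecology analysis of eukaryotic plankton metabarcoding surveys
across hydrographic fronts: diversity partitioning, OTU-connectivity,
phylogenetic null-model inference of community assembly processes, and
trait-based functional diversity — with a built-in metacommunity simulator
so the whole pipeline is testable without any external dataset.

## Who this is for

Microbial and plankton ecologists who have an OTU (or ASV) count table, a
rooted phylogeny of those OTUs, a mixed-type trait table, and per-sample
environmental measurements, and who want to answer: *which ecological
process — selection, dispersal, or drift — dominates the differences
between my communities, and how do taxonomic, phylogenetic and functional
diversity partition across stations and seasons?*

## The statistics at the core

**Phylogenetic turnover.** For communities *A* and *B* with cophenetic
distance *d* over the tree,

  βMNTD(A,B) = ½ [ mean_{i∈A} min_{j∈B} d(i,j) + mean_{j∈B} min_{i∈A} d(i,j) ]

on presence/absence. Its null distribution comes from 999 random shuffles of
the tip labels across the regional-pool tree; the standardized deviation

  βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null

flags selection when |βNTI| > 2 (negative: homogeneous selection, positive:
variable selection).

**Compositional turnover.** The Raup-Crick metric compares the observed
Jaccard dissimilarity against 999 null community pairs drawn by
occupancy-weighted sampling without replacement, preserving each sample's
richness; RC = 2·P(J_null < J_obs, ties counted half) − 1 ∈ [−1, 1]. For
pairs with |βNTI| ≤ 2, RC > 0.95 indicates dispersal limitation,
RC < −0.95 homogenizing dispersal, and |RC| ≤ 0.95 ecological drift.

**Around the null models:** analytic (hypergeometric) rarefaction and
bias-corrected Chao1; shared/station-specific occurrence categories and
abundant (>0.1%), low (0.1–0.01%), rare (<0.01%) read-share classes;
station×season networks weighted by numbers of shared OTUs, with a
curated-richness control (seasons subsampled to equal OTU numbers, Spearman
correlation of edge weights); adonis-style sequential PERMANOVA on
Bray-Curtis or βMNTD matrices; Gower trait distance → PCoA → convex-hull
functional richness normalized to [0, 1] by the pool hull; complete-linkage
clustering of trait space into ecological strategies.

**The simulator** grows a Yule phylogeny, evolves niche optima and twelve
morpho-trophic traits along it (Brownian motion, optionally with an
early-burst conservatism profile), and assembles communities by multinomial
sampling of J individuals with weights = regional abundance × Gaussian
environmental filter × station dispersal kernel. Scenario presets make each
of the five canonical assembly processes dominant; a full-design survey
preset emulates 3 seasons × 5 stations × 2 depths × 3 size fractions × 3
replicates with a frontal station receiving pulsed nutrients.

## Worked example

```python
from collections import Counter
import frontassembly as fa

config = fa.scenario_preset("homogeneous_selection", seed=1)
table, tree, traits, env, truth = fa.generate_metacommunity(config)
print(table)
results = fa.infer_assembly(table, tree, n_null=999, seed=1)
counts = Counter(r.process.value for r in results)
for process, n in counts.most_common():
    print(f"{process}: {n}/{len(results)} pairs")
r = results[0]
print(f"example pair: bMNTD={r.bmntd_obs:.3f} null={r.null_mean:.3f}+/-{r.null_sd:.3f} "
      f"bNTI={r.bnti:.2f} RC={r.rc:.2f} -> {r.process.value}")
```

prints

```
OtuTable(20 samples x 67 OTUs)
HomogeneousSelection: 162/190 pairs
Drift: 26/190 pairs
HomogenizingDispersal: 2/190 pairs
example pair: bMNTD=1.023 null=2.063+/-0.309 bNTI=-3.37 RC=0.63 -> HomogeneousSelection
```

Twenty samples were assembled under one narrow, phylogenetically conserved
environmental filter; the classifier attributes 85% of the 190 pairwise
comparisons to homogeneous selection. The example pair's observed βMNTD
(1.02) sits 3.4 null standard deviations below the tip-shuffle expectation
(2.06 ± 0.31): its compositional turnover happens among close relatives,
the signature of a shared selective environment.

## Command line

```bash
frontassembly all --config run.yaml --seed 42 --outdir runs/demo
```

with a YAML config such as

```yaml
outdir: runs/demo
seed: 42
scenario: default_survey   # or paths under `inputs:` for real data
n_null: 999
n_perm: 999
m_axes: 4
k_strategies: 9
permanova_terms: [NOx, ammonium, silicate, PAR]
```

Subcommands `simulate`, `filter`, `diversity`, `assembly`, `stats`,
`functional` run a stage (plus its prerequisites); every run writes TSV/JSON
artifacts and a `manifest.json` with seeds, parameters and checksums, and is
byte-reproducible under a fixed seed.

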
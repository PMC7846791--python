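# Methods

This note documents the models and procedures implemented in
`frontassembly`, the parameters that matter, the design decisions taken
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real survey data.

## Data model

The central object is a samples × OTUs matrix of read counts with
per-sample metadata (season, station, depth, size fraction, replicate), an
OTU → taxonomic-reference map, and three side tables: a rooted phylogeny
over OTU tips, a per-reference trait table (twelve mixed-type morphological
and trophic traits plus an obligate-phototrophy flag), and per-sample
environmental measurements. Counts must be non-negative integers (floats
integral to 1e-9 are cast, anything else rejected); all-zero OTU columns
are dropped with a warning at construction. Sample merging sums counts over
the chosen metadata fields and names merged samples by joining the retained
fields with `|` in a fixed order, so merges are associative and read-count
conserving by construction.

## Diversity bookkeeping

Richness is the number of OTUs with positive count. Rarefaction is the
analytic hypergeometric expectation E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)],
evaluated with log-gamma arithmetic so deep samples do not overflow; the
Monte-Carlo subsampling cross-check in the test suite agrees within three
standard errors. Chao1 uses the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)) by default (the classic F1²/2F2 variant is a
flag) because the correction stays defined when no doubletons exist.

Occurrence categories follow the shared / station-specific dichotomy within
each season; abundance classes cut per-season read shares at 0.1% and
0.01%, with boundary shares assigned to the lower class (the thresholds are
printed as strict inequalities). OTU-connectivity is the number of OTUs
shared between every pair of station×season (optionally ×depth) groups;
edges are kept at weight zero rather than dropped so network statistics see
the full pair set. The curated-richness control subsamples each season's
OTU *identities* (not reads) uniformly down to the minimum seasonal
richness and reports the Spearman correlation between original and curated
edge weights; subsampling identities is the least-assumption reading of
"equal numbers of OTUs by season", and the read-weighted alternative can be
built by filtering counts first.

## Assembly inference

Phylogenetic turnover is presence/absence βMNTD; conspecific taxa shared by
both communities contribute zero distance (they are their own nearest
taxa). The null model shuffles tip labels across the **entire regional-pool
tree** — every tip of the supplied phylogeny, including taxa that never
occur in the analysed table. When the tree is pruned to the table (the
normal situation with real data, where the tree is built from the observed
OTUs) this is identical to shuffling over the table pool; for simulated
data, where the tree *is* the regional pool, the broader shuffle is what
gives the null its contrast. A filter that consistently excludes part of
the pool would otherwise erase its own evidence: the excluded clade
disappears from the table, the null collapses onto the selected clade, and
homogeneous selection becomes undetectable in principle. One permutation is
shared by all sample pairs per null replicate; 999 replicates by default.

βNTI standardizes the observed βMNTD by the null standard deviation. Where
the null distribution is degenerate (a star phylogeny leaves βMNTD
invariant under relabelling) the standard deviation is zero and βNTI is
defined as 0 — no detectable deviation — rather than NaN.

Raup-Crick uses the Jaccard dissimilarity, a pool of all OTUs in the table
weighted by occupancy (fraction of samples occupied; abundance weighting is
a flag, off by default to keep all metrics presence-based), and null
communities drawn by weighted sampling without replacement via Gumbel
top-k, preserving each sample's observed richness. Ties J_null = J_obs
count one half (mid-P). RC is rescaled to [−1, 1]. Null communities are
drawn once per sample and paired across samples; each pair still receives
`n_null` independent null comparisons, and the tie/below counts use exact
integer cross-multiplication rather than floating-point Jaccard
comparisons.

Classification follows the strict-threshold rule table: βNTI < −2
homogeneous selection, βNTI > 2 variable selection, otherwise RC > 0.95
dispersal limitation, RC < −0.95 homogenizing dispersal, else drift;
boundary values fall through to the weaker category. All pairs of the
supplied table are compared (replicates included); the summary network
groups pairs by station×season and keeps the multiplicity of repeated
non-selection edges.

The phylogeny-trait check is a Mantel test (Pearson correlation of
off-diagonal entries, one-sided permutation p with the (count+1)/(n+1)
convention) between cophenetic and Gower distances over the same taxa. It
is implemented in-package rather than via a library call because the
permutation stream must be seedable for reproducible pipelines.

## Permutation statistics

PERMANOVA partitions the Gower-centered −½D² inner-product matrix with
sequential (Type I) sums of squares in the user-given term order, supports
numeric covariates and categorical factors (dummy-coded, rank-checked — a
constant or confounded term is an error naming the term), and obtains
p-values by raw permutation of sample identities: (count+1)/(n_perm+1), or
exact count/total when all n! permutations are enumerated (`n_perm=None`).
A model with zero residual sum of squares yields F = ∞, which compares
correctly against permuted statistics. The two published analysis variants
(with and without temperature) are simply two term lists, not special
cases. Kruskal-Wallis (tie-corrected, χ² approximation) and Spearman rank
correlation delegate to scipy, with the all-ties case defined as H = 0 and
constant-vector correlations reported as missing.

## Functional diversity

Gower distance ranges numeric traits by their pool range and scores
categorical/binary traits 0/1, dropping a trait's weight for any pair in
which either value is missing; a pair with no comparable trait is an error
naming the rows. PCoA eigendecomposes the centered matrix; genuinely
negative eigenvalues (non-Euclidean residue of Gower on mixed data) are
dropped and logged — no Cailliez/Lingoes correction by default —
while ~zero eigenvalues are retained so degenerate geometries (collinear
trait spaces) still embed. Functional richness is the convex-hull volume of
a community's OTUs in the first m axes divided by the pool hull volume, so
the pool scores exactly 1. m defaults to 4: hull volumes in higher
dimensions need more points than typical station communities provide and
become numerically fragile. Strategies are complete-linkage clusters of the
Gower matrix cut at k = 9; cluster ids are relabelled by first appearance,
making the partition (not the numbering) the contract. Scipy's tie-break
for equal merge heights is accepted as-is; partitions are
order-independent whenever merge heights are distinct, which the test suite
checks on generic data.

## The synthetic metacommunity

The generator is a first-class module, not a fixture: it produces the
statistical structure the analysis assumes, with ground truth.

* **Phylogeny**: pure-birth (Yule) tree, exponential waiting times, tips
  extended to the present (ultrametric), labelled OTU0001…
* **Niche optima**: Brownian motion along the tree, z-scored across tips.
  `niche_conservatism` > 0 switches to an early-burst profile — the BM rate
  decays as exp(−c·depth) — concentrating niche divergence at deep splits
  so that close relatives share niches. Plain BM on a Yule tree leaves most
  trait variance on terminal branches, which decorrelates sister species;
  conservatism is the biologically standard way to express that niches are
  clade-level attributes.
* **Traits**: liabilities mix a standardized BM component with independent
  noise; the phylogenetic variance share is s/(s+0.5) for
  `trait_signal` = s, so s = 0 gives phylogeny-free traits and s = 1 a 2:1
  heritable mix. Cell sizes are exponentiated liabilities with
  SizeMax = SizeMin·(1+|liability|); categorical traits threshold
  liabilities at realized quantiles into their vocabularies.
* **Abundances**: regional log-normal (`abundance_sigma`), optionally
  modulated per sample by a log-normal fluctuation (`abundance_noise`) that
  models bloom dynamics and patchiness and is the source of compositional
  turnover when selection is otherwise fixed.
* **Assembly**: per sample, weights = regional × exp(−(env−µ)²/2σ²) ×
  dispersal, and the community is one multinomial draw of J individuals
  (drift). Dispersal limitation partitions the pool into disjoint
  station pools mixed with the global pool at migration rate m. Size
  fractions split each OTU's counts by a per-OTU affinity (90% to a home
  fraction, 10% leakage), mimicking filtration cross-contamination.
* **Environment**: a one-dimensional temperature-like axis. Modes:
  `seasonal` (season base + ocean→coast station offsets), `quantile`
  (stations pinned to quantiles of the realized niche distribution),
  `peak` (all samples at the densest niche point), `constant`. The
  front station receives a pulse in stratified seasons: larger J and
  relaxed selection, the minimal mechanism for a diversity hotspot fed by
  nutrient input. Reported nutrient/temperature values are deterministic
  functions of season, station and the niche axis plus small seeded noise.

All randomness flows from one root seed through named substreams (tree,
traits, abundances, environment, communities, fractions), so each component
is reproducible in isolation.

### Scenario presets and their calibration

Presets use 128 OTUs, 5 stations × 4 replicates, one season and fraction,
J = 2000 — sizes at which 999-replicate nulls run in seconds. Parameters
were fixed at design time so that each preset's generative mechanism
actually dominates its classification at this scale:

* `homogeneous_selection`: σ_sel = 0.05 on a strongly conserved niche
  (conservatism 2.5), environment at the 0.9 niche quantile so the filter
  passes a minority clade, abundance fluctuations σ = 3.0 to drive
  within-clade turnover. Detection of homogeneous selection *requires*
  turnover among close relatives; with no turnover βMNTD is ~0 under both
  observation and null.
* `variable_selection`: stations at the 0.05–0.95 niche quantiles,
  σ_sel = 0.25, conservatism 1.0 — different stations select different
  clades.
* `dispersal_limitation`: neutral, disjoint station pools, m = 10⁻⁴.
* `homogenizing_dispersal`: neutral, one strongly skewed pool
  (σ_abund = 2.5) sampled at log-spaced intensities (J spread ×8): nested
  communities are more similar than the occupancy-weighted null expects.
* `drift`: neutral and well mixed with σ_abund = 0.6, which keeps every
  taxon comfortably above the 1/J detection threshold. Near-threshold taxa
  have abundance-determined, cross-sample-correlated presence that the
  occupancy null cannot represent, and would register as spurious
  homogenizing dispersal; a calibrated neutral limit is a design
  requirement of the null-model framework, not a free choice.

The full-design `default_survey` preset uses broad selection (σ_sel = 0.8),
seasonal environmental movement, seasonally tightening selection (richness
declines through the year) and a pulsed front station. It exercises the
diversity, connectivity, PERMANOVA and functional machinery; its pairwise
classifications are a drift/selection mixture rather than the
near-unanimous homogeneous selection of a real survey, because the niche
breadth that stabilizes its connectivity structure also weakens the βNTI
signal at 256-OTU scale.

### What the synthetic tests do and do not show

Passing tests demonstrate that the estimators are correct (oracle and
hand-example agreement), that the null models are calibrated in the neutral
limit, and that each assembly process is recovered when its mechanism
dominates at desk scale. They do not demonstrate performance on real
metabarcoding data, whose OTU trees have radically uneven tip densities,
whose abundances are compositional with sequencing-depth artifacts, and
whose environmental drivers are multivariate and autocorrelated — none of
which the generator emulates. Problem sizes in the test suite (128–256
OTUs, 999 nulls, seeds 1–5) were chosen so the full suite runs in minutes
on one CPU.

## Numerical choices

Log-gamma combinatorics for rarefaction; exact integer cross-multiplication
for RC tie detection; Gumbel top-k for weighted sampling without
replacement; βNTI defined as 0 at zero null variance; PCoA negative
eigenvalues dropped (logged), ~zero eigenvalues retained; convex-hull
degeneracy surfaces as an error advising a smaller m; permutation p-values
never return 0; merged-sample ids are deterministic `|`-joins; all TSV/JSON
output is byte-stable under a fixed seed.

## Known limitations

Abundance-weighted βMNTD and Bray-Curtis-based Raup-Crick are out of scope
(presence-based metrics only, matching the non-weighted analysis choice).
The front's spring/neap disturbance cycle is represented statically, not
dynamically. The curated control's read-subsampling alternative and the per-pair βNTI
null pool exist as options but are not the defaults; Raup-Crick pools are
always estimated from the full table supplied, so per-season pooling is
achieved by passing per-season tables explicitly rather than by a flag.
Coverage-based richness extrapolation is replaced by analytic rarefaction
plus the Chao1 asymptote.
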
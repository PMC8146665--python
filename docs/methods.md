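# Methods

## Coordinate conventions

VCF positions are 1-based; a `Region` is half-open `[start, end)` so its
length is `end − start`. Under this convention the canonical core region
3R:6928858–6930547 spans 1689 bp, and distances from a gene's (exclusive)
end coordinate to a downstream gene's start are plain differences. Published
downstream-gene distances are ambiguous about their anchor (the focal gene's
end vs the end of the enclosing P450 supercluster at 3R:6978142), so
`downstream_distance` takes the anchor explicitly rather than fixing one.

## Effect annotation

The annotator handles a single-CDS, single-transcript gene model (the
motivating gene has no reported alternative splicing). A SNP inside the CDS
is mapped to its transcript index (reverse-complemented on the minus
strand), the alternate base is substituted into its codon, both codons are
translated with the standard genetic code (Biopython), and the variant is
classified missense / synonymous / stop_gained / stop_lost, labelled
one-letter-AA + codon number + one-letter-AA (e.g. `I359V`). A reference
base that disagrees between VCF and gene model raises a data-integrity
error rather than being reinterpreted.

Frequencies are computed per (population × species) cohort — population
labels that already encode species (e.g. `BFcol` vs `BFgam`) are used as-is;
a mixed-species population label is split. The "All" column is
haplotype-weighted (pooled alt count over pooled haplotype count), not a
mean of cohort frequencies; a `cohort_mean` mode exists for the alternative
reading. The high-frequency filter is strict: a variant is kept only when
its frequency *exceeds* the threshold (default 5 %) in at least one cohort.

## Hamming clustering

Distances are SNP counts over the biallelic sites of the analysis region
(not per-bp), so the cut height (default 7 SNPs) has the same units as the
published clustering threshold. The linkage method is selectable (single /
complete / average) and defaults to single linkage, whose flat clusters at
cut h are exactly the connected components of the graph joining pairs at
distance ≤ h — a semantics the tests verify against an independent
union-find oracle. Clusters at or above `min_cluster_freq` (default 1 %)
are named C1…Ck by descending size (ties broken by the lowest member
index); the rest fold into `wt`. One global dendrogram is cut, not
per-population dendrograms.

## Lewontin's D′

With alt frequencies pA, pB and joint alt–alt gamete frequency pAB,
D = pAB − pA·pB and

    D′ = D / min(pA(1−pB), (1−pA)pB)        if D > 0
    D′ = D / min(pA·pB, (1−pA)(1−pB))       if D < 0
    D′ = 0                                  if D = 0.

The sign is kept: +1 means perfect coupling, −1 means the alt alleles never
co-occur on a haplotype. A site monomorphic in the analysed cohort makes D′
undefined and is flagged explicitly (NaN plus a `defined` mask). This
matters for population-stratified analyses: a pooled D′ of 1 driven by
population structure must become *undefined or weak* within cohorts, not a
silent 0.

## Median-joining networks

The minimum spanning network keeps every edge that belongs to at least one
minimum spanning tree, relaxed by an integer epsilon (edge kept when its
weight ≤ minimax path weight + epsilon; epsilon defaults to 0, the sparsest
choice). Median vectors are the per-site majorities of node triplets
connected in the current network; a candidate median is accepted only if it
does not increase the cost of spanning the node set, candidates are
inserted in sorted order, triplets are enumerated in lexicographic node
order, and inferred nodes of degree < 3 are pruned as obsolete — so reruns
are bit-identical. Components are taken after dropping edges heavier than
`max_edge` (default 2 SNPs). Concordance with a cluster assignment matches
each component to the cluster label held by the plurality of its haplotypes
(ties resolved towards the larger cluster, then lexicographically); an
optimal one-to-one matching mode is available, since the plurality metric is
a documented choice rather than a canonical definition.

## EHH

Haplotypes identical over the core region form core groups (≥ 1 % frequency
by default); when a cluster assignment is supplied, the named clusters are
the groups and each distinct wild-type core haplotype above threshold
becomes its own `wt-k` group. Moving outward from the core edge, EHH at a
site x is Σ C(e_s,2)/C(c,2) over the subgroups e_s of cumulative identity
from the edge through x — the probability two random group members are
identical over the whole interval. EHH is evaluated only at variant-site
positions (it is constant between sites), starts at 1, never increases, and
is truncated at the first 0 or at 200 kb. `ehh_area` integrates a curve
trapezoidally over genomic distance; left and right arms are summed.

Two cohort-level summaries exist: `mean_core_group_area` (unweighted over
groups) and `population_ehh_area`, which weights each group by its share of
all haplotype pairs and therefore measures the probability that two random
cohort members share the core *and* remain identical to distance x,
integrated. The weighted form is the one that responds to diversity
reduction: in a diverse cohort, any two haplotypes that happen to share the
core are usually a recent family whose flank identity is family-level, so
the unweighted mean barely distinguishes a bottlenecked cohort from a
diverse one, while the pair-weighted form separates them cleanly.

## The simulator and its study conditions

A forward Wright–Fisher model over a fixed lattice of candidate SNP
positions: each offspring gamete is a crossover mosaic of one parent's two
haplotypes (crossover probability 1 − exp(−r·gap) per inter-site gap),
parents are drawn with multiplicative diploid fitness (1 + s per focal alt
copy) when selection is on, and alleles flip symmetrically with probability
mu per site per generation. Founder haplotypes are all distinct and at
linkage equilibrium, with ancestral site frequencies drawn Uniform(0.1,
0.9) from a lattice-keyed stream so that independently simulated demes share
ref/alt letters and ancestral frequencies and can be merged.

Defaults, chosen once as the study conditions: 100 diploids per deme (200
haplotypes), 400 sites at 200 bp spacing on 3R with the focal site centred
in the 1689 bp core region, mu = 1e−6, r = 2e−6 per bp per generation, 60
generations, focal allele initialised at frequency 0.5. With these rates the
expected lineage recombination between the core and a point d bp away over
t generations is r·d·t ≈ 1 at d ≈ 8 kb for t = 60, so EHH decays well
inside the ±40 kb flanks.

Two distinct scenarios share this machinery:

* **Neutral control** (`SimConfig()` defaults, s = 0, focal frequency 0.5).
  At frequency 1/2 the carrier and non-carrier classes are exchangeable
  under allele relabelling, so the probability that the carrier group has
  the larger EHH area is exactly 1/2 — an exact null for the
  carrier-vs-wild-type contrast. A neutral allele *surviving* from rarity
  would not give this null: its few carriers are related by the survival
  conditioning itself, which biases carrier identity upward.

* **Recent hard sweep** (`sweep_config()`: focal frequency 0.01 — two
  founder copies — with selection s = 0.2 over the final 25 generations).
  The sweep signal requires the allele to rise from (near-)single origin:
  selection acting on an allele already at intermediate frequency merely
  expands the carrier class proportionally and forces no recent common
  ancestry, hence no EHH signal. From two copies, the deterministic odds
  growth e^{s·t} puts the allele at roughly 0.6–0.95 after 25 selected
  generations. `simulate_surviving_sweep` re-runs lost or (nearly) completed
  replicates with the next derived seed until both allele classes segregate
  at ≥ 5 % of haplotypes: a contrast against wild type needs a wild-type
  background to exist, and a handful of escapees from a finished sweep is a
  single family, not a background.

* **Bottleneck** (optional epoch `(start, size, duration)`, e.g. 10 diploids
  for 15 generations starting at generation 20): collapses diversity and
  lengthens shared haplotypes with no selection — the demographic confound
  the per-population analysis is designed to expose.

`simulate_sweep_contrast` records, per paired replicate, the focal
frequency, the mean pairwise carrier identity over a ±10 kb window, and
their population-scale product `carrier_homozygosity` (the fraction of all
haplotype pairs that are identical carrier pairs). The product is the
contrast statistic: identity alone is inflated in small surviving neutral
carrier classes, whereas high identity *at high frequency* is the sweep
signature.

### What the simulator does and does not emulate

It produces phased diploids with realistic within-deme haplotype structure,
LD decaying with distance, site-frequency variation, sweep and bottleneck
signatures, and coding sites with synonymous/missense classes (via a
planted random CDS free of internal stops). It does not model migration or
admixture between demes (demes evolve independently), overlapping
generations, gene conversion, variable recombination or mutation rates
along the sequence, back-mutation-aware infinite-sites behaviour (sites are
two-state and can recur), or realistic African *Anopheles* demography.
Passing tests therefore demonstrate that the statistics recover planted
signals under a clean Wright–Fisher model at small N — not that they would
have the same power or false-positive behaviour on real population-resequencing data at study scale,
where sample sizes, recombination heterogeneity and population structure
differ substantially.

## Numerical and degenerate-input choices

* Hamming distances come from `scipy.spatial.distance.pdist` (fractional
  Hamming × site count, rounded to integers); clustering from
  `scipy.cluster.hierarchy` with `fcluster(criterion="distance")`.
* D′ on a monomorphic site raises/flags rather than returning 0.
* EHH for a group of fewer than two members is undefined and raises; in
  per-population runs such groups are skipped with a log line.
* Unphased or multiallelic VCF records are skipped and counted, never split
  or imputed; a sample present in the VCF but absent from the panel is an
  error.
* Median-joining caps inferred nodes (default 2000) and iterations to keep
  degenerate inputs bounded; the cap logs a warning.
* All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; derived seeds stay below 2^31.

## Problem sizes used in the checks

The automated checks run the simulator at its default deme size (200
haplotypes, 300–400 sites): 20 surviving-sweep replicates for the sweep
recovery rate, 200 neutral replicates for the binomial null, 20 matched
pairs for the bottleneck contrast, and 100/50 random instances for the
EHH-formula and single-linkage oracle equivalences. These sizes give stable
Monte-Carlo estimates (binomial CI half-width ≈ 7 percentage points at 200
replicates) while keeping a full run at around one minute on one CPU.

## Known limitations

* The effect annotator is single-transcript, single-frame; no splice or UTR
  annotation, no multi-interval CDS generation in the simulator (the type
  supports multiple CDS intervals; the generator plants one).
* The median-joining implementation recomputes the spanning structure per
  candidate acceptance; it is intended for the hundreds-of-haplotypes scale
  of a gene region, not genome-scale inputs.
* Concordance's plurality matching is a declared convention; published
  concordance figures may use a different, unstated formula.
* The neutral-control exactness argument holds for the carrier/non-carrier
  split at focal frequency 1/2; it does not extend to the core-haplotype
  group decomposition, which is why the carrier contrast is the sweep
  detector of record.
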
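# Methods

`ystrkit` implements the statistical toolchain used to analyse
Y-chromosome short-tandem-repeat (Y-STR) haplotypes within a SNP-defined
haplogroup — the workflow of population studies of haplogroup Q in the
Americas: classify chromosomes on a marker-labeled tree, summarize
haplotype diversity, ordinate individuals, connect haplotypes in
median-joining networks, and date lineage expansions from microsatellite
variance. This note records the models, the defaults, and the choices made
where the design was genuinely open.

## Data model and filters

An STR profile stores one male's repeat counts per locus. Values are exact
decimals so that partial-repeat micro-variants (e.g. `13.2` = 13 repeats
plus a 2-bp partial motif) survive round trips unchanged. Four systems
(YCAIIa/b, DYS385a/b, DYS459, DYS464) are duplicated on the Y: their two
alleles cannot be phased to a copy and are stored unordered.

The *minimal haplotype* is the classical forensic seven-locus set DYS19,
DYS389I, DYS389B, DYS390, DYS391, DYS392, DYS393; DYS389B is accepted
directly or derived as DYS389II − DYS389I (DYS389II amplifies a fragment
containing DYS389I). DYS385a/b, part of the historical minimal haplotype,
is disregarded throughout because its alleles are unphaseable.

All haplotype statistics assume one integer allele per single-copy locus,
so *atypical* samples — carrying a micro-variant or a duplication of a
normally single-copy locus at any analysis locus — are excluded first and
reported in an exclusion table; exclusions are never silent. Profiles
missing a required locus are likewise excluded and logged rather than
partially averaged: complete-case analysis is the only reproducible rule
when the upstream typing panel varies. Ordination is the one exception on
micro-variants: fractional alleles subtract cleanly, so micro-variant
carriers stay in the distance matrix and only duplicated-locus samples are
dropped there.

## Haplogroup classification

The haplogroup tree is a rooted YCC-style tree; each node carries one or
more defining biallelic markers (the bundled tree covers haplogroup Q:
M242 at the root, MEH2/M346/L53/L54 internally, M3 and its sublineages,
L191/L330/PV3/PV4, and Q1b-M378). A sample's label is the deepest node
whose path from the root is entirely derived. Untyped markers block
nothing — hierarchical genotyping deliberately leaves deep branches
untyped once an upstream marker resolves — while a derived call below an
ancestral call on the same path, or derived calls on diverging branches,
raise an error. A label is starred (a *paragroup*, e.g. `Q1a3a1-L54*`)
when at least one child marker was typed ancestral and none derived: the
chromosome belongs to the node but to no examined sublineage. Frequencies
are direct counts with percentages within each population's classified
total (one decimal); clade aggregation sums a node's column with all of
its descendants'.

The bundled 463-chromosome survey composition (15 populations from
Mongolia/Kamchatka to Mexico, Central America, the Andes and southeastern
South America, with three anomaly-flagged samples) drives the package's
worked examples: direct counting and clade aggregation on it reproduce the
published continental fractions (99.5% L54 clade, 80% M3 clade among 436
Native American chromosomes) and every per-analysis sample size (433 for
ordination; 431/348/83 for dating) from the package's own exclusion rules.

## Diversity

Haplotype diversity is Nei's unbiased gene diversity
h = n/(n−1)·(1 − Σᵢ pᵢ²) over distinct minimal haplotypes — the
probability that two chromosomes drawn without replacement differ. Repeat
variance V is the unweighted mean over the seven single-copy minimal-
haplotype loci of the per-locus sample variance (n−1 denominator). Both
conventions (unbiased estimators, 7-locus V) are stated in output
metadata because variance can also be reported over larger panels.

## Ordination

The default individual-by-individual distance is the squared
repeat-difference summed over loci, d(i,j) = Σₗ (aᵢₗ − aⱼₗ)² — the standard
microsatellite individual distance, computed here over 33 single-copy loci
when the full panel is available (duplicated systems are excluded because
their alleles cannot be paired across samples). Since this d is already a
squared Euclidean distance, PCoA double-centers it directly:
B = −½ J d J, eigendecomposition, coordinates = eigenvectors ×
√eigenvalue. Results are deterministic up to per-axis sign, so tests
compare reconstructed distances or Procrustes-aligned configurations, not
raw signs. A mismatch-count metric is available behind a flag; it is not
generally Euclidean, and any negative eigenvalues are reported and
excluded from the explained-variance denominator, never silently dropped.
The metric in use is recorded in the run manifest.

## Median-joining networks

Loci are ordinal multistate characters with stepwise cost |aᵢ−aⱼ| per
locus, weighted by integer locus weights ∝ 1/Varₗ (scaled so the smallest
weight is ≥ 1, rounded, capped at 99; zero-variance loci get the cap):
fast-mutating loci count for less, as in standard network practice.

Construction iterates to a fixpoint: (1) build the ε-relaxed minimum
spanning network — an edge is feasible when its length exceeds the
bottleneck (single-linkage merge) distance of its endpoints by at most ε;
at the default ε = 0 this is exactly the union of all minimum spanning
trees; (2) for every triplet connected within that network, form the
per-locus median (the middle value, which minimizes linear stepwise cost)
and add all unobserved medians whose connection cost is within ε of the
round's minimum. Afterwards, unobserved medians of degree ≤ 2 whose
removal does not lengthen the minimum spanning tree are pruned, so
surviving median vectors have degree ≥ 3. Nodes are processed in
lexicographic order, making the network reproducible; median ties cannot
arise with complete integer data (the middle of three integers is unique).

Reduced-median preprocessing, applied on request before median-joining,
expands each locus into binary threshold characters (value ≥ t), takes the
closure under triplet majority medians, and retains a candidate when the
best two-edge chain through an existing haplotype costs at most r times
the median's star cost (default r = 2; r = 1 keeps only cost-neutral
medians, large r keeps all — node count is monotone in r). Candidate
medians are enumerated from connected triplets only; no exhaustive Steiner
search is attempted.

## ASD dating

Under the unconstrained symmetric stepwise mutation model the average
squared difference in repeat count between sampled chromosomes and their
founder grows linearly: E[ASDₗ] = μ·T after T generations. With the
founder approximated by the per-locus median haplotype (even n takes the
lower central value — a fixed, declared tie-break), the age is

T = mean(ASDₗ)/μ_eff × g years,

with μ_eff = 6.9×10⁻⁴ per locus per generation and g = 25 years by
default — the evolutionary effective calibration appropriate for time
depths of ≳ 40 generations; pedigree rates are deliberately not offered.
The standard error is computed over loci as sd(Tₗ)/√L of the per-locus
ages Tₗ = ASDₗ/μ_eff × g (equivalently the propagated sd of per-locus
ASDs; the two differ only by the common scale factor, and the choice is
declared in the manifest). A monomorphic sample returns T = 0, SE = 0;
one locus returns an age with SE undefined. Ages are reported in kya to
one decimal. Input samples are pre-filtered for duplicated loci and
micro-variants on the dated locus set (the seven minimal-haplotype loci
unless overridden); no partial averaging over incomplete profiles.

## Synthetic data

The simulator generates what the analyses assume, so every stage is
testable without a genotype download.

* **Star genealogy** (the limit of a rapid expansion): each of n samples
  evolves independently from the founder for T_g generations; per-locus
  mutation counts are Binomial(T_g, μ) — exactly the per-generation
  Bernoulli model — and each mutation steps ±1 with equal probability.
  This makes E[ASD about the founder] = μ·T_g exactly, the identity the
  dating tests check.
* **Coalescent genealogy**: a Kingman n-coalescent drawn with msprime
  (haploid lineages; the effective size parameter `ne` is scaled so that
  E[pairwise TMRCA] = 2·ne generations), with per-locus mutation counts
  Poisson(μ × branch length) dropped branch by branch.
* **Structure and SNPs**: populations get founders evolved from a common
  root founder for a configurable divergence, or explicit founders; SNP
  markers are layered on the root, on a population stem, or on a random
  internal clade of a coalescent tree, and the truth record lists each
  marker's derived samples and each sample's generating haplogroup node.
* **Anomalies**: configurable per-sample rates inject +0.2 partial-repeat
  alleles and second alleles at single-copy loci, exercising the filters.

Defaults (n = 100, μ = 6.9×10⁻⁴, L = 7, T_g = 1000, founder
13-13-16-24-10-14-13 — a common Native American Q modal haplotype) mirror
the regime the statistics are used in. The model is intentionally minimal:
no range constraints on repeat counts (reflecting boundaries would bias
ASD against the effective-rate calibration), no multi-step mutations, no
migration, admixture or selection. Passing recovery tests therefore show
correctness *under the stepwise model on the stated genealogies*, not
robustness to real-data complications such as locus-specific rates,
population structure within lineages, or genotyping error.

One master seed feeds named substreams (founders, mutation draws, SNP
placement, anomalies), so adding an operation never perturbs another's
draws and identical configurations reproduce byte-identical outputs.

## Problem sizes in the validation suite

The test suite and the acceptance script size their simulations for desk
runtimes while keeping Monte-Carlo error informative: dating recovery uses
200 replicates of n = 100 at T_g ∈ {200, 1000, 4000} (mean within 3 MC
SEs of truth; observed bias ~1%); the ASD-linearity check uses a single
n = 2000 draw; network-vs-oracle comparisons use exhaustive brute force on
≤ 6 haplotypes over 3 loci; coalescent pairwise checks use 400 replicates
of n = 2 (the exponential TMRCA tail dominates the variance there).

## Known limitations

* The haplogroup tree fixture encodes one published topology; markers
  reported but never observed (M19, M199, L401, NTW01, M323) are present
  and classifiable but untested against derived calls in real data.
* Median-joining follows the connected-triplet heuristic; like the
  original algorithm it does not guarantee a minimum Steiner network.
* The reduced-median retention rule is a declared in-package convention
  (chain/star ratio ≤ r); other software's internal tie-breaking may
  produce different, equally valid, intermediate sets.
* ASD dating inherits the calibration debate around Y-STR mutation rates;
  ages scale inversely with μ_eff and should be read comparatively.
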
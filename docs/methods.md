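# Methods

This note documents the models, conventions and design choices behind
`metapan`, in the order the pipeline runs them.

## Pangenome partitioning

Presence of a gene cluster in a genome means copy number ≥ 1; higher
copy numbers never change a category call (they matter only for
single-copy core selection). Categories are mutually exclusive and
exhaustive:

* **singleton** — exactly one carrier genome (checked first, so a
  single-genome input yields singletons rather than core clusters);
* **core** — all genomes;
* **genus_specific** — all genomes of exactly one genus, no others;
* **multi_genus_specific** — all genomes of ≥ 2 genera, no others;
* **accessory_other** — everything else.

Taxon-specific calls that rest on a genus represented by a single genome
are flagged (`involves_single_genome_genus`), because such genera
satisfy the "all genomes of the genus" condition vacuously and inflate
genus-specific counts. A cluster is habitat-tagged coastal (offshore)
iff every host genus carries that habitat label; any mixed set, or a set
touching a genus labeled `rare`, is tagged `none`.

Prevalence classes per genus use prevalence 1 for *core*, < 0.15 for
*rare*, and everything else — including exactly 0.15 — *intermediate*.
Reading the boundary this way makes the three classes exhaustive and the
boundary testable.

Functional enrichment across genome groups is a Rao score test for
equality of presence proportions: with pooled fraction p̄, group
fractions p_g and group sizes N_g,

    score = Σ_g N_g (p_g − p̄)² / (p̄(1 − p̄)),

referred to χ²(groups − 1), with Benjamini–Hochberg q-values across
functions. The score is defined as 0 (p = 1) when p̄ ∈ {0, 1}. The
statistic is asymptotic; for very small genome collections the
permutation null is discrete and the χ² p-value can differ from the
exact one by a factor of ~2, which is acceptable for screening but
worth remembering when group sizes are below ~20.

## Read-recruitment summaries

* **Detection** is breadth of coverage: the fraction of positions with
  depth ≥ 1. A genome is treated as present in a sample when detection
  ≥ 0.25 (the comparator is ≥ and the threshold is configurable).
* **Mean coverage Q2Q3** sorts the depth vector and drops ⌊n/4⌋
  positions from each end before averaging. Trimming by position count
  on a stable sort avoids quantile-interpolation ambiguity and is
  reproducible across platforms. Vectors shorter than 4 fall back to the
  plain mean with a warning. The trim is applied per gene (and per
  genome for whole-genome coverage); whether to trim per gene or per
  genome before subsetting is a genuinely open convention, and the
  per-gene choice is the one documented and tested here.
* **Single-copy core genes (SCGs)** of a genus are clusters at copy
  number exactly 1 in every genome of the genus. A single-genome genus
  can be given a nearest-neighbor genus; its SCG set is then the
  intersection of its own single-copy clusters with the neighbor's SCG
  set, which prevents the vacuous-core inflation described above.
* **Relative abundance**: per genome and sample, the Q2Q3 coverages of
  the genus's SCGs are averaged, zeroed when detection is below
  threshold, then normalized across genomes within the sample; genus
  abundance is the sum over member genomes. Averaging (rather than
  summing) SCG coverage is the default because genera have differently
  sized SCG sets and raw sums would bias toward genera with more SCGs;
  the raw-sum behavior is available via `mode="sum"`. Samples where no
  genome passes detection stay all-zero rather than dividing by zero.

Coordinates are 0-based half-open everywhere internally; one-based
inclusive gene coordinates are accepted on input behind an explicit
flag.

## pN/pS from single-codon variants

The unit of observation is the codon (matching codon-resolved variant
callers). For each sense reference codon, synonymous/nonsynonymous
*sites* are counted by enumerating all nine single-nucleotide
substitutions; substitutions creating stop codons count nonsynonymous,
and syn + nonsyn = 3 for every sense codon. Reference stop codons are
skipped entirely with a counted warning. The default genetic code is the
bacterial/archaeal table 11, configurable.

A codon position is a *variant site* when its coverage is at least
`min_coverage` (default 20) and the most abundant non-reference codon
reaches a `departure` frequency of 0.05 (configurable; the coverage
filter is the load-bearing one, the departure floor suppresses
sequencing noise). The variant is classified by amino-acid identity of
the full ref/alt codons — however many nucleotides differ — with ties
between non-reference codons broken lexicographically for
reproducibility. Then per gene, genome and sample:

    pN = n_nonsyn_variants / nonsynonymous sites
    pS = n_syn_variants / synonymous sites
    pN/pS = pN / pS   (undefined when pS = 0)

Site totals include only codons passing the coverage filter, so pN and
pS are proportions over the same observed portion of the gene; a gene
with no codon passing the filter yields an undefined (NaN) record.
Undefined ratios are excluded from ranking, summaries and ANOVA rather
than imputed or pseudocounted — pseudocounts would distort rank curves
at the well-conserved end of the spectrum, which is exactly the region
of interest. Raising `min_coverage` can only remove variant sites
(monotone filtering). Variant records are expected on the coding
strand; `to_coding_strand` re-orients minus-strand representations, and
a double application is the identity.

## Habitat clustering

Environmental parameters are z-scaled (mean 0, SD 1 with ddof = 1;
constant columns dropped with a warning). k-means uses k-means++ with a
configurable number of restarts, keeping the best within-cluster sum of
squares; k is chosen from 2..k_max by maximizing the Calinski–Harabasz
index (B/(k−1))/(W/(n−k)), with smaller k winning ties and W = 0
reported as +inf. k = 1 is never returned — the index is undefined
there, and the search convention starts at 2. PCA is a centered SVD;
component signs are fixed by making each loading vector's
largest-magnitude element positive, and scores × loadingsᵀ reconstructs
the centered matrix.

## Variance decomposition and downstream summaries

`variance_components` fits a main-effects OLS of defined ratios on
ordered categorical factors and reports sequential (Type I) sums of
squares as fractions of the total SS, residual included. The default
order is (gene, genome, sample); in a balanced complete design the
decomposition is order-invariant, otherwise the order is a modeling
choice and should be stated with results. Interactions are deliberately
not modeled — the question the decomposition answers is whether
selective pressure is a property of the gene rather than of the sample
or genome, and main effects suffice for that contrast.

Gene ranking uses the arithmetic mean ratio over the samples where the
gene passed the coverage filter, ascending, ties broken by gene
identifier; ranks are a permutation of 1..n over defined genes. The
purifying-selection summary is the per-genome fraction of gene-level
mean ratios at or below a cutoff (default 0.1), monotone in the cutoff.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the pipeline is
sensitive to, with every quantity recorded as ground truth:

* **Pangenome** — configured numbers of core, genus-specific,
  multi-genus-specific and singleton clusters; a tenth of core clusters
  get a second copy in one random genome so the single-copy core is a
  strict subset of the core. Genus-specific clusters requested for a
  single-genome genus are recorded as singletons, consistent with the
  classifier's precedence.
* **Coverage** — per-position depths are negative-binomial with mean m
  and variance m + a·m² (dispersion a, default 0.5); the mean is
  `depth_match` (50) when genome habitat matches the sample's habitat,
  `depth_mismatch` (0.1) otherwise, and `depth_rare` (0) for rare
  genera, times a per-genome lognormal abundance multiplier (σ = 0.4).
  Encoding the habitat effect as a mean-depth multiplier rather than
  presence/absence means the 0.25 detection threshold does real work:
  mismatched genomes have nonzero but sub-threshold expected breadth.
  Truth abundances are expected relative depths after applying the
  detection rule to the expected breadth P(depth ≥ 1), which is exactly
  what the recruitment stage can recover.
* **Variants** — round(pS_target · S) synonymous and round(pN_target ·
  N) nonsynonymous variant codons are planted at distinct eligible
  sites (stop codons never planted, as reference or alternative); truth
  is the realized count ratio, so rounding is inside the truth, not an
  error term. Every codon gets a covered record, mirroring profilers
  that report all positions. The planted alternative's frequency is
  0.30 of a 100× coverage; in stochastic mode its read count is
  binomial.
* **Environment** — two Gaussian clusters with coastal shifts up in
  chlorophyll/silicate-type parameters and down in salinity/pH-type
  parameters, separated by `env_separation` within-cluster SDs.

Dispersion 0 switches all generators into a deterministic mode
(constant depths, fixed variant placement at the first eligible sites,
exact planted frequencies) that exists solely to make exact-equality
round-trip tests possible. Every generator is a pure function of its
configuration including the seed.

What the simulation does **not** model: read-level artifacts
(mapping bias, competitive-mapping arbitration, duplicates), sequencing
error (so no false-positive variant sites), linkage between variant
sites, strain mixtures within a population, genome rearrangement, or
phylogenetic correlation between genera. Passing round-trip tests
therefore demonstrates that the estimators are correct for the stated
observation model, not that they are robust to every artifact of real
short-read data.

## Problem sizes and numerical conventions

Default test and demonstration sizes (6 genera × 3 genomes, ~100 gene
clusters of 60 codons, 12 samples) keep full-pipeline runs in seconds
while leaving every category, habitat and selection contrast
represented; the acceptance script uses 100 random matrices, 1000
random depth vectors, 100 replicate genes and 100 clustering seeds.
Floats are written with `%.10g`; all tables are UTF-8, tab-delimited,
single header row, `#` comment lines carrying the seed. Reruns with the
same configuration are byte-identical, which is asserted in the test
suite.

## Known limitations

* The enrichment score test is asymptotic (see above) and is a
  documented stand-in for the original tool's test, not a
  bit-compatible reimplementation; likewise the per-gene pN/pS
  arithmetic documents its own site-counting convention rather than
  claiming equality with any specific variant-caller pipeline.
* Genus-level abundance inherits whatever reference bias exists in the
  genome collection; the module consumes the depths it is given and
  cannot correct upstream mapping choices.
* The ANOVA treats pN/pS values as homoscedastic observations; ratios
  from marginally covered genes are noisier, and coverage-weighted
  variants of the decomposition are out of scope.
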
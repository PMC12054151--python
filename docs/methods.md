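# Methods

This note documents the statistical conventions, the synthetic-data
model, and the design choices made where the underlying procedure left
room for interpretation.

## Coverage statistics

**Breadth** is the fraction of genome positions with depth ≥ 1.
Genome detection compares breadth to a threshold (default 0.5)
*inclusively* — "at least 50%" means a genome sitting exactly on the
boundary is detected. Gene detection is analogous but stricter: at
least 90% of the gene's nucleotides (1-based inclusive interval on the
genome) must reach the minimum depth (default 1×); the 90% boundary is
again inclusive. Strand is irrelevant to coverage and ignored.

**Q2Q3 mean depth.** Among several possible "interquartile mean"
conventions we use the symmetric midmean: sort the L per-position
depths, drop ⌊L/4⌋ from each tail, average the rest. This convention
is parameter-free, leaves a non-empty slice for every L ≥ 1 (for L < 4
nothing is trimmed and the midmean equals the plain mean), and has the
property the trim exists for: any inflation of the top-⌊L/4⌋ depths —
a mobile element recruiting reads from the whole community — leaves the
statistic exactly unchanged. Whether the upstream tooling's quartile
bounds are inclusive at exactly-Q1/Q3 values is not documented anywhere
we could rely on; the midmean is therefore a declared convention, not an
inference, and the test suite pins it against a brute-force
sort-and-slice oracle.

## Abundance

Two normalizations are deliberately kept separate:

* **Relative abundance** (heatmap-facing): zero the Q2Q3 depth of every
  undetected genome, then divide by the per-sample total of the zeroed
  values. Samples where nothing is detected yield all-zero rows rather
  than an error — empty mucosal samples are an expected biological
  outcome, not a failure. Species-level values are sums of member
  genome values and conserve per-sample totals to ≤ 1e−12.
* **Clade abundance** (classifier-facing): the raw sum of member Q2Q3
  depths, with no detection zeroing. The source procedure words the two
  metrics differently in different places; exposing both (the zeroing
  variant behind `zero_undetected=True` / `--zero-undetected`,
  default off) avoids silently conflating them.

Clade **prevalence** uses the max-breadth rule: a clade is detected in a
sample when its best-covered member genome reaches the breadth
threshold. Missing (genome, sample) rows are treated as depth 0,
breadth 0.

## Habitat classification

The site universe is the eight codes BM, KG, PT, SUBP, SUPP, SV, TD,
TH; the hard palate (HP) is excluded by default because a single sample
cannot support a group comparison (a custom universe can be passed).
All unordered bipartitions into two non-empty groups are enumerated —
2^(k−1) − 1 of them, 127 for k = 8; ordered duplicates are redundant
because both statistics are (anti)symmetric under group swap.

* The abundance statistic is the pooled-variance Student *t* (not
  Welch), positive when group 1's mean is higher.
* The prevalence statistic is the Rao score statistic for the group
  term of a binomial-logit GLM of detection on group membership, which
  for this one-binary-covariate design reduces to the Pearson χ² of the
  2×2 table, N(ad−bc)²/(n₁n₂m₁m₀). It is 0 whenever a margin is
  degenerate (all samples detected, or none).

Numerical edge cases, all deterministic: maps that leave a group with
zero samples (or t-test df < 1) are *skipped*, not scored 0 — scoring
them 0 could never change the winner but skipping keeps the reported
maximum honest. A zero pooled variance yields t = 0 for equal means
and signed infinity otherwise, so a perfect separation beats every
finite map. Ties in |statistic| break toward the map whose preferred
group has fewer sites, then lexicographically smaller codes —
parsimony first, then determinism. The preferred side is the group
with the higher mean abundance or detection proportion. A
"no preference" call (empty preferred set) is only made when a minimum
|statistic| is explicitly requested (`min_stat`); by default the best
map is always reported, since downstream grouping needs a label.

## Genome curation

QC keeps completeness ≥ 90 (inclusive) and contamination < 5 (strict),
matching the wording the thresholds come with ("at least" / "below").
Dereplication enforces the pairwise constraint — no retained pair above
98% ANI — via quality-ranked greedy selection: sort by completeness
(desc), contamination (asc), length (desc), id (asc); accept a
candidate iff it is within bounds of every genome already accepted.
The greedy rule is our choice (standard dereplication practice); the
pairwise constraint alone does not determine which member of a
redundant cluster survives, so a different rule could retain a slightly
different set of the same size structure. Asymmetric ANI inputs
(alignment-based methods are directional) are symmetrized by
elementwise maximum — the conservative direction, merging more.

## Enrichment

Function occurrence counts are binarized (presence = count ≥ 1) before
testing: the binomial family models per-genome presence, not copy
number. The per-function score is the same Rao/Pearson statistic as
above generalized to g groups ((g−1)-df χ²); pairwise contrasts are
obtained by re-running on group subsets. Module completeness is the
fraction of steps with ≥ 1 alternative present; the full nested
boolean grammar of module definitions is out of scope — modules are
supplied pre-flattened as step lists with comma-separated alternatives.
The multiple-testing adjustment is Benjamini–Hochberg (the convention
of the surrounding toolchain; delegated to
`statsmodels.stats.multitest`, pinned in tests against a brute-force
step-up implementation). Significance is strict q < 0.01.

## Sub-group structure

Ward linkage on Euclidean distances (scipy); for ANI input the feature
matrix is the rows of the symmetrized similarity matrix — the embedding
is a declared choice, since "cluster the ANI matrix" does not specify
one. The gap statistic follows Tibshirani–Walther–Hastie with the
simpler uniform-over-observed-range reference distribution:
Gap(k) = mean_B log W\*_k − log W_k, s_k scaled by √(1 + 1/B), optimal
k = smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1} (falling back to k_max
when the rule never fires). W_k is the total within-cluster sum of
squared distances to centroids, computed from the Ward labels.

## Synthetic-data generator

The generator emulates site-structured read-recruitment depth, the one
input the real study takes from large external downloads. Per
(genome, sample): a dropout fraction of positions (clade- and
site-specific) is forced to exactly zero at uniformly random positions,
modelling accessory regions absent from the local population and
producing partial breadth (realized breadth ≈ 1 − dropout at high
depth); of the remainder, an outlier fraction receives depth around
mean × multiplier, modelling mobile-element spikes; the rest draw from
Poisson (overdispersion a = 0) or negative binomial with variance
m + a·m² (mean/dispersion parameterization). No published depth
distribution exists for this pipeline, so the family is chosen to
exercise exactly what Q2Q3 is meant to resist. One global seed expands
into per-(genome, sample) substreams by hashing the id pair (BLAKE2b →
`SeedSequence`), so adding a sample never perturbs existing profiles.
Dropout is positionally independent; a block/contiguous dropout mode is
a non-goal. Reads, mapping and sequencing error are not simulated.

The default community (`default_community_config`) is three two-genome
clades over the eight classifier sites — a tongue-dorsum specialist, a
plaque (SUPP+SUBP) specialist, and a keratinized-gingiva specialist —
with mean depth 20 and 5% dropout at preferred sites (breadth ≈ 0.95,
well above the detection threshold) versus depth 0.5 and 50% dropout
elsewhere (breadth ≈ 0.2, below it), overdispersion 0.5, and 2% of
positions spiked at 25× the mean. These values are a deliberately
strong, clean preference signal: they represent the regime the
classifier is designed for (clear site tropism, as the real organisms
show), and recovery rates measured on them demonstrate correctness of
the machinery, not power under weak or confounded preferences. Genome
length defaults to 2,000 bp and validation runs use 20 samples per
site with ~100 replicate clades — sizes at which binomial noise in
breadth is negligible while a full replicate simulates and classifies
in under a second.

What passing tests on this generator do **not** show about real data:
cross-mapping between related genomes (competitive mapping artifacts),
compositional coupling between clades in a sample, uneven sample sizes
across sites (the real collection is highly unbalanced), and
non-uniform coverage along the genome beyond i.i.d. outliers.

## Pipeline

Stage order is curation → coverage → abundance → classification →
enrichment; each stage writes one headered TSV with stable column
order, and a manifest records config, version, stages and input
checksums, so identical inputs and config reproduce byte-identical
outputs. Enrichment groups genomes by the habitat label their clade
received from the abundance-metric classification (preferred-site set,
comma-joined) unless an explicit groups table is supplied.

## Known limitations

* The greedy dereplication representative choice is one of several
  defensible rules; collections dereplicated elsewhere may differ in
  membership (not in the pairwise guarantee).
* The classifier reports no significance for the winning map
  (enumeration maximizes a statistic; it is not a calibrated test), so
  `min_stat` is the only guard against classifying pure noise.
* Module definitions must be pre-flattened; complexes and nested
  alternatives are not parsed.
* The gap statistic uses the uniform reference only, not the principal
  -component-aligned variant.
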
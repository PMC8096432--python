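# Methods

This note records the models and procedures implemented in `metaprof`,
the defaults and why they hold, the numerical choices made where the
design was genuinely open, and the limits of what the synthetic
benchmarks demonstrate.

## Marker discovery

A species pangenome is the union of its genomes' gene families at 90%
protein identity, each family linked to a 50%-identity parent family.
Per family we compute:

- **coreness** — member genomes / species genomes, in [0, 1];
- **uniqueness90 / uniqueness50** — number of *other* species' pangenomes
  containing the family at each clustering tier (variants excluding
  low-quality species are also computed);
- **external_genomes90 / 50** — number of other-species *genomes*
  containing it.

Species whose names match a fixed regular expression (placeholder taxa:
"Candidatus", "_sp", "bacterium", symbionts, "unidentified", …) are
flagged low-quality; matching is case-sensitive and token-based on
underscore-separated names.

Candidate markers are families encoding 150–1500 aa proteins. Selection
iterates tier rounds A → B → C (U for single-genome species):

| tier | coreness | u90 | u50 | eg90 | eg50 |
|------|----------|-----|-----|------|------|
| A | > 0.80 | ≤ 2 | ≤ 2 | ≤ 10 | ≤ 5 |
| B | (0.70, 0.80] | ≤ 5 | ≤ 5 | < 15 | < 10 |
| C | (0.50, 0.70] | < 10 | < 15 | < 25 | < 20 |
| U | single genome | = 0 | = 0 | — | — |

After any round with more than 50 accumulated candidates, candidates are
ranked by `score = coreness × S_u(u50) × S_u(u90)` and up to 150 are
kept; otherwise the next tier's looser thresholds are tried. Species
ending with fewer than 10 markers are dropped. The uniqueness term
`S_u(u) = −log(1 − (10⁴ − min(10⁴, u))/10⁴ + 10⁻⁴) × 15`, clamped at
zero, is maximal (≈ 138.155) at u = 0 and decays log-shaped toward zero
at u = 10⁴; the 10⁻⁴ term regularizes the logarithm at u = 0. Coreness
enters as a fraction: a percentage scale would multiply every score by
100 and leave the ranking unchanged.

Boundary semantics are strict where the rules say "higher/lower than"
and inclusive where they say "of"; tier bands are disjoint by
construction (verified exhaustively over a coreness × uniqueness grid).

Marker externality refinement splits each marker into non-overlapping
150 bp chunks and searches them (both strands) against all other
species' genomes; a species containing any chunk verbatim joins the
marker's external-species list. Exact matching stands in for a
seed-and-extend mapper and is adequate for synthetic fixtures; the
interface also accepts an externally produced hit list so a real mapper
can substitute.

## Taxonomic profiling

Alignments are filtered (read length ≥ 70 nt, MAPQ ≥ 5); each read
contributes to exactly one marker (best MAPQ, then most aligned bases,
then smallest marker id). Marker depth is aligned bases / marker length
— true depth rather than read counts, making the estimate insensitive to
fragmentary alignments. The species coverage is the trimmed mean of its
full marker depth vector: zeros for unhit markers are included (a
species with few hit markers is thereby down-weighted), the vector is
sorted, and floor(stat_q · n) entries are removed from each end
(stat_q = 0.2). Trimming uses integer counts, not quantile
interpolation: it is deterministic and matches a sort-and-slice oracle
exactly.

Quasi-markers whose external-species list intersects the set of species
already detected through unique markers are excluded from their own
species' depth vector before trimming — their signal may come from the
external species. A species is reported only if more than a third of its
usable markers have nonzero depth (configurable detection threshold);
this suppresses false positives from isolated spurious alignments.

Internal-clade coverages are sums over detected descendant species;
relative abundance is 100 × coverage / rank total. The unknown fraction
estimates reads from taxa absent from the database:
`reads_explained = Σ coverage_t × genome_length_t / mean_read_length`,
`unknown = 100 × max(0, total − explained) / total`, with known
abundances rescaled to sum to 100 − unknown. The sample's empirical mean
read length is used, not a constant.

Profiles serialize to a MetaPhlAn-style TSV (taxonomy path, taxid path,
abundance, with an UNKNOWN row) and to the CAMI profiling format
(`@SampleID/@Version/@Ranks` headers and
`TAXID RANK TAXPATH TAXPATHSN PERCENTAGE` rows). Both writers round-trip
losslessly through their readers; the CAMI reader recovers the unknown
fraction as 100 minus the species-rank sum.

## Strain genotyping

Consensus calling takes the most frequent base per marker position.
A position is masked N when its mean base quality is below 30 or the
major allele accounts for less than 80% of observations; mean quality
was chosen as the column aggregation because the rule speaks of the
position's quality without naming a statistic, and the mean is the least
surprising choice for error-free synthetic data. Breadth counts called
(non-N) positions over the marker length, so ambiguous positions reduce
breadth exactly like uncovered ones. Markers with fewer than 8 reads or
breadth below 0.8 are rejected.

Sample/marker filtering alternates dropping samples with < 20 retained
markers and markers present in < 80% of remaining samples until a fixed
point; the two rules interact (dropping samples changes marker
prevalence), and iterating makes the result satisfy both
simultaneously. Consensus sequences are trimmed by 50 bases at each end
(mapping boundary effect) and concatenated in lexicographic marker
order; a sample missing a retained marker is N-padded rather than
dropped, since it already passed the 20-marker floor.

Distances are Kimura 2-parameter over sites where both sequences are
unambiguous; saturation (non-positive logarithm argument) raises rather
than returning a fabricated value. The built-in tree is neighbor-joining
with deterministic tie-breaking (smallest Q criterion, then the
lexicographically smallest pair); on additive matrices it reproduces the
input distances exactly, and an external MSA/ML-tree command can replace
the built-ins. Pairwise tree distances are normalized by the total
branch length, making them comparable across trees.

Transmission inference keeps one sample per subject (earliest timestamp,
ties by sample id; samples without metadata are singleton subjects) and
sets the strain-identity threshold at the first percentile of the
unrelated-pair distance distribution. The percentile uses the
**lower / nearest-rank** order statistic by default: with linear
interpolation the fraction of unrelated pairs strictly below the
threshold can exceed 1% by one pair (e.g. 18/1760 ≈ 1.02%), defeating
the bound that motivates the first-percentile rule; the nearest-rank
definition guarantees at most 1% for every sample count. Linear
interpolation remains available (`percentile_method="linear"`). Fewer
than 100 unrelated pairs triggers a warning (the percentile is then
unstable) but the threshold is still computed.

## Presence/absence strain typing

Family coverage is Σ(depth × gene length) over member genes divided by
the family's mean gene length — the numerator is a base count, so the
value is invariant to how alignments are fragmented, and for the common
single-copy case it equals the gene depth. The sorted (descending)
coverage curve of the nonzero families is summarized by its median
(plateau). A sample is *detectable* when the plateau reaches
`min_coverage = 2` and the curve values at the quartile edges (ranks
0.25k and 0.75k of the k nonzero families) stay within
`left_max = 1.25` and `right_min = 0.75` times the plateau: a steeply
decaying curve indicates reads scattered across the pangenome rather
than a resident strain. The quartile convention for the edge positions
is our choice — only the three multipliers are fixed by the method — and
is configurable. Within a detectable sample a family is present when its
coverage reaches half the plateau, with an absolute floor of
min_coverage/2; presence calls are monotone in coverage.

The clustering view filters families present in < 2 samples or absent in
≤ 5, then removes families present in > 95% or < 5% of the remainder,
computes Jaccard distances on rows and columns and applies Ward-linkage
hierarchical clustering with scipy's deterministic leaf order. The locus
test statistic for a gene group is Σ gene lengths / span along the
contig (1 for perfectly adjacent genes); the null redraws same-size gene
sets from the contig's genes, and `p = (1 + #{null ≥ observed}) /
(1 + n_permutations)` (add-one estimator, explicit seed). Under the null
the p-values are uniform (checked by a Kolmogorov-Smirnov test).

## Functional profiling

For each database sequence the union of hit intervals must cover at
least 50% of its positions or all its hits are discarded (boundary
inclusive); the filter applies separately to the nucleotide and
translated tiers and is idempotent and order-independent. Nucleotide
assignment gives each read to its best-scoring pangene (optionally split
equally among the up-to-k best, k = 5 mode); unassigned reads fall
through to translated search, where hits below 80% identity are dropped
and the survivors within 1% of the read's best score share its weight
equally. The protein-tier coverage filter runs before the identity
filter, mirroring the per-target semantics of the nucleotide tier. Equal
weight splitting (rather than score-weighted) keeps conservation exact
and simple: total assigned weight + unclassified + unmapped equals the
read count exactly at every tier.

Abundances are read weight per kilobase of family sequence (RPK),
stratified by the pangene's species, with translated-tier weight in an
"unclassified" stratum. Regrouping sums member families per stratum; a
family with several EC annotations contributes its full abundance to
each (multi-counting is what makes regrouping additive per stratum).
CPM renormalization scales community totals to 10⁶ with a single global
factor, so stratum proportions are unchanged and regroup/renormalize
commute up to that factor.

The gold standard for a synthetic community weights each genome's family
copy numbers by its per-base depth and applies the same length
normalization, so estimate and truth are on one scale.

## Synthetic data generator

The generator emulates the study conditions end to end: species
pangenomes with core families present in every genome (identical
sequence) and accessory families in random proper subsets; genes of
600–1500 nt (uniform, multiple of 3 — typical bacterial gene sizes)
laid on one contig with 60–150 nt spacers, ~30% on the minus strand;
optional cross-species family sharing to create quasi-marker candidates;
communities with log-normal(0, 1) cell-ratio abundances sampled
multinomially with probability ∝ abundance × genome length; uniform read
starts, random strands, independent substitution errors at a configurable
rate (0 for the exact-matching fixtures) with Phred qualities encoded to
match; strains derived by accessory-family excision followed by SNVs at
distinct positions within genes; transmission pairs share a byte-identical
strain. Two gold abundance scales are emitted — cell-ratio (what a
coverage-based profiler estimates) and read-fraction (what a
read-counting profiler estimates). All randomness flows from one seed and
outputs are byte-identical across runs.

Read tiling for per-marker fixtures has two modes: `random` (uniform
start positions, Poisson-like depth) and `uniform` (evenly spaced
starts). The presence/absence benchmark uses `uniform` at 4×: it models
the "uniform depth" condition directly, whereas Poisson sampling at 4×
leaves ~5% of 600 nt genes below the presence threshold through sampling
noise alone, which is a statement about sampling variance rather than
about the caller.

**What the generator does not emulate:** sequencing indels and
platform-specific error profiles, GC and positional coverage bias,
repeats and horizontal transfer within genomes (beyond the explicit
shared-family option), real pangenome openness, and read mapping
ambiguity from homologous regions — the built-in matcher only reports
exact full-read occurrences, so mapper-induced false placements are out
of scope. Passing benchmarks therefore demonstrates correctness of the
statistical machinery (depth estimation, trimming, thresholds, distances,
conservation), not robustness to real-data mapping noise.

## Problem sizes and defaults used in the validation scenarios

The validation suite runs at desk scale, chosen so each scenario
exercises every code path with comfortable statistical margins: 15
species × 50,000 reads for taxonomic recovery; all ≤ 6,188 depth
multisets of length ≤ 12 over a 5-value alphabet × 4 stat_q values for
the trimmed-mean oracle; 20 universes of 3–10 species (1–4 genomes each)
for the marker audit; 30 strains at 10× for consensus fidelity; 40
unrelated subjects + 10 transmission pairs for the threshold test; a
200-family pangenome with 10% accessory deletion at uniform 4× for
repertoire recovery; 10 species × 100,000 reads for EC recovery.

## Known limitations

- The exact matcher cannot place reads spanning gene boundaries, which
  biases per-gene depth low by a factor ≈ (L − r + 1)/L for gene length
  L and read length r; the unknown-fraction estimate absorbs this for
  taxonomic profiles, and EC-level Bray-Curtis carries a small residual
  (~0.95–0.97 rather than ~1.0).
- NJ is the built-in tree method; maximum-likelihood trees are supported
  only through the external command hook.
- The taxonomy handling assumes rank-complete lineages
  (kingdom → species); incomplete NCBI-style lineages would need rank
  imputation upstream.
- Consensus calling treats base qualities as given; it does not model
  mapping quality or indels (the concatenation layer raises on
  length-mismatched consensus as a signal that an external aligner is
  needed).
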
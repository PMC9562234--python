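# Methods

## Scope and coordinate conventions

`ervpop` operates downstream of the variant callers: its inputs are
per-individual insertion calls (discordant-read caller dialect), deletion
calls in two dialects (a read-depth caller carrying two p-value-like
`eval` scores, and a split-read caller carrying read support and a 0/1/2
genotype), BED intervals of ERV sequence similarity in the reference, and
a sample table (individual, species, island, hybrid flag, mean coverage).
It does not align reads or run callers.

All internal coordinates are 0-based half-open. BED is read and written
as-is; TSV call tables default to 1-based inclusive positions on disk
(flag `one_based`), matching how the upstream callers print them. Numeric
TSV columns accept both dot and comma decimal separators, because
published frequency tables in this literature print comma decimals; all
output uses dots. The split-read deletion dialect may arrive as a merged
multi-sample VCF (`INFO/END`, `INFO/PE`, `FORMAT/GT`), parsed with pysam;
records whose `END` precedes `POS` are rejected before parsing because
htslib silently drops the invalid field.

## Filter cascades

All printed thresholds are treated as inclusive, since the sources state
them without strictness qualifiers:

- insertion stringent: support reads ≥ 5, filter level ≥ 8 (the caller's
  ordinal confidence tier, 8 = highest), genotype quality in [10, 200],
  ≥ 2 clipped reads on each side;
- insertion relaxed (re-counting): support reads ≥ 1, filter level ≥ 5;
- read-depth deletions, stringent: eval1 ≤ 0.05, eval2 ≤ 0.05, length
  ≤ 20 kb; relaxed: eval1 ≤ 1, eval2 ≤ 1 with **no** length cap — the
  relaxed tier deliberately re-states only the score thresholds;
- split-read deletions (both tiers): length 90–20,000 bp, ≥ 2 supporting
  reads.

Filters are pure row selections: idempotent, order-independent, and the
relaxed survivors are a superset of the stringent survivors for every
dialect (property-tested over random call sets).

## Locus construction

Each stringent insertion call at position *p* becomes the window
[*p*−50, *p*+51) — a 101 bp window, since "extended by 50 bp in both
directions" does not state inclusivity and the symmetric closed extension
of a 1 bp point is the natural reading — clamped at the chromosome start.
Windows are transitively merged when they share ≥ 1 bp; touching
half-open intervals do **not** merge. Each merged locus is annotated with
the majority family among its constituent calls, ties broken by the
earliest call position then lexicographically, so annotation is
deterministic. Deletion-derived (assembly) loci are reduced the same way,
per dialect, with the family taken from the maximally-overlapping
similarity block (ties: lower block start, then family name).

The presence matrix counts, for each non-assembly locus and individual,
the relaxed calls whose window overlaps the locus; a call spanning two
adjacent loci counts in both. Relaxed calls that overlap no stringent
locus are discarded. For assembly loci an individual scores present (1)
unless a passing deletion call covering the locus shows *complete*
absence: any read-depth deletion, or a split-read genotype of 2. A
heterozygous split-read deletion leaves one ERV-bearing haplotype, so the
individual still counts as a carrier at the binary level.

## Frequencies and the fixed-locus calibration

Frequencies are individual-level detection frequencies (carriers /
group size), not allele frequencies: the callers report presence. Fixed
candidates are loci with frequency > 0 in every in-scope group; the scope
defaults to focal species plus outgroups, excluding hybrid groups (the
fixed-locus argument concerns locus age relative to speciation, and
hybrid groups are not lineages). The false-negative rate is 1 minus the
mean (over candidate loci) of the per-locus grand mean of group
frequencies; the grand-mean-of-group-means convention weights species
equally regardless of sample size.

The calibration restricts candidates to non-assembly loci. Assembly-side
presence is scored by the absence of a deletion call, so its error mode
is a false *positive* (a missed deletion call turns a non-carrier into an
apparent carrier); polymorphic assembly loci therefore tend to appear at
low frequency in every group and would bias the estimated miss rate
upward if admitted. The calibration measures the miss rate of insertion
detection, which is what the non-assembly loci carry.

## Abundance and MIR

Relative abundance divides an individual's identification counts per
family by the individual's total; counts (not binary presence) are used
because the statistic is defined on numbers of identifications.
Individuals with zero identifications are dropped with a warning. MIR is
the group median over the all-samples median of relative abundance,
NaN where the denominator median is 0; medians of even-sized groups use
the midpoint convention. The modified MIR replaces the global denominator
with the island population's own species, so a species sampled on a
single island is identically 1. Two diagnostic regressions are provided:
per-family identifications on per-family locus counts, and per-individual
fixed-locus detection rate on mean coverage (the interpretable reading of
a coverage-sensitivity regression; both use ordinary least squares with
the slope's t-distribution p-value).

## Segregation screens

Sharing classes partition loci by the number of groups with frequency
> 0: all groups, several, exactly one (private), or none (undetected —
possible when a locus is defined by stringent calls from an individual
whose relaxed calls fail to map back, vanishingly rare in practice).
Chromosome density uses locus midpoints, counts both locus sources
identically, and reports loci/Mbp per chromosome, a binned positional
profile, a pooled terminal-vs-interior density ratio (terminal window =
10% of each chromosome arm by default), and the pairwise relative density
difference |d_i − d_j| / min(d_i, d_j).

The differentiated-region screen intersects loci with externally supplied
region intervals by any-overlap and reports every in-region locus with
|f_A − f_B| ≥ `contrast_min_delta` between the configured species pair,
sorted by the signed difference. The default cutoff of 0.4 was chosen so
that the smallest published contrast (0.42) passes; whether the original
selection used a threshold, a high/low frequency band, or curation is not
stated, so the threshold rule is exposed as configuration. The
mid-species frequency is reported for inspection but never filtered on —
its intermediacy is an observation, not a criterion.

Welch's t (Satterthwaite degrees of freedom, two-sided) and one-way ANOVA
are thin wrappers over `scipy.stats`, with explicit degenerate-input
handling (identical constant groups return the zero statistic instead of
float noise) and with independent long-hand formula oracles in the test
suite.

## Synthetic cohort generator

The generator emulates the study conditions of a multi-species island
radiation, not read-level sequencing:

- **Structure.** `n_species` focal species (default 5) × islands (2) ×
  individuals per population (10), optional outgroup species; per-sample
  mean coverage uniform on 6–49×.
- **Loci.** A backbone of ancestral fixed loci (homozygous in everyone,
  outgroups included) plus polymorphic loci. Positions are drawn across a
  five-chromosome genome (532 Mbp total) proportional to length, with a
  configurable excess of density in the terminal 10% of each chromosome
  (default factor 2, reflecting observed chromosome-end enrichment) and a
  minimum spacing of 250 bp so distinct simulated loci cannot merge
  downstream. Family assignment follows Zipf weights (exponent 1),
  because real ERV family sizes are heavily skewed.
- **Polymorphism.** Each polymorphic locus is assigned a carrier subset
  of the focal species — never all of them, mirroring the observation
  that segregating loci are missing from at least one species — with the
  subset size geometrically distributed towards 1. Within each carrier
  island population the insertion allele frequency is Beta(0.8, 2)
  (low-skewed), and individual zygosities are Hardy–Weinberg draws.
  Optional per-species family-enrichment multipliers reweight carrier
  species selection, producing family bursts concentrated in one lineage.
- **Detection.** Per individual × carried locus, an independent Bernoulli
  draw: homozygotes detected at 1 − 0.08 regardless of coverage (a single
  flat miss rate is the simplest model consistent with a
  coverage-independent calibration on fixed loci; it is also extended
  below 4× rather than guessing an unstated low-coverage behaviour);
  heterozygotes on the line through (4×, 0.45) and (30×, 1.0), clamped to
  [0, 1] and flat above saturation. Emitted insertion calls always pass
  the relaxed filter and pass the stringent filter with probability 0.8.
  About 2.6% of loci (the observed assembly-side share, 698/26,964) are
  represented inversely: non-carriers emit deletion calls (the read-depth
  dialect only for homozygous absence; the split-read dialect with
  genotype 2 − copy number, at 491:207 dialect odds) plus one similarity
  block per locus.

What the generator does **not** model: correlated detection failures
(each call is an independent draw), solo-LTR vs full-provirus states,
selection or drift over generations, read-level artefacts, and reference
bias. Passing recovery tests therefore demonstrates that the pipeline's
arithmetic and bookkeeping are correct under the stated detection model,
not that the model captures every failure mode of real short-read data.

## Problem sizes and numerics

The recovery analyses use a 300-individual cohort (5 species × 2 islands
× 30) with 300 fixed and 700 polymorphic loci — large enough that the
binomial standard error of the calibration (~0.001) is well inside the
±0.01 assessment band — and 50 individuals × 300 heterozygous loci
(15,000 pairs, s.e. ≈ 0.4 percentage points) for the 4× heterozygous miss
percentage. Interval merging is a sort-and-sweep over cumulative maxima,
checked against an O(n²) transitive-merge oracle on 1,000 random call
sets; locus assignment uses binary search over the sorted non-overlapping
locus intervals. All randomness flows through `numpy.random.default_rng`
seeded from a single integer; identical seeds reproduce identical
cohorts, call tables, and downstream results.

## Known limitations

- The false-negative calibration assumes fixed candidates are truly
  fixed; in small cohorts a polymorphic locus segregating in every
  in-scope group would bias the estimate upward (the generator's
  carrier-subset rule removes this case from the simulated conditions,
  but real data offer no such guarantee).
- Assembly-side presence inherits the false-positive error mode described
  above; its frequencies are upper bounds.
- The relaxed re-count can only confirm loci already defined by stringent
  calls; genuinely relaxed-only loci are invisible by design.
- MIR is undefined for families absent from more than half of all
  samples (zero global median), and unstable for very small groups.
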
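# Methods

## Problem setting

A long-read *de novo* assembly of a repeat-rich genome is a bag of
contigs: unordered, unoriented, partially redundant (duplicate contigs,
overlapping tilings) and sprinkled with repeat-induced ambiguity. Given
a related reference assembly, `digiscaff` places those contigs along
reference chromosomes using alignment evidence only, and extracts a
*minimal complete scaffold*: a smallest ordered contig selection whose
alignments linearly cover the chromosome. No consensus is built, no
orientation is assigned, and no gap is filled — the output is an
ordering plus a coverage estimate, intended for rapid screening and
annotation triage rather than assembly finishing.

## Queries and ranks

Probes are cut from the reference, never from the draft assembly:

* **gene-queries**: annotated `gene` features with span strictly greater
  than `min_gene_len` (default 2500 nt; the strict inequality is
  deliberate — a 2500 nt gene is excluded). Only `gene`-type GFF3
  features are used; transcripts and exons are ignored. The probe
  sequence is always the forward strand regardless of annotation strand,
  since the aligner recovers minus-strand placements on its own and the
  scaffold never assigns orientations.
* **ranked-queries**: fragments of length `fragment_len` (default
  4000 nt) starting at multiples of `fragment_len + spacing` (spacing
  5000 nt for dense scans of a scaffold, 20,000 nt for chromosome-scale
  runs). A trailing fragment shorter than `fragment_len` is dropped by
  default so every query has the same coverage denominator;
  `--keep-partial` overrides.

The rank — 0-based order along the source sequence — is encoded in the
FASTA header as `{seq_id}|r{rank}|{start}-{end}` (0-based half-open), so
every downstream step can recover chromosome order from headers alone.

## Alignment layer

BLAST+ (`makeblastdb` + `blastn`, tabular `-outfmt 6`) is the production
aligner; defaults are task `blastn` with e-value 1e-10, appropriate for
≥ 2.5 kb near-identical probes where stringency suppresses short
spurious hits. Raw hits are never merged at this layer, keeping the
evidence auditable.

A built-in exact-seed aligner (`oracle_align`) indexes subject k-mers
(k = `min_seed`, ≥ 12), extends each seed maximally in both directions,
and reports maximal exact matches of the query and its reverse
complement as 100%-identity hits with BLAST coordinate conventions
(1-based inclusive; minus-strand hits have `s_start > s_end`). It exists
as an independent reference implementation for the test suite and as a
BLAST-free path for high-identity data; it is not a general aligner (no
mismatches, no gaps).

## Coverage, tiers, and the positive-cell grid

For each (query, subject) pair all hit intervals are unioned on the
query axis; the pair's `covered_fraction` is union length over query
length. This is the redundancy filter: a repeat inside a query can hit
the same contig many times without inflating coverage beyond 1.

A successive-threshold schedule — descending tiers, default (0.90, 0.80,
0.70, 0.50) — assigns each pair the highest tier its coverage meets;
pairs below the last tier are discarded. The schedule is fully
configurable: the default is this package's own concrete choice, and a
different schedule will change which borderline pairs survive. Matrix
rows (contigs with ≥ 1 positive cell) are sorted by leftmost positive
rank, then longest rank span, then id — the tie-breaks are a convention
chosen for determinism.

## Minimal complete scaffold

Each contig is summarized by its positive-rank interval
[min rank, max rank]. Selection is the classic greedy furthest-reach
interval cover over the set of positive ranks: from the first uncovered
positive rank, among contigs whose interval contains it, pick the one
reaching furthest right (ties: earlier start, then lexicographically
smaller id); continue past its reach. Greedy is provably
minimum-cardinality on gapless interval instances, which the test suite
verifies exhaustively on small instances and against brute-force subset
search on random ones. Rank runs with no positive cell anywhere are
recorded as explicit gaps — a draft assembly need not cover the whole
chromosome.

Cells of selected contigs are classified **red**, all other positive
cells **blue**. Because a contig's interval is the full [min, max] span
of its positive ranks, every cell of a selected contig lies inside its
selected interval; blue cells therefore always belong to unselected
(redundant or repeat-carrying) contigs.

**Linear coverage.** Selected rank intervals that overlap *or abut*
(consecutive ranks are physically consecutive along the chromosome)
merge into runs; each run spans from its first query's start to its last
query's end in reference coordinates, and the union of run spans is
divided by the full chromosome length (not the query footprint). Spacing
between consecutive covered queries inside a run is counted as covered —
one defensible reading of a "linear" estimate; the alternative (counting
only query footprints) would scale the estimate by roughly
`fragment_len / (fragment_len + spacing)`.

**Repeat flagging.** Per rank, the number of distinct contigs with a
positive cell is a local redundancy signal. A rank is flagged when (a)
it lies in at least one window of `window` consecutive ranks (default 5)
whose mean distinct-contig count is ≥ `min_contigs` (default 4), and (b)
it is itself positive. Condition (a) suppresses isolated one-rank
spikes; condition (b) stops a flagged region from bleeding into hit-less
flanks. Maximal runs of flagged ranks are reported.

## Read splitting and homopolymer census

Reads are cut into non-overlapping k-mers (default k = 250) at offsets
0, k, 2k, …, qualities sliced in lockstep; the trailing remainder < k is
dropped by default ("split evenly" read as equal-length pieces), with
`--keep-remainder` emitting it as a short final record. Conservation
holds exactly: emitted bases equal Σ⌊L/k⌋·k.

The census counts, per base, the fraction of k-mers containing a run of
≥ `run_len` (default 10) identical bases, each k-mer counting at most
once per base. A 10 nt homopolymer is a negligible feature of a 20 kb
read but a substantial one of a 250-mer, which is why the census is
reported alongside splitting: such k-mers are the error-prone input of
short-read-style polishing.

## Run statistics

The run table has one MinION (MIN) reference run and n Flongle (FLG)
replicate runs per line. Because only a single MIN value exists per
parameter, FLG-vs-MIN comparisons are one-sample t-tests of the n FLG
values against the MIN value as a fixed reference:
t = (x̄ − μ₀)/(s/√n), df = n − 1, two-sided p. Read and base counts are
log2-transformed first (the formats differ by an order of magnitude; on
the raw scale the MIN reference would sit tens of standard deviations
out for trivial reasons of scale). Paired two-sample t-tests (matched
conditions such as two basecalling models on the same runs) reduce to a
one-sample t of the differences. The two-way repeated-measures ANOVA is
the classic univariate decomposition with subject error strata — each
within-subject effect tested against its own effect × subject
interaction (Error(subject/(A·B)) in R's `aov` notation); it requires a
complete balanced design and is validated in the tests against an
explicit sums-of-squares partition. t statistics and p-values are
computed via scipy (`ttest_1samp`, `ttest_rel`) and the ANOVA via
statsmodels `AnovaRM`; the test suite cross-checks them against exact
rational arithmetic with a 60-digit Decimal incomplete-beta evaluation,
and against the sums-of-squares partition, respectively.

Derived throughput metrics (`table1_summary`) are plain ratios of the
table's totals: FLG output as a percentage of MIN output, each format's
share of total bases/reads/input fmoles (partition shares sum to 100%),
mean FLG input, the top-two FLG runs' contribution, and per-pore FLG
output in Mb over a stated total pore count (default 250, i.e. five
Flongles averaging ~50 usable pores).

The packaged run table (`data/gb_ls_coga4_runs.tsv`) is the printed
summary of the GB-ls-coga4 *D. suzukii* sequencing experiment, with
units normalized to integers of bases/reads and GB of file size. Its
inputs are rounded to the precision of the printed report, so statistics
recomputed from it carry that rounding (e.g. the log2-bases reference
33.9496 vs the printed 33.949).

## Synthetic data

The generator is a pure function of (parameters, seed) via numpy's
`default_rng`; identical calls give identical bytes.

* `simulate_genome`: i.i.d. background at a given GC fraction (default
  0.42, a typical drosophilid value) with planted repeat families —
  tandem (dispersion 0: abutting copies in one block) or dispersed
  (random non-overlapping placements); copy positions recorded.
* `fragment_into_contigs`: contiguous tiling with jittered breakpoints,
  per-contig 3′ extension by a sampled overlap, a `dup_rate` fraction
  re-emitted (randomly reverse-complemented) as duplicates, shuffled
  output order, full truth map.
* `simulate_annotation`: one gene per equal-width slot (non-overlap by
  construction) with a stated fraction of spans ≤ 2500 nt to exercise
  the gene-length filter.
* `simulate_reads`: error-free reference substrings with uniform
  qualities and uniformly drawn lengths.

What this does *not* emulate: sequencing errors (no indel/substitution
model), chimeric reads, heterozygosity, assembly mis-joins, or diverged
repeat copies. Passing the parameter-recovery tests therefore shows the
pipeline's logic is correct on clean evidence — order recovery, cover
minimality, coverage arithmetic — not that it is robust to noisy
alignments; on real data that robustness is delegated to BLAST and the
tier schedule. Default test scale (120–500 kb genomes, 8–30 contigs,
~50–120 queries, ≤ 300 reads) keeps the full suite fast while leaving
every code path exercised at realistic shape ratios.

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open internally; the BLAST tabular
  dialect's 1-based inclusive convention is preserved at file
  boundaries, and minus-strand subject intervals stay descending.
* Zero-variance samples (one-sample t, paired t with identical
  differences) raise a degenerate-input error rather than returning
  NaN/inf.
* An empty matrix yields an empty scaffold with coverage 0 rather than
  an error; an empty query set refuses serialization.
* Coverage fractions are exact rational ratios of integer base counts
  evaluated in floats; ties between equal-reach contigs resolve by
  start then id, making the whole pipeline byte-deterministic.

## Known limitations

* The tier schedule is a package default, not a calibrated constant;
  chromosome-scale results on real assemblies depend on it.
* The minimal scaffold is minimal per gapless run of the observed
  positive ranks; it inherits any ambiguity of [min, max] interval
  summarization when a contig's hits are widely split (e.g. a genuine
  translocation would be silently spanned).
* The exact-seed aligner finds only exact matches; with mismatched or
  gapped homology it understates coverage and is unsuitable beyond
  high-identity settings.
* `run_blast` shells out to BLAST+ and inherits its version-dependent
  tie behaviour in bitscores; the scaffold layer does not depend on
  bitscores except as a recorded maximum.
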
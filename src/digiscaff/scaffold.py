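"""Core scaffolding: coverage filtering, contig ordering, minimal cover.

The pipeline turns raw alignment hits into an incidence grid of *positive
cells* — (contig, query-rank) pairs where the query is covered above a
threshold tier — then selects a smallest ordered set of contigs whose
rank intervals cover the grid (the *minimal complete scaffold*), and
estimates the fraction of the reference chromosome that selection covers
linearly.

Per-pair filtering keeps one coverage record per (query, subject) pair:
all hits between the pair are unioned on the query axis, so repeat-driven
multi-hits never double-count.  A successive-threshold schedule (default
tiers 0.90, 0.80, 0.70, 0.50 of query coverage) assigns each pair the
highest tier it meets; pairs below the last tier are discarded.

Contig orientation is never assigned: the scaffold orders contigs along
the chromosome without deciding strands or building consensus sequence.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from digiscaff.alignment import AlignmentHit
from digiscaff.errors import InputDataError, ParameterError
from digiscaff.queries import Query, parse_query_id

DEFAULT_TIERS = (0.90, 0.80, 0.70, 0.50)


@dataclass(frozen=True)
class QueryCoverage:
    """Unioned alignment coverage for one (query, subject) pair."""

    query_id: str
    subject_id: str
    covered_fraction: float
    best_bitscore: float
    n_hits: int


@dataclass
class ContigQueryMatrix:
    """Incidence grid: queries on the X-axis (by rank), contigs on the Y-axis.

    ``positives`` maps ``(subject_id, rank)`` to the threshold tier the
    pair passed.
    """

    queries: list[Query]
    contigs: list[str]
    positives: dict[tuple[str, int], float]

    def contig_interval(self, subject_id: str) -> tuple[int, int]:
        ranks = [r for (c, r) in self.positives if c == subject_id]
        return (min(ranks), max(ranks))

    def ranks_of(self, subject_id: str) -> list[int]:
        return sorted(r for (c, r) in self.positives if c == subject_id)

    def covered_ranks(self) -> list[int]:
        return sorted({r for (_, r) in self.positives})


@dataclass
class MinimalScaffold:
    """An ordered contig selection giving linear coverage of the reference.

    ``selected`` holds ``(subject_id, first_rank, last_rank)`` sorted by
    first rank; ``classification`` colours every positive cell red
    (selected contig) or blue (redundant / repeat evidence); ``gaps`` are
    maximal rank runs between covered ranks with no positive cell.
    """

    selected: list[tuple[str, int, int]]
    coverage_pct: float
    classification: dict[tuple[str, int], str]
    gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def selected_contigs(self) -> list[str]:
        return [c for c, _, _ in self.selected]


# ---------------------------------------------------------------------------
# coverage


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of a union of 1-based inclusive intervals."""
    total = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end >= start:
            total += end - start + 1
            last_end = end
        last_end = max(last_end, end)
    return total


def compute_query_coverage(
    hits: Sequence[AlignmentHit], queries: Sequence[Query]
) -> list[QueryCoverage]:
    """Union hit intervals per (query, subject) pair on the query axis.

    ``covered_fraction`` is union length over query length — overlapping
    hits never double-count.
    """
    length_by_id = {q.query_id: q.length for q in queries}
    grouped: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for hit in hits:
        qlen = length_by_id.get(hit.query_id)
        if qlen is None:
            raise InputDataError(f"hit references unknown query {hit.query_id!r}")
        if not (1 <= hit.q_start <= hit.q_end <= qlen):
            raise InputDataError(
                f"hit interval [{hit.q_start},{hit.q_end}] outside query "
                f"{hit.query_id!r} of length {qlen}"
            )
        grouped[(hit.query_id, hit.subject_id)].append(hit)

    coverages = []
    for (query_id, subject_id), pair_hits in grouped.items():
        union = _union_length([(h.q_start, h.q_end) for h in pair_hits])
        coverages.append(
            QueryCoverage(
                query_id=query_id,
                subject_id=subject_id,
                covered_fraction=union / length_by_id[query_id],
                best_bitscore=max(h.bitscore for h in pair_hits),
                n_hits=len(pair_hits),
            )
        )
    return coverages


def filter_by_thresholds(
    coverages: Sequence[QueryCoverage],
    queries: Sequence[Query],
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> ContigQueryMatrix:
    """Assign each pair the highest coverage tier it meets.

    Pairs below the lowest tier are discarded.  The matrix lists every
    query as a column (even hit-less ones) and only contigs with at least
    one positive cell as rows.
    """
    tiers = tuple(tiers)
    if not tiers or any(not (0 < t <= 1) for t in tiers):
        raise ParameterError(f"tiers must lie in (0, 1], got {tiers}")
    if any(nxt >= prev for nxt, prev in zip(tiers[1:], tiers)):
        raise ParameterError(f"tiers must be strictly descending, got {tiers}")

    rank_by_id = {q.query_id: q.rank for q in queries}
    positives: dict[tuple[str, int], float] = {}
    for cov in coverages:
        rank = rank_by_id.get(cov.query_id)
        if rank is None:
            raise InputDataError(f"coverage references unknown query {cov.query_id!r}")
        tier = next((t for t in tiers if cov.covered_fraction >= t), None)
        if tier is None:
            continue
        key = (cov.subject_id, rank)
        positives[key] = max(positives.get(key, 0.0), tier)

    contigs = sorted({c for (c, _) in positives})
    ordered_queries = sorted(queries, key=lambda q: q.rank)
    return ContigQueryMatrix(ordered_queries, contigs, positives)


def order_contigs(matrix: ContigQueryMatrix) -> ContigQueryMatrix:
    """Sort contig rows by (leftmost positive rank asc, rightmost rank
    desc, subject_id); the longest-reaching contig at a position comes
    first."""
    if not matrix.contigs:
        raise InputDataError("cannot order an empty matrix")

    def key(subject_id: str):
        first, last = matrix.contig_interval(subject_id)
        return (first, -last, subject_id)

    ordered = sorted(matrix.contigs, key=key)
    return ContigQueryMatrix(matrix.queries, ordered, dict(matrix.positives))


# ---------------------------------------------------------------------------
# mapped-contigs grid file


def write_mapped_contigs(matrix: ContigQueryMatrix, path: str | Path) -> None:
    """Write the incidence grid as CSV: one row per contig (Y-axis order),
    one column per query in rank order; positive cells carry their tier."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["contig"] + [q.query_id for q in matrix.queries])
        for contig in matrix.contigs:
            row = [contig]
            for q in matrix.queries:
                tier = matrix.positives.get((contig, q.rank))
                row.append("" if tier is None else f"{tier:g}")
            writer.writerow(row)


def read_mapped_contigs(path: str | Path) -> ContigQueryMatrix:
    """Read a grid written by :func:`write_mapped_contigs`.

    Query columns are rebuilt from their rank-encoded header ids; the
    probe sequences themselves are not stored in the grid.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        queries = []
        for qid in header[1:]:
            seq_id, rank, start, end = parse_query_id(qid)
            queries.append(Query(qid, seq_id, start, end, rank, "ranked", ""))
        contigs = []
        positives: dict[tuple[str, int], float] = {}
        for row in reader:
            contig = row[0]
            contigs.append(contig)
            for q, cell in zip(queries, row[1:]):
                if cell:
                    positives[(contig, q.rank)] = float(cell)
    return ContigQueryMatrix(queries, contigs, positives)


# ---------------------------------------------------------------------------
# minimal complete scaffold


def select_minimal_scaffold(
    matrix: ContigQueryMatrix,
    ref_length: int | None = None,
) -> MinimalScaffold:
    """Greedy furthest-reach interval cover over query ranks.

    From the first uncovered positive rank, among contigs whose rank
    interval contains it, pick the one extending furthest right (ties:
    earlier start, then lexicographic id); repeat from the next rank past
    its reach.  Rank runs with no positive cell at all are recorded as
    gaps.  Cells of selected contigs are classified red, all remaining
    positive cells blue.
    """
    covered = matrix.covered_ranks()
    if not covered:
        return MinimalScaffold([], 0.0, {})

    intervals = {c: matrix.contig_interval(c) for c in matrix.contigs}
    selected: list[tuple[str, int, int]] = []
    chosen: set[str] = set()
    i = 0
    while i < len(covered):
        r = covered[i]
        candidates = [
            (c, first, last)
            for c, (first, last) in intervals.items()
            if first <= r <= last and c not in chosen
        ]
        # every positive rank lies inside the interval of at least one contig
        contig, first, last = min(candidates, key=lambda t: (-t[2], t[1], t[0]))
        selected.append((contig, first, last))
        chosen.add(contig)
        while i < len(covered) and covered[i] <= last:
            i += 1

    selected.sort(key=lambda t: (t[1], t[2], t[0]))

    gaps = []
    for prev, nxt in zip(covered, covered[1:]):
        if nxt > prev + 1:
            gaps.append((prev + 1, nxt - 1))

    classification = {
        cell: ("red" if cell[0] in chosen else "blue") for cell in matrix.positives
    }
    scaffold = MinimalScaffold(selected, 0.0, classification, gaps)
    if ref_length is not None:
        scaffold.coverage_pct = linear_coverage_pct(scaffold, matrix.queries, ref_length)
    return scaffold


def linear_coverage_pct(
    scaffold: MinimalScaffold, queries: Sequence[Query], ref_length: int
) -> float:
    """Percent of the reference linearly covered by the selected contigs.

    Selected rank intervals that overlap or abut (consecutive ranks are
    consecutive along the chromosome) merge into runs; each run spans
    from the start of its first query to the end of its last query in
    reference coordinates, and the union of run spans is divided by the
    full reference length.
    """
    if not scaffold.selected:
        return 0.0
    by_rank = {q.rank: q for q in queries}
    max_rank = max(q.rank for q in queries)
    for _, first, last in scaffold.selected:
        if first not in by_rank or last not in by_rank or last > max_rank:
            raise InputDataError("selected interval references unknown query ranks")

    # merge rank-adjacent or overlapping intervals into runs
    runs: list[list[int]] = []
    for _, first, last in scaffold.selected:
        if runs and first <= runs[-1][1] + 1:
            runs[-1][1] = max(runs[-1][1], last)
        else:
            runs.append([first, last])

    spans = [(by_rank[first].start, by_rank[last].end) for first, last in runs]
    spans.sort()
    union = 0
    last_end = 0
    for start, end in spans:
        start = max(start, last_end)
        if end > start:
            union += end - start
        last_end = max(last_end, end)
    return 100.0 * union / ref_length


def flag_repeat_regions(
    matrix: ContigQueryMatrix, window: int = 5, min_contigs: int = 4
) -> list[tuple[int, int]]:
    """Flag rank runs where many distinct contigs pile onto each query.

    A rank is flagged when it is positive and lies in at least one
    length-``window`` rank window whose mean distinct-contig count is
    >= ``min_contigs``; maximal runs of flagged ranks are returned.  The
    window condition suppresses isolated multi-hit spikes while the
    positivity condition keeps the flagged run from bleeding into
    hit-less flanks.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if not matrix.queries:
        return []
    max_rank = max(q.rank for q in matrix.queries)
    counts = [0] * (max_rank + 1)
    per_rank: dict[int, set[str]] = defaultdict(set)
    for contig, rank in matrix.positives:
        per_rank[rank].add(contig)
    for rank, contigs in per_rank.items():
        counts[rank] = len(contigs)

    n = len(counts)
    window = min(window, n)
    qualifying = [False] * n  # rank belongs to some qualifying window
    for start in range(0, n - window + 1):
        mean = sum(counts[start : start + window]) / window
        if mean >= min_contigs:
            for r in range(start, start + window):
                qualifying[r] = True

    flagged = [r for r in range(n) if qualifying[r] and counts[r] >= 1]
    regions: list[tuple[int, int]] = []
    for r in flagged:
        if regions and r == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], r)
        else:
            regions.append((r, r))
    return regions


# ---------------------------------------------------------------------------
# plotting


def plot_grid(
    matrix: ContigQueryMatrix,
    scaffold: MinimalScaffold | None = None,
    path: str | Path = "mapped_contigs.png",
    red_only: bool = False,
) -> None:
    """Render the incidence grid: contigs on Y, query ranks on X; red
    cells mark the minimal scaffold, blue cells redundant hits.

    ``red_only`` restricts rows to the selected contigs, reproducing a
    minimal-scaffold-only view; the title reports the linear coverage
    estimate when a scaffold is supplied.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classification: Mapping[tuple[str, int], str]
    if scaffold is not None:
        classification = scaffold.classification
    else:
        classification = {cell: "blue" for cell in matrix.positives}

    contigs = matrix.contigs
    if red_only:
        if scaffold is None:
            raise ParameterError("red_only plotting requires a scaffold")
        keep = set(scaffold.selected_contigs)
        contigs = [c for c in contigs if c in keep]

    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.12 * (len(matrix.queries) + 1)), max(3.0, 0.25 * (len(contigs) + 1)))
    )
    ypos = {c: i for i, c in enumerate(contigs)}
    for (contig, rank), _tier in matrix.positives.items():
        if contig not in ypos:
            continue
        color = "red" if classification.get((contig, rank)) == "red" else "blue"
        ax.scatter(rank, ypos[contig], marker="s", s=36, c=color, linewidths=0)
    ax.set_yticks(range(len(contigs)))
    ax.set_yticklabels(contigs, fontsize=6)
    ax.set_xlabel("query rank")
    ax.set_ylabel("contig")
    ax.invert_yaxis()
    if scaffold is not None:
        ax.set_title(f"linear coverage estimate: {scaffold.coverage_pct:.3f}%")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
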
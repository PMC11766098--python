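"""Synthetic genomes, contig sets, annotations and reads with ground truth.

Every generator is a pure function of its parameters and an explicit
seed, so fixtures are reproducible byte-for-byte.  The simulated data
emulate the situations the scaffolding pipeline must handle: a
chromosome with planted tandem or dispersed repeat families (the driver
of multi-mapping "blue" cells), a contig set sampled from it with
overlaps and optional duplicates (redundant draft assemblies), a gene
annotation mixing spans above and below the gene-query length filter,
and long reads of varying length for the splitting pipeline.

Reads are error-free substrings: downstream tests need exact identity
between planted and recovered coordinates, not an error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from digiscaff.alignment import reverse_complement
from digiscaff.errors import ParameterError
from digiscaff.queries import GeneAnnotation, ReferenceSequence
from digiscaff.splitkit import ReadRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatFamily:
    """A planted repeat family: ``dispersion`` 0 lays copies in tandem,
    otherwise copies are scattered at random positions."""

    unit_len: int
    copies: int
    dispersion: int = 0


@dataclass(frozen=True)
class ContigTruth:
    """True placement of one simulated contig on its source sequence."""

    contig_id: str
    source_id: str
    start: int  # 0-based half-open on the reference
    end: int
    strand: str
    is_duplicate: bool
    duplicate_of: str | None = None


@dataclass(frozen=True)
class RepeatTruth:
    family_id: str
    unit_len: int
    positions: tuple[int, ...]  # 0-based start of each planted copy


@dataclass
class TruthMap:
    """Ground truth shared by the generators, keyed by record id."""

    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    repeats: list[RepeatTruth] = field(default_factory=list)
    genes: list[GeneAnnotation] = field(default_factory=list)

    def true_order(self) -> list[str]:
        """Non-duplicate contig ids by true start coordinate."""
        originals = [c for c in self.contigs.values() if not c.is_duplicate]
        return [c.contig_id for c in sorted(originals, key=lambda c: c.start)]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_id\tsource_id\tstart\tend\tstrand\tis_duplicate\tduplicate_of\n")
            for c in self.contigs.values():
                fh.write(
                    f"{c.contig_id}\t{c.source_id}\t{c.start}\t{c.end}\t{c.strand}\t"
                    f"{int(c.is_duplicate)}\t{c.duplicate_of or ''}\n"
                )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_genome(
    length: int,
    repeat_families: Sequence[RepeatFamily] = (),
    gc: float = 0.42,
    seed: int = 0,
    seq_id: str = "chrSim",
) -> tuple[ReferenceSequence, TruthMap]:
    """An i.i.d. background sequence with repeat copies planted at
    recorded positions."""
    if repeat_families and length < 10 * max(f.unit_len for f in repeat_families):
        raise ParameterError("genome length must be >= 10x the largest repeat unit")
    planted_total = sum(f.unit_len * f.copies for f in repeat_families)
    if planted_total > length // 2:
        raise ParameterError("repeat families exceed half the genome length")

    rng = np.random.default_rng(seed)
    seq = list(_random_sequence(rng, length, gc))
    truth = TruthMap()
    occupied: list[tuple[int, int]] = []

    for fam_idx, fam in enumerate(repeat_families):
        unit = _random_sequence(rng, fam.unit_len, gc)
        positions: list[int] = []
        if fam.dispersion == 0:
            # tandem: one block of abutting copies
            block = fam.unit_len * fam.copies
            start = _place(rng, length, block, occupied)
            occupied.append((start, start + block))
            positions = [start + i * fam.unit_len for i in range(fam.copies)]
        else:
            for _ in range(fam.copies):
                start = _place(rng, length, fam.unit_len, occupied)
                occupied.append((start, start + fam.unit_len))
                positions.append(start)
        for pos in positions:
            seq[pos : pos + fam.unit_len] = unit
        truth.repeats.append(
            RepeatTruth(f"fam{fam_idx}", fam.unit_len, tuple(sorted(positions)))
        )

    return ReferenceSequence(seq_id, "".join(seq)), truth


def _place(
    rng: np.random.Generator, length: int, width: int, occupied: list[tuple[int, int]],
    max_tries: int = 1000,
) -> int:
    for _ in range(max_tries):
        start = int(rng.integers(0, length - width + 1))
        if all(start + width <= lo or start >= hi for lo, hi in occupied):
            return start
    raise ParameterError("could not place repeat copy without overlap; genome too small")


def fragment_into_contigs(
    ref: ReferenceSequence,
    n_contigs: int,
    overlap: int | tuple[int, int] = 0,
    dup_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReferenceSequence], TruthMap]:
    """Tile the reference into ``n_contigs`` contigs with sampled
    overlaps; a ``dup_rate`` fraction are re-emitted (randomly
    reverse-complemented) as duplicates; output order is shuffled.
    """
    if n_contigs < 1:
        raise ParameterError(f"n_contigs must be >= 1, got {n_contigs}")
    if n_contigs > ref.length:
        raise ParameterError(f"cannot tile {ref.length} bases into {n_contigs} contigs")
    if isinstance(overlap, int):
        ov_lo, ov_hi = overlap, overlap
    else:
        ov_lo, ov_hi = overlap
    if ov_lo < 0 or ov_hi < ov_lo:
        raise ParameterError(f"bad overlap range ({ov_lo}, {ov_hi})")

    rng = np.random.default_rng(seed)
    # contiguous breakpoints with jitter around an even grid
    bounds = [0]
    step = ref.length / n_contigs
    for i in range(1, n_contigs):
        center = i * step
        jitter = rng.uniform(-0.25, 0.25) * step
        bounds.append(int(round(center + jitter)))
    bounds.append(ref.length)
    bounds = sorted(set(bounds))
    if len(bounds) != n_contigs + 1:
        raise ParameterError("tiling infeasible: contigs would collapse to zero length")

    truth = TruthMap()
    contigs: list[ReferenceSequence] = []
    for i in range(n_contigs):
        start = bounds[i]
        ov = int(rng.integers(ov_lo, ov_hi + 1)) if ov_hi > 0 else ov_lo
        end = min(bounds[i + 1] + ov, ref.length)
        cid = f"tig{i:05d}"
        contigs.append(ReferenceSequence(cid, ref.sequence[start:end]))
        truth.contigs[cid] = ContigTruth(cid, ref.seq_id, start, end, "+", False)

    n_dups = round(dup_rate * n_contigs)
    dup_sources = rng.choice(n_contigs, size=n_dups, replace=False)
    for j, src_idx in enumerate(sorted(int(s) for s in dup_sources)):
        src = contigs[src_idx]
        src_truth = truth.contigs[src.seq_id]
        flip = bool(rng.integers(0, 2))
        seq = reverse_complement(src.sequence) if flip else src.sequence
        cid = f"tig{n_contigs + j:05d}_dup"
        contigs.append(ReferenceSequence(cid, seq))
        truth.contigs[cid] = ContigTruth(
            cid, ref.seq_id, src_truth.start, src_truth.end,
            "-" if flip else "+", True, duplicate_of=src.seq_id,
        )

    order = rng.permutation(len(contigs))
    return [contigs[int(i)] for i in order], truth


def simulate_annotation(
    ref: ReferenceSequence,
    n_genes: int,
    span_range: tuple[int, int] = (2501, 8000),
    short_fraction: float = 0.3,
    short_span_range: tuple[int, int] = (500, 2500),
    seed: int = 0,
) -> list[GeneAnnotation]:
    """Non-overlapping gene features; a ``short_fraction`` of them have
    spans at or below 2500 nt to exercise the gene-length filter.

    Genes are placed one per equal-width slot so non-overlap is
    guaranteed by construction.
    """
    if n_genes == 0:
        return []
    slot = ref.length // n_genes
    if slot <= max(span_range[1], short_span_range[1]):
        raise ParameterError(
            f"cannot place {n_genes} non-overlapping genes of span <= "
            f"{max(span_range[1], short_span_range[1])} in {ref.length} bases"
        )
    rng = np.random.default_rng(seed)
    n_short = round(short_fraction * n_genes)
    short_slots = set(int(i) for i in rng.choice(n_genes, size=n_short, replace=False))

    genes = []
    for i in range(n_genes):
        lo, hi = short_span_range if i in short_slots else span_range
        span = int(rng.integers(lo, hi + 1))
        slack = slot - span
        offset = int(rng.integers(0, slack)) if slack > 0 else 0
        start = i * slot + offset + 1  # 1-based inclusive
        end = start + span - 1
        strand = "+" if rng.integers(0, 2) else "-"
        genes.append(GeneAnnotation(f"gene{i:04d}", ref.seq_id, start, end, strand))
    return genes


def write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\tsynthgen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def simulate_reads(
    ref: ReferenceSequence,
    n_reads: int,
    length_range: tuple[int, int] = (300, 5000),
    seed: int = 0,
    quality_char: str = "I",
) -> list[ReadRecord]:
    """Error-free substrings of the reference with uniform qualities and
    uniformly drawn lengths."""
    if n_reads < 1:
        raise ParameterError(f"n_reads must be >= 1, got {n_reads}")
    lo, hi = length_range
    if lo < 1 or hi < lo or hi > ref.length:
        raise ParameterError(f"bad read length range ({lo}, {hi}) for reference of "
                             f"length {ref.length}")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, ref.length - length + 1))
        reads.append(
            ReadRecord(
                f"read{i:06d}",
                ref.sequence[start : start + length],
                quality_char * length,
            )
        )
    return reads
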
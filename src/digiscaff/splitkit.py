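"""Fixed-length read splitting and homopolymer census.

Long nanopore reads are split evenly into non-overlapping k-mers
(default k = 250) so that polishing tools designed around short reads
can consume them; base qualities are sliced in lockstep.  A trailing
remainder shorter than k is dropped by default (``keep_remainder``
emits it as a final short record).

Nanopore chemistry is error-prone on homopolymer runs, and a run that
is long relative to a 250-mer weighs heavily on polishing — the census
counts, per base, the fraction of k-mers containing a run of at least
``run_len`` (default 10) identical bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from digiscaff.errors import ParameterError, ParseError

DEFAULT_K = 250
DEFAULT_RUN_LEN = 10
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record; quality is the per-base Phred string."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SplitSummary:
    """Bookkeeping for one splitting pass."""

    n_reads_in: int = 0
    n_kmers_out: int = 0
    bases_out: int = 0
    bases_dropped: int = 0
    homopolymer_fraction: dict[str, float] = field(default_factory=dict)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") or "r")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTQ records (gzip-transparent)."""
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(title.split()[0], seq.upper(), qual)
        except ValueError as exc:
            raise ParseError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def split_read(read: ReadRecord, k: int = DEFAULT_K, keep_remainder: bool = False) -> list[ReadRecord]:
    """Split one read into k-mers at offsets 0, k, 2k, ...; child ids are
    ``{read_id}/p{index}``."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    pieces = []
    n_full = len(read) // k
    for idx in range(n_full):
        lo, hi = idx * k, (idx + 1) * k
        pieces.append(ReadRecord(f"{read.read_id}/p{idx}", read.sequence[lo:hi], read.quality[lo:hi]))
    if keep_remainder and len(read) % k:
        lo = n_full * k
        pieces.append(ReadRecord(f"{read.read_id}/p{n_full}", read.sequence[lo:], read.quality[lo:]))
    return pieces


def split_reads(
    reads: Iterable[ReadRecord],
    k: int = DEFAULT_K,
    keep_remainder: bool = False,
) -> tuple[list[ReadRecord], SplitSummary]:
    """Split a read stream; returns all k-mers and a summary.

    Base conservation: without the remainder, ``bases_out`` equals
    ``sum(floor(L_i / k) * k)`` over input reads.
    """
    summary = SplitSummary()
    kmers: list[ReadRecord] = []
    for read in reads:
        summary.n_reads_in += 1
        pieces = split_read(read, k=k, keep_remainder=keep_remainder)
        emitted = sum(len(p) for p in pieces)
        summary.n_kmers_out += len(pieces)
        summary.bases_out += emitted
        summary.bases_dropped += len(read) - emitted
        kmers.extend(pieces)
    return kmers, summary


def homopolymer_census(
    kmers: Iterable[ReadRecord | str], run_len: int = DEFAULT_RUN_LEN
) -> dict[str, float]:
    """Per base, the fraction of k-mers containing >= ``run_len``
    consecutive copies of that base (each k-mer counts at most once per
    base)."""
    if run_len < 2:
        raise ParameterError(f"run_len must be >= 2, got {run_len}")
    needles = {base: base * run_len for base in BASES}
    counts = {base: 0 for base in BASES}
    total = 0
    for kmer in kmers:
        seq = kmer if isinstance(kmer, str) else kmer.sequence
        total += 1
        for base, needle in needles.items():
            if needle in seq:
                counts[base] += 1
    if total == 0:
        return {base: 0.0 for base in BASES}
    return {base: counts[base] / total for base in BASES}


def split_fastq_file(
    in_path: str | Path,
    out_path: str | Path,
    k: int = DEFAULT_K,
    run_len: int = DEFAULT_RUN_LEN,
    keep_remainder: bool = False,
) -> SplitSummary:
    """File-level pipeline: split a FASTQ, write the k-mers, run the census."""
    kmers, summary = split_reads(read_fastq(in_path), k=k, keep_remainder=keep_remainder)
    write_fastq(kmers, out_path)
    summary.homopolymer_fraction = homopolymer_census(kmers, run_len=run_len)
    return summary
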
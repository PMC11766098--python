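"""Query-vs-contig alignment: BLAST+ driving, tabular parsing, seed oracle.

Alignments travel as 12-column BLAST tabular records (``-outfmt 6``):
qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend, sstart,
send, evalue, bitscore.  All coordinates in the tabular dialect are
1-based inclusive; a hit on the subject minus strand has
``s_start > s_end``.

``oracle_align`` is an exact-match seed-and-extend aligner used as an
independent reference in tests and as a fallback when BLAST+ is absent:
it reports maximal exact matches (both strands) above a seed length with
the same record layout and coordinate conventions as ``parse_tabular``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from digiscaff.errors import InputDataError, MissingToolError, ParameterError, ParseError
from digiscaff.queries import Query, ReferenceSequence

TABULAR_COLUMNS = (
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST-tabular alignment record."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    @property
    def is_minus_strand(self) -> bool:
        return self.s_start > self.s_end

    def to_tabular(self) -> str:
        return "\t".join(
            (
                self.query_id,
                self.subject_id,
                f"{self.pct_identity:.3f}",
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.evalue:.2g}",
                f"{self.bitscore:.1f}",
            )
        )


def parse_tabular(source: str | Path | IO[str] | Iterable[str]) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output; ``#`` comment lines skipped."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_tabular(fh)
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ParseError(
                f"expected 12 tab-separated columns, found {len(fields)}", lineno
            )
        try:
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"unparseable numeric field: {exc}", lineno) from exc
    return hits


def write_tabular(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.to_tabular() + "\n")


# ---------------------------------------------------------------------------
# external BLAST+


def run_blast(
    query_fasta: str | Path,
    contig_fasta: str | Path,
    evalue: float = 1e-10,
    task: str = "blastn",
    threads: int = 1,
) -> list[AlignmentHit]:
    """Align queries against contigs with NCBI BLAST+ (makeblastdb + blastn).

    The subject database is built in a temporary workspace.  Queries are
    long (>= 2.5 kb) near-identical sequences, so a stringent default
    e-value keeps spurious short hits out.
    """
    for exe in ("makeblastdb", "blastn"):
        if shutil.which(exe) is None:
            raise MissingToolError(
                f"NCBI BLAST+ executable {exe!r} not found on PATH; "
                "install BLAST+ or use the oracle aligner"
            )
    query_fasta, contig_fasta = Path(query_fasta), Path(contig_fasta)
    for p in (query_fasta, contig_fasta):
        if not p.exists() or p.stat().st_size == 0:
            raise InputDataError(f"FASTA file missing or empty: {p}")

    with tempfile.TemporaryDirectory(prefix="digiscaff_blast_") as tmp:
        db = str(Path(tmp) / "subjectdb")
        subprocess.run(
            ["makeblastdb", "-in", str(contig_fasta), "-dbtype", "nucl", "-out", db],
            check=True, capture_output=True, text=True,
        )
        proc = subprocess.run(
            [
                "blastn", "-task", task, "-query", str(query_fasta), "-db", db,
                "-outfmt", "6", "-evalue", str(evalue),
                "-num_threads", str(threads),
            ],
            check=True, capture_output=True, text=True,
        )
    return parse_tabular(proc.stdout.splitlines())


# ---------------------------------------------------------------------------
# internal exact-seed aligner


def oracle_align(
    query: Query, subject: ReferenceSequence, min_seed: int = 12
) -> list[AlignmentHit]:
    """Report maximal exact matches of the query (both strands) in the
    subject, as 100%-identity hits.

    Seeds of length ``min_seed`` are indexed over the subject and extended
    maximally in both directions; duplicate extensions collapse to one hit.
    """
    if min_seed < 12:
        raise ParameterError(f"min_seed must be >= 12, got {min_seed}")
    hits: list[AlignmentHit] = []
    hits.extend(_exact_hits(query.query_id, query.sequence, subject, min_seed, "+"))
    hits.extend(
        _exact_hits(query.query_id, reverse_complement(query.sequence), subject, min_seed, "-")
    )
    return hits


def _exact_hits(
    query_id: str, qseq: str, subject: ReferenceSequence, k: int, strand: str
) -> list[AlignmentHit]:
    sseq = subject.sequence
    if len(qseq) < k or len(sseq) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(sseq) - k + 1):
        index.setdefault(sseq[j : j + k], []).append(j)

    seen: set[tuple[int, int, int, int]] = set()
    out: list[AlignmentHit] = []
    for i in range(len(qseq) - k + 1):
        for j in index.get(qseq[i : i + k], ()):
            # extend the seed maximally on both sides
            qs, ss = i, j
            while qs > 0 and ss > 0 and qseq[qs - 1] == sseq[ss - 1]:
                qs -= 1
                ss -= 1
            qe, se = i + k, j + k
            while qe < len(qseq) and se < len(sseq) and qseq[qe] == sseq[se]:
                qe += 1
                se += 1
            key = (qs, qe, ss, se)
            if key in seen:
                continue
            seen.add(key)
            length = qe - qs
            if strand == "+":
                q_start, q_end = qs + 1, qe
                s_start, s_end = ss + 1, se
            else:
                # qseq is the reverse complement: map back to forward query
                # coordinates; the subject interval is reported descending.
                q_start, q_end = len(qseq) - qe + 1, len(qseq) - qs
                s_start, s_end = se, ss + 1
            out.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=subject.seq_id,
                    pct_identity=100.0,
                    aln_length=length,
                    mismatches=0,
                    gap_opens=0,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=0.0,
                    bitscore=round(1.9 * length, 1),
                )
            )
    return out
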
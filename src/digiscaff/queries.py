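"""Query construction: gene-queries and ranked-queries from a reference.

A *query* is a reference-derived probe sequence used as BLAST bait against
a collection of draft-assembly contigs.  Two flavours exist:

* **gene-queries** — the sequences of annotated genes longer than a
  minimum span (default 2500 nt), in start-coordinate order;
* **ranked-queries** — fixed-length genomic fragments (default 4000 nt)
  extracted at a regular spacing (default 20,000 nt) along a chromosome.

Each query carries a *rank*: its 0-based order along the source sequence.
The rank is encoded in the FASTA header (``{seq_id}|r{rank}|{start}-{end}``,
coordinates 0-based half-open) so that downstream ordering is recoverable
from headers alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from digiscaff.errors import InputDataError, ParameterError, ParseError

DEFAULT_MIN_GENE_LEN = 2500
DEFAULT_FRAGMENT_LEN = 4000
DEFAULT_SPACING = 20000

_QUERY_ID_RE = re.compile(r"^(?P<seq_id>.+)\|r(?P<rank>\d+)\|(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class ReferenceSequence:
    """A named nucleotide sequence (chromosome, scaffold or contig)."""

    seq_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene feature, 1-based inclusive coordinates as in GFF3."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Query:
    """A ranked probe sequence; coordinates 0-based half-open."""

    query_id: str
    seq_id: str
    start: int
    end: int
    rank: int
    kind: str  # "gene" or "ranked"
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def make_query_id(seq_id: str, rank: int, start: int, end: int) -> str:
    return f"{seq_id}|r{rank}|{start}-{end}"


def parse_query_id(query_id: str) -> tuple[str, int, int, int]:
    """Recover ``(seq_id, rank, start, end)`` from a rank-encoded header."""
    m = _QUERY_ID_RE.match(query_id)
    if m is None:
        raise ParseError(f"not a rank-encoded query id: {query_id!r}")
    return (m["seq_id"], int(m["rank"]), int(m["start"]), int(m["end"]))


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    records = [
        ReferenceSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path, width: int = 80) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_gff3_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read features of type ``gene`` from a GFF3 file.

    Other feature types (mRNA, exon, ...) are ignored.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    annotations = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        annotations.append(
            GeneAnnotation(gene_id, feat.seqid, feat.start, feat.end, feat.strand or "+")
        )
    return annotations


# ---------------------------------------------------------------------------
# extraction


def extract_gene_queries(
    refs: Sequence[ReferenceSequence],
    annotations: Sequence[GeneAnnotation],
    min_gene_len: int = DEFAULT_MIN_GENE_LEN,
) -> list[Query]:
    """Build gene-queries: one per annotated gene strictly longer than
    ``min_gene_len``, ranked by start coordinate within each sequence.

    Sequences are always taken from the forward strand; BLAST recovers
    minus-strand placements on its own and no orientation is assigned.
    """
    by_id = {r.seq_id: r for r in refs}
    kept: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        ref = by_id.get(ann.seq_id)
        if ref is None:
            raise InputDataError(
                f"annotation {ann.gene_id!r} references unknown sequence {ann.seq_id!r}"
            )
        if not (1 <= ann.start <= ann.end <= ref.length):
            raise InputDataError(
                f"annotation {ann.gene_id!r} ({ann.start}-{ann.end}) exceeds bounds of "
                f"{ann.seq_id!r} (length {ref.length})"
            )
        if ann.span > min_gene_len:
            kept.setdefault(ann.seq_id, []).append(ann)

    queries: list[Query] = []
    for seq_id in sorted(kept):
        ref = by_id[seq_id]
        for rank, ann in enumerate(sorted(kept[seq_id], key=lambda a: (a.start, a.end))):
            start, end = ann.start - 1, ann.end  # to 0-based half-open
            queries.append(
                Query(
                    query_id=make_query_id(seq_id, rank, start, end),
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    rank=rank,
                    kind="gene",
                    sequence=ref.sequence[start:end],
                )
            )
    return queries


def extract_ranked_queries(
    ref: ReferenceSequence,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    spacing: int = DEFAULT_SPACING,
    keep_partial: bool = False,
) -> list[Query]:
    """Extract regularly spaced fixed-length fragments along ``ref``.

    Fragments start at 0, ``fragment_len + spacing``, ``2*(fragment_len +
    spacing)``, ...  By default only full-length fragments are emitted; a
    trailing partial fragment is kept only with ``keep_partial=True``.
    """
    if fragment_len <= 0:
        raise ParameterError(f"fragment_len must be >= 1, got {fragment_len}")
    if spacing < 0:
        raise ParameterError(f"spacing must be >= 0, got {spacing}")

    step = fragment_len + spacing
    queries: list[Query] = []
    rank = 0
    for start in range(0, ref.length, step):
        end = start + fragment_len
        if end > ref.length:
            if not keep_partial or start >= ref.length:
                break
            end = ref.length
        queries.append(
            Query(
                query_id=make_query_id(ref.seq_id, rank, start, end),
                seq_id=ref.seq_id,
                start=start,
                end=end,
                rank=rank,
                kind="ranked",
                sequence=ref.sequence[start:end],
            )
        )
        rank += 1
    return queries


# ---------------------------------------------------------------------------
# query FASTA round-trip


def write_queries(queries: Sequence[Query], path: str | Path) -> None:
    """Serialize queries as FASTA; the header is the rank-encoded query id
    plus a ``kind=`` tag in the description."""
    if not queries:
        raise InputDataError("refusing to write an empty query set")
    records = [
        SeqRecord(Seq(q.sequence), id=q.query_id, description=f"kind={q.kind}")
        for q in queries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_queries(path: str | Path) -> list[Query]:
    queries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, rank, start, end = parse_query_id(rec.id)
        kind = "ranked"
        for token in rec.description.split():
            if token.startswith("kind="):
                kind = token[len("kind="):]
        queries.append(
            Query(rec.id, seq_id, start, end, rank, kind, str(rec.seq).upper())
        )
    return queries
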
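"""Readers/writers for the sequence and tabular formats shared by all stages.

Sequences live in a single canonical alphabet per record: mature/precursor
miRNA references are RNA (``U``), genomic and transcript sequences are DNA
(``T``).  :func:`to_rna` / :func:`to_dna` convert explicitly at module
boundaries; the two letters are never mixed inside one record.

Tag-count tables (unique small-RNA sequence x per-library raw count) are the
central in-memory container downstream of read cleaning; they are stored as a
pandas DataFrame with the tag sequence as index and one integer column per
library label.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "TagCountTable",
    "to_rna",
    "to_dna",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tag_table",
    "write_tag_table",
    "write_gff3",
]

MISSING = "."


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    description: str = ""
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def to_rna(seq: str) -> str:
    """Canonicalize to the RNA alphabet (T -> U, uppercase). Idempotent."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Canonicalize to the DNA alphabet (U -> T, uppercase). Idempotent."""
    return seq.upper().replace("U", "T")


_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement in the sequence's own alphabet."""
    table = _RNA_COMP if "U" in seq else _DNA_COMP
    return seq.translate(table)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime pinned so identical content gives identical bytes
            import io

            raw = gzip.GzipFile(filename="", mode="wb", mtime=0,
                                fileobj=open(path, "wb"))
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Multi-line sequences are concatenated; the text after the first
    whitespace of the header is kept in ``description``, separate from ``id``.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) 4-line-record FASTQ file."""
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                break
            seq_line = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            lineno += 4
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record near line {lineno}")
            head, seq_line = head.rstrip("\n"), seq_line.rstrip("\n")
            plus, qual = plus.rstrip("\n"), qual.rstrip("\n")
            if not head.startswith("@"):
                raise FormatError(f"{path}: line {lineno - 3}: expected '@' header")
            if not plus.startswith("+"):
                raise FormatError(f"{path}: line {lineno - 1}: expected '+' separator")
            ident, _, desc = head[1:].partition(" ")
            if len(qual) != len(seq_line):
                raise FormatError(
                    f"{path}: record {ident!r}: quality/sequence length mismatch"
                )
            records.append(
                SequenceRecord(id=ident, seq=seq_line.upper(), description=desc, qual=qual)
            )
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


@dataclass
class TagCountTable:
    """Unique small-RNA tags with one raw count per library.

    ``counts`` is indexed by tag sequence with one non-negative integer
    column per library label, in library order.
    """

    counts: pd.DataFrame
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(self.counts.columns)
        self.counts = self.counts[self.labels].astype(int)
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate tag {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative tag count")

    @classmethod
    def from_counter(cls, per_library: dict[str, dict[str, int]],
                     labels: Sequence[str] | None = None) -> "TagCountTable":
        labels = list(labels) if labels is not None else list(per_library)
        df = pd.DataFrame(per_library).reindex(columns=labels).fillna(0).astype(int)
        df.index.name = "tag"
        return cls(df, labels)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def library_total(self, label: str) -> int:
        return int(self.counts[label].sum())

    def total_counts(self) -> pd.Series:
        """Per-tag count summed over libraries."""
        return self.counts.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagCountTable):
            return NotImplemented
        return self.labels == other.labels and self.counts.equals(other.counts)


def write_tag_table(table: TagCountTable, path: str | Path) -> None:
    """Write a tag table as TSV: one ``tag`` column plus a column per library."""
    out = table.counts.copy()
    out.index.name = "tag"
    out.to_csv(path, sep="\t")


def read_tag_table(path: str | Path) -> TagCountTable:
    df = pd.read_csv(path, sep="\t", index_col="tag", dtype={"tag": str})
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate tag")
    return TagCountTable(df.astype(int), list(df.columns))


def write_gff3(features: Iterable[dict], path: str | Path, source: str = "stressmir") -> None:
    """Write GFF3 (1-based inclusive coordinates).

    Each feature dict needs ``seqid, start, end, strand, type, attributes``
    (attributes: dict rendered as ``k=v`` pairs).
    """
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        str(f["seqid"]), source, f.get("type", "region"),
                        str(f["start"]), str(f["end"]), MISSING,
                        f.get("strand", "+"), MISSING, attrs or MISSING,
                    ]
                )
                + "\n"
            )
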
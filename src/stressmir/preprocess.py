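"""Raw-read cleaning, tag collapsing and descriptive small-RNA profiles.

Cleaning removes the 3' adapter (located by an exact match of its first
8 nt), drops adapter-less and polyA reads, applies the 18-30 nt length
window and collapses survivors into unique tags with per-library counts.
The module also computes the two standard descriptive profiles of a
small-RNA library -- the read-length distribution and the 5'-nucleotide
bias -- and exact-match genome mapping counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import SequenceRecord, TagCountTable, revcomp, to_dna

__all__ = [
    "CleaningSummary",
    "clean_reads",
    "clean_libraries",
    "length_distribution",
    "first_nt_bias",
    "map_to_genome",
]

ADAPTER_SEED_LEN = 8
POLYA_FRACTION = 0.8


@dataclass
class CleaningSummary:
    """Per-library read accounting of the cleaning step."""

    raw_reads: int = 0
    adaptors_removed: int = 0       # reads discarded for missing adapter
    too_short_removed: int = 0      # trimmed length < min_len
    too_long_removed: int = 0       # trimmed length > max_len
    polya_removed: int = 0
    clean_reads: int = 0
    mapped_total: int = 0
    mapped_unique: int = 0

    def check_conservation(self) -> bool:
        return self.raw_reads == (
            self.clean_reads + self.adaptors_removed + self.too_short_removed
            + self.too_long_removed + self.polya_removed
        )


def _trim_adapter(seq: str, adapter_seed: str) -> str | None:
    pos = seq.find(adapter_seed)
    return None if pos < 0 else seq[:pos]


def clean_reads(records: Iterable[SequenceRecord], adapter: str,
                min_len: int = 18, max_len: int = 30,
                keep_untrimmed: bool = False
                ) -> tuple[dict[str, int], CleaningSummary]:
    """Trim, filter and collapse one library's reads into tag counts.

    ``keep_untrimmed`` admits reads without an adapter hit at full length
    (for pre-trimmed input); by default they are discarded and counted
    under ``adaptors_removed``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(adapter) < ADAPTER_SEED_LEN:
        raise ValueError(
            f"adapter must be at least {ADAPTER_SEED_LEN} nt (seed length)")
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")

    seed = to_dna(adapter)[:ADAPTER_SEED_LEN]
    counts: Counter[str] = Counter()
    summary = CleaningSummary()
    for rec in records:
        summary.raw_reads += 1
        seq = to_dna(rec.seq)
        insert = _trim_adapter(seq, seed)
        if insert is None:
            if keep_untrimmed:
                insert = seq
            else:
                summary.adaptors_removed += 1
                continue
        if insert and insert.count("A") / len(insert) >= POLYA_FRACTION:
            summary.polya_removed += 1
            continue
        if len(insert) < min_len:
            summary.too_short_removed += 1
            continue
        if len(insert) > max_len:
            summary.too_long_removed += 1
            continue
        counts[insert] += 1
        summary.clean_reads += 1
    return dict(counts), summary


def clean_libraries(libraries: dict[str, Iterable[SequenceRecord]],
                    adapter: str, min_len: int = 18, max_len: int = 30,
                    keep_untrimmed: bool = False
                    ) -> tuple[TagCountTable, dict[str, CleaningSummary]]:
    """Clean every library and assemble the joint tag-count table."""
    per_lib: dict[str, dict[str, int]] = {}
    summaries: dict[str, CleaningSummary] = {}
    for label, records in libraries.items():
        per_lib[label], summaries[label] = clean_reads(
            records, adapter, min_len, max_len, keep_untrimmed)
    return TagCountTable.from_counter(per_lib, list(libraries)), summaries


def length_distribution(table: TagCountTable, unique: bool = False) -> pd.Series:
    """Fraction of reads (or of unique tags) per tag length.

    Count-weighted over all libraries by default; ``unique=True`` weights
    every tag once.
    """
    if not table.tags:
        raise ValueError("empty tag table")
    lengths = pd.Series([len(t) for t in table.tags], index=table.counts.index)
    weights = pd.Series(1, index=table.counts.index) if unique \
        else table.total_counts()
    dist = weights.groupby(lengths).sum()
    return dist / dist.sum()


def first_nt_bias(table: TagCountTable) -> pd.DataFrame:
    """Per-length fractions of the 5' nucleotide (RNA alphabet, U not T)."""
    if not table.tags:
        raise ValueError("empty tag table")
    idx = table.counts.index
    lengths = pd.Series([len(t) for t in idx], index=idx)
    first = pd.Series([("U" if t[0] == "T" else t[0]) for t in idx], index=idx)
    weights = table.total_counts()
    out = weights.groupby([lengths, first]).sum().unstack(fill_value=0)
    out = out.reindex(columns=["A", "C", "G", "U"], fill_value=0)
    return out.div(out.sum(axis=1), axis=0)


def map_to_genome(table: TagCountTable, genome: SequenceRecord | Sequence[SequenceRecord]
                  ) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Exact-substring genome mapping of every tag, both strands.

    Returns a per-tag hit table (list of 1-based (seqid, start, strand)
    hits, hit count) and per-library mapping totals: ``mapped_total`` sums
    the counts of tags with at least one hit, ``mapped_unique`` counts
    such tags.
    """
    genomes = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    seqs = [(g.id, to_dna(g.seq)) for g in genomes]

    hits_per_tag: list[list[tuple[str, int, str]]] = []
    for tag in table.tags:
        fwd = to_dna(tag)
        rev = revcomp(fwd)
        hits: list[tuple[str, int, str]] = []
        for seqid, gseq in seqs:
            for query, strand in ((fwd, "+"), (rev, "-")):
                start = gseq.find(query)
                while start >= 0:
                    hits.append((seqid, start + 1, strand))
                    start = gseq.find(query, start + 1)
        hits_per_tag.append(hits)

    annotated = pd.DataFrame(
        {"n_hits": [len(h) for h in hits_per_tag], "hits": hits_per_tag},
        index=table.counts.index,
    )
    mapped_mask = annotated["n_hits"] > 0
    stats = {}
    for label in table.labels:
        col = table.counts[label]
        stats[label] = {
            "mapped_total": int(col[mapped_mask].sum()),
            "mapped_unique": int(((col > 0) & mapped_mask).sum()),
        }
    return annotated, stats
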
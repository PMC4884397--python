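"""Known-miRNA identification and counting from collapsed tags.

A tag is assigned to a known miRNA under two criteria applied in order:
an exact, full-length, mismatch-free match to the miRNA precursor, and at
least a 16-nt overlap between the tag's precursor interval and the
annotated mature interval (5'/3' offsets are otherwise unrestricted).
Tags satisfying both contribute their raw count to that miRNA; a miRNA is
"identified" in a library when its count there is positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import SequenceRecord, TagCountTable, to_rna

__all__ = [
    "MiRNARef",
    "MiRNACount",
    "load_refs",
    "expand_slash_group",
    "match_precursor",
    "overlaps_mature",
    "quantify_known",
    "family_rollup",
]

DEFAULT_MIN_OVERLAP = 16

_FAMILY_RE = re.compile(r"(miR\d+)", re.IGNORECASE)


@dataclass
class MiRNARef:
    """One known miRNA: precursor, mature, and the mature's offset."""

    name: str
    precursor_seq: str
    mature_seq: str
    mature_start: int  # 1-based offset of mature within precursor
    family: str = ""

    def __post_init__(self) -> None:
        self.precursor_seq = to_rna(self.precursor_seq)
        self.mature_seq = to_rna(self.mature_seq)
        s = self.mature_start - 1
        if self.precursor_seq[s:s + len(self.mature_seq)] != self.mature_seq:
            raise ValueError(
                f"{self.name}: mature is not at precursor offset {self.mature_start}")
        if not 18 <= len(self.mature_seq) <= 26:
            raise ValueError(f"{self.name}: mature length outside 18-26 nt")
        if not self.family:
            m = _FAMILY_RE.search(self.name)
            self.family = m.group(1) if m else self.name

    @property
    def mature_end(self) -> int:
        return self.mature_start + len(self.mature_seq) - 1


@dataclass
class MiRNACount:
    name: str
    counts: dict[str, int]
    supporting_tags: list[str] = field(default_factory=list)


def expand_slash_group(name: str) -> list[str]:
    """Expand a slash-grouped miRNA name into its individual members.

    ``lus-miR160a/e/f`` -> ``[lus-miR160a, lus-miR160e, lus-miR160f]``.
    Suffixes after the first member replace its trailing letter block.
    """
    if "/" not in name:
        return [name]
    head, *rest = name.split("/")
    m = re.match(r"^(.*?)([a-z]+\d*)$", head)
    if m is None:
        return [head] + rest
    stem = m.group(1)
    return [head] + [stem + suffix for suffix in rest]


def load_refs(mature: list[SequenceRecord], hairpin: list[SequenceRecord]
              ) -> list[MiRNARef]:
    """Pair miRBase-style mature and hairpin FASTA records by name."""
    hp = {r.id: to_rna(r.seq) for r in hairpin}
    refs = []
    for rec in mature:
        if rec.id not in hp:
            raise ValueError(f"no precursor for mature {rec.id!r}")
        mat = to_rna(rec.seq)
        pos = hp[rec.id].find(mat)
        if pos < 0:
            raise ValueError(f"{rec.id}: mature not found in its precursor")
        refs.append(MiRNARef(name=rec.id, precursor_seq=hp[rec.id],
                             mature_seq=mat, mature_start=pos + 1))
    names = [r.name for r in refs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate miRNA names in reference set")
    return refs


def match_precursor(tag: str, ref: MiRNARef) -> int | None:
    """1-based offset of an exact full-length occurrence of tag, or None.

    No mismatches, no indels; the first (5'-most) occurrence is reported.
    """
    pos = ref.precursor_seq.find(to_rna(tag))
    return None if pos < 0 else pos + 1


def overlaps_mature(tag_offset: int, tag_len: int, ref: MiRNARef,
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> bool:
    """True iff the tag interval shares >= min_overlap nt with the mature."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    tag_end = tag_offset + tag_len - 1
    overlap = min(tag_end, ref.mature_end) - max(tag_offset, ref.mature_start) + 1
    return overlap >= min_overlap


def quantify_known(table: TagCountTable, refs: list[MiRNARef],
                   min_overlap: int = DEFAULT_MIN_OVERLAP
                   ) -> pd.DataFrame:
    """Per-miRNA, per-library counts under the two alignment criteria.

    A tag matching several distinct precursors contributes its count once
    per matched miRNA name.  Returns a miRNA x library integer DataFrame
    including all-zero rows for unidentified references.
    """
    if not refs:
        raise ValueError("empty reference set")
    names = [r.name for r in refs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate miRNA names in reference set")

    out = pd.DataFrame(0, index=names, columns=table.labels, dtype=int)
    support: dict[str, list[str]] = {n: [] for n in names}
    for tag in table.tags:
        rna = to_rna(tag)
        row = table.counts.loc[tag]
        for ref in refs:
            off = match_precursor(rna, ref)
            if off is None:
                continue
            if not overlaps_mature(off, len(rna), ref, min_overlap):
                continue
            out.loc[ref.name] += row.astype(int)
            support[ref.name].append(tag)
    out.attrs["support"] = support
    out.index.name = "mirna"
    return out


def family_rollup(counts: pd.DataFrame, refs: list[MiRNARef]) -> pd.DataFrame:
    """Sum member counts per family."""
    fam = {r.name: r.family for r in refs}
    return counts.groupby(counts.index.map(fam)).sum()
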
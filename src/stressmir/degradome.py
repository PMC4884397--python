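"""Degradome (PARE) tag mapping, peak categorization, cleavage matching.

Degradome tags are the 5' ends of uncapped mRNA fragments; a pile-up of
tag 5' ends at one transcript position evidences miRNA-guided cleavage.
Each occupied position is placed into one of five categories relative to
the transcript's coverage profile (0 best: the unique maximum; 4 worst:
a single raw read).  Predicted target sites are confirmed when an
occupied position falls within a small window of the site's expected
cleavage position -- the transcript nucleotide paired with miRNA
position 10, the universal plant-miRNA slicing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable

import numpy as np

from .io_formats import SequenceRecord, to_dna
from .target_score import TargetAlignment

__all__ = [
    "DegradomeProfile",
    "CleavageEvent",
    "clean_degradome",
    "build_profiles",
    "categorize",
    "match_cleavage",
]

DEG_MIN_LEN = 20
DEG_MAX_LEN = 21
CLEAVAGE_WINDOW = 1


@dataclass
class DegradomeProfile:
    """Raw tag 5'-end counts per 1-based transcript position."""

    transcript: str
    counts: dict[int, int] = field(default_factory=dict)

    def occupied(self) -> list[int]:
        return sorted(p for p, c in self.counts.items() if c >= 1)


@dataclass
class CleavageEvent:
    mirna: str
    transcript: str
    cleavage_pos: int
    peak_count: int
    category: int
    expectation: float
    site_start: int
    site_end: int


def clean_degradome(reads: Iterable[SequenceRecord],
                    min_len: int = DEG_MIN_LEN, max_len: int = DEG_MAX_LEN,
                    ncrna: Iterable[SequenceRecord] | None = None
                    ) -> dict[str, int]:
    """Collapse degradome reads to tag counts, keeping 20-21 nt tags.

    Tags identical to an entry of the supplied ncRNA reference set
    (rRNA/tRNA/snoRNA contaminants) are removed.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    ncrna_seqs = {to_dna(r.seq) for r in ncrna} if ncrna else set()
    tags: Counter[str] = Counter()
    for rec in reads:
        seq = to_dna(rec.seq)
        if not min_len <= len(seq) <= max_len:
            continue
        if seq in ncrna_seqs:
            continue
        tags[seq] += 1
    return dict(tags)


def build_profiles(tags: dict[str, int], transcripts: list[SequenceRecord]
                   ) -> dict[str, DegradomeProfile]:
    """Exact sense-strand tag mapping into per-transcript 5'-end profiles.

    Each tag increments the position of its 5' end at every sense match on
    every matching transcript; antisense matches are not counted.
    """
    profiles = {t.id: DegradomeProfile(transcript=t.id) for t in transcripts}
    seqs = [(t.id, to_dna(t.seq)) for t in transcripts]
    for tag, count in tags.items():
        for tid, seq in seqs:
            start = seq.find(tag)
            while start >= 0:
                pos = start + 1
                profiles[tid].counts[pos] = profiles[tid].counts.get(pos, 0) + count
                start = seq.find(tag, start + 1)
    return {tid: p for tid, p in profiles.items() if p.counts}


def categorize(profile: DegradomeProfile, position: int,
               median_over_occupied: bool = True,
               transcript_length: int | None = None) -> int:
    """Five-level peak category of one occupied position.

    4: single raw read.  Otherwise, with M the maximum count and med the
    median count: 0 when the position is the unique maximum; 1 when it
    ties the maximum attained more than once; 2 when below the maximum
    but above the median; 3 when at or below the median.  The median is
    taken over occupied positions (CleaveLand convention); pass
    ``median_over_occupied=False`` with ``transcript_length`` to include
    zero positions instead.
    """
    count = profile.counts.get(position, 0)
    if count < 1:
        raise ValueError(
            f"position {position} of {profile.transcript} is not occupied")
    if count == 1:
        return 4
    values = [c for c in profile.counts.values() if c >= 1]
    M = max(values)
    if median_over_occupied:
        med = float(np.median(values))
    else:
        if transcript_length is None:
            raise ValueError("transcript_length required for full-length median")
        padded = values + [0] * (transcript_length - len(values))
        med = float(np.median(padded))
    if count == M:
        return 0 if values.count(M) == 1 else 1
    if count > med:
        return 2
    return 3


def match_cleavage(alignments: list[TargetAlignment],
                   profiles: dict[str, DegradomeProfile],
                   window: int = CLEAVAGE_WINDOW,
                   median_over_occupied: bool = True) -> list[CleavageEvent]:
    """Confirm target sites against degradome peaks.

    For a gap-free site the expected cleavage position is site_end - 9
    (the transcript base paired with miRNA position 10 counted from the
    miRNA 5' end).  An event is emitted when an occupied position lies
    within +/-window of it; the most abundant such position is taken and
    categorized on the transcript's profile.
    """
    events: list[CleavageEvent] = []
    for aln in alignments:
        if aln.n_gaps != 0 and "-" in aln.paired[8:12]:
            raise ValueError(
                "gapped alignment across miRNA positions 10-11: "
                f"{aln.mirna} on {aln.transcript}")
        profile = profiles.get(aln.transcript)
        if profile is None:
            continue
        expected = aln.site_end - 9
        candidates = [
            (profile.counts[p], -abs(p - expected), p)
            for p in range(expected - window, expected + window + 1)
            if profile.counts.get(p, 0) >= 1
        ]
        if not candidates:
            continue
        count, _, pos = max(candidates)
        events.append(CleavageEvent(
            mirna=aln.mirna, transcript=aln.transcript, cleavage_pos=pos,
            peak_count=count,
            category=categorize(profile, pos, median_over_occupied),
            expectation=aln.expectation,
            site_start=aln.site_start, site_end=aln.site_end,
        ))
    return events
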
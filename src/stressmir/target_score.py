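"""Plant miRNA target complementarity scoring (psRNATarget-style).

A target site is scored by an expectation penalty accumulated along the
miRNA from its 5' end: 1.0 per mismatch, 0.5 per G:U wobble, 2.0 per gap,
each doubled inside the seed region (miRNA positions 2-13).  At most two
gaps are allowed and none adjacent to the cleavage-critical positions
10-11.  The alignment minimizing the expectation is found by dynamic
programming; sites at or below the reporting cutoff (default 5.0) are
candidate targets.  Scores fall on a half-integer grid by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_formats import SequenceRecord, revcomp, to_rna

__all__ = [
    "TargetAlignment",
    "score_site",
    "scan_transcriptome",
    "ScoringScheme",
]

SEED_START, SEED_END = 2, 13      # doubled-penalty region, 1-based
GAP_FORBIDDEN = (10, 11)          # no gap events at these miRNA positions
MAX_GAPS = 2
DEFAULT_CUTOFF = 5.0

# penalties in half-units so all arithmetic is integral
_MM, _WB, _GP = 2, 1, 4
_BIG = 10 ** 6

_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class ScoringScheme:
    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    seed_start: int = SEED_START
    seed_end: int = SEED_END
    max_gaps: int = MAX_GAPS
    cutoff: float = DEFAULT_CUTOFF


@dataclass
class TargetAlignment:
    mirna: str
    transcript: str
    site_start: int          # 1-based on the transcript, inclusive
    site_end: int
    expectation: float
    paired: str              # per alignment column: | match, o G:U, x mismatch, - gap
    n_gaps: int
    mirna_seq: str = ""
    site_seq: str = ""


def _encode(seq: str, what: str) -> np.ndarray:
    s = to_rna(seq)
    try:
        return np.array([_IDX[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"{what} contains a non-ACGU base: {exc}") from None


def _pair_cost(m: int, r: int) -> int:
    """Half-unit cost of pairing miRNA base m with revcomp-site base r."""
    if m == r:
        return 0
    if (m, r) in ((2, 0), (3, 1)):  # G:U and U:G wobbles
        return _WB
    return _MM


def _weight(pos: int) -> int:
    return 2 if SEED_START <= pos <= SEED_END else 1


def _dp(enc_m: np.ndarray, enc_r: np.ndarray) -> np.ndarray:
    """Cost table over (miRNA consumed, revcomp-site consumed, gaps used)."""
    L, S = len(enc_m), len(enc_r)
    dp = np.full((L + 1, S + 1, MAX_GAPS + 1), _BIG, dtype=np.int64)
    dp[0, 0, 0] = 0
    for i in range(L + 1):
        for j in range(S + 1):
            for g in range(MAX_GAPS + 1):
                cur = dp[i, j, g]
                if cur >= _BIG:
                    continue
                if i < L and j < S:
                    c = _pair_cost(int(enc_m[i]), int(enc_r[j])) * _weight(i + 1)
                    if cur + c < dp[i + 1, j + 1, g]:
                        dp[i + 1, j + 1, g] = cur + c
                if g < MAX_GAPS:
                    pos = min(i + 1, L)
                    if pos not in GAP_FORBIDDEN:
                        gc = _GP * _weight(pos)
                        if i < L and cur + gc < dp[i + 1, j, g + 1]:
                            dp[i + 1, j, g + 1] = cur + gc
                        if j < S and cur + gc < dp[i, j + 1, g + 1]:
                            dp[i, j + 1, g + 1] = cur + gc
    return dp


def score_site(mirna_seq: str, site_seq: str) -> TargetAlignment:
    """Minimum-expectation alignment of a miRNA to one candidate site.

    ``site_seq`` is the transcript sense-strand site, 5'->3'; the miRNA
    binds antisense, so the miRNA is aligned against the site's reverse
    complement and penalty positions count from the miRNA 5' end.  Ties
    are broken toward fewer gaps.
    """
    enc_m = _encode(mirna_seq, "miRNA")
    site_rna = to_rna(site_seq)
    _encode(site_rna, "site")
    enc_r = _encode(revcomp(site_rna), "site")
    if abs(len(enc_r) - len(enc_m)) > MAX_GAPS:
        raise ValueError("site length differs from miRNA length by more than "
                         f"{MAX_GAPS} (the gap limit)")
    dp = _dp(enc_m, enc_r)
    L, S = len(enc_m), len(enc_r)
    final = dp[L, S]
    g_best = int(np.flatnonzero(final == final.min())[0])  # fewest gaps first
    best = int(final[g_best])

    # traceback
    cols: list[str] = []
    i, j, g = L, S, g_best
    while i > 0 or j > 0:
        cur = dp[i, j, g]
        if i > 0 and j > 0:
            c = _pair_cost(int(enc_m[i - 1]), int(enc_r[j - 1])) * _weight(i)
            if dp[i - 1, j - 1, g] + c == cur:
                cols.append("|" if c == 0 else
                            ("o" if c in (_WB, 2 * _WB) else "x"))
                i, j = i - 1, j - 1
                continue
        moved = False
        if g > 0:
            for (pi, pj) in ((i - 1, j), (i, j - 1)):
                if pi < 0 or pj < 0:
                    continue
                pos_f = min(pi + 1, L)  # same position rule as forward pass
                if pos_f in GAP_FORBIDDEN:
                    continue
                if dp[pi, pj, g - 1] + _GP * _weight(pos_f) == cur:
                    cols.append("-")
                    i, j, g = pi, pj, g - 1
                    moved = True
                    break
        if not moved:
            raise AssertionError("traceback failed")
    cols.reverse()
    return TargetAlignment(
        mirna="", transcript="", site_start=1, site_end=len(site_rna),
        expectation=best / 2.0, paired="".join(cols), n_gaps=g_best,
        mirna_seq=to_rna(mirna_seq), site_seq=site_rna,
    )


@njit(cache=True)
def _scan_kernel(enc_m: np.ndarray, enc_y: np.ndarray, lengths: np.ndarray,
                 costs: np.ndarray, gaps: np.ndarray) -> None:
    """Min alignment cost for every (start-in-y, site length) window.

    ``enc_y`` is the reverse complement of the whole transcript; window
    (a, S) covers y[a:a+S].  Writes half-unit costs and the gap count of
    the minimal alignment (ties toward fewer gaps).
    """
    L = enc_m.shape[0]
    N = enc_y.shape[0]
    n_len = lengths.shape[0]
    max_s = L + MAX_GAPS
    dp = np.empty((L + 1, max_s + 1, MAX_GAPS + 1), dtype=np.int64)
    for a in range(N):
        for li in range(n_len):
            S = lengths[li]
            if a + S > N:
                costs[a, li] = _BIG
                gaps[a, li] = 0
                continue
            for i in range(L + 1):
                for j in range(S + 1):
                    for g in range(MAX_GAPS + 1):
                        dp[i, j, g] = _BIG
            dp[0, 0, 0] = 0
            for i in range(L + 1):
                for j in range(S + 1):
                    for g in range(MAX_GAPS + 1):
                        cur = dp[i, j, g]
                        if cur >= _BIG:
                            continue
                        if i < L and j < S:
                            m = enc_m[i]
                            r = enc_y[a + j]
                            if m == r:
                                c = 0
                            elif (m == 2 and r == 0) or (m == 3 and r == 1):
                                c = _WB
                            else:
                                c = _MM
                            if SEED_START <= i + 1 <= SEED_END:
                                c *= 2
                            if cur + c < dp[i + 1, j + 1, g]:
                                dp[i + 1, j + 1, g] = cur + c
                        if g < MAX_GAPS:
                            pos = i + 1
                            if pos > L:
                                pos = L
                            if pos != 10 and pos != 11:
                                gc = _GP
                                if SEED_START <= pos <= SEED_END:
                                    gc *= 2
                                if i < L and cur + gc < dp[i + 1, j, g + 1]:
                                    dp[i + 1, j, g + 1] = cur + gc
                                if j < S and cur + gc < dp[i, j + 1, g + 1]:
                                    dp[i, j + 1, g + 1] = cur + gc
            best = _BIG
            bg = 0
            for g in range(MAX_GAPS + 1):
                if dp[L, S, g] < best:
                    best = dp[L, S, g]
                    bg = g
            costs[a, li] = best
            gaps[a, li] = bg


def scan_transcriptome(mirnas: list[SequenceRecord],
                       transcripts: list[SequenceRecord],
                       cutoff: float = DEFAULT_CUTOFF) -> list[TargetAlignment]:
    """Scan every transcript position for sites of every miRNA.

    All sense-strand windows whose length is within the gap limit of the
    miRNA length are scored; sites with expectation <= cutoff are kept,
    and overlapping sites of one miRNA-transcript pair are deduplicated
    keeping the minimum-expectation site (ties: fewer gaps, then 5'-most).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    out: list[TargetAlignment] = []
    half_cutoff = int(round(cutoff * 2))
    for tx in transcripts:
        tx_rna = to_rna(tx.seq)
        enc_y = _encode(revcomp(tx_rna), "transcript")
        N = len(enc_y)
        for mi in mirnas:
            enc_m = _encode(mi.seq, "miRNA")
            L = len(enc_m)
            lengths = np.arange(max(L - MAX_GAPS, 1), L + MAX_GAPS + 1,
                                dtype=np.int64)
            costs = np.full((N, len(lengths)), _BIG, dtype=np.int64)
            gaps = np.zeros((N, len(lengths)), dtype=np.int64)
            _scan_kernel(enc_m, enc_y, lengths, costs, gaps)

            hits: list[tuple[int, int, int, int, int]] = []
            for a in range(N):
                for li, S in enumerate(lengths):
                    if costs[a, li] <= half_cutoff:
                        # window in revcomp coords -> sense coords
                        start = N - a - int(S) + 1
                        end = N - a
                        hits.append((int(costs[a, li]), int(gaps[a, li]),
                                     start, end, int(S)))
            hits.sort(key=lambda h: (h[0], h[1], h[2]))
            taken: list[tuple[int, int]] = []
            for cost, g, start, end, S in hits:
                if any(start <= te and ts <= end for ts, te in taken):
                    continue
                taken.append((start, end))
                aln = score_site(mi.seq, tx_rna[start - 1:end])
                aln.mirna = mi.id
                aln.transcript = tx.id
                aln.site_start = start
                aln.site_end = end
                out.append(aln)
    out.sort(key=lambda a: (a.mirna, a.transcript, a.site_start))
    return out
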
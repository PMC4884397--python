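"""Novel miRNA locus prediction from genome-mapped tags.

Mireap-style: tag hits are clustered along the genome, a window around
each cluster is folded, and the window is accepted as a novel miRNA
hairpin only if the community annotation criteria hold -- an abundant
mature tag on one stem arm, a star partner region on the opposite arm
forming a duplex with few mismatches and no large bulge, the canonical
2-nt 3' overhang, adequate stem stability, and strong read bias toward
the miRNA/miRNA* duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .folding import fold, vienna_available
from .io_formats import SequenceRecord, TagCountTable, revcomp, to_dna, to_rna
from .preprocess import map_to_genome

__all__ = [
    "HairpinCriteria",
    "Window",
    "HairpinCandidate",
    "extract_windows",
    "evaluate_candidate",
    "name_novel",
    "predict_novel",
]


@dataclass
class HairpinCriteria:
    """Config-exposed thresholds of the hairpin acceptance rules."""

    flank: int = 250                 # nt added each side of a cluster
    merge_gap: int = 30              # hits within this many nt merge
    max_cluster_span: int = 200      # wider clusters split per abundant tag
    mature_min_len: int = 18
    mature_max_len: int = 25
    max_duplex_mismatches: int = 4
    max_bulge: int = 2               # nt, per strand, between adjacent pairs
    overhang: int = 2                # expected star 3' overhang
    overhang_tol: int = 1
    min_loop: int = 3                # nt between mature and star arms
    max_loop: int = 60
    mfe_cutoff: float = -18.0        # kcal/mol, thermodynamic backend
    min_stem_pairs: int = 14         # fallback backend stability criterion
    duplex_bias: float = 0.9         # duplex share of window tag counts
    backend: str = "auto"


@dataclass
class Window:
    chrom: str
    start: int   # 1-based inclusive, genomic
    end: int
    strand: str
    seq: str     # RNA, window's own 5'->3' orientation
    # (tag RNA sequence, 1-based start within seq, total count)
    tags: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class HairpinCandidate:
    chrom: str
    start: int   # genomic span of the mature..star hairpin
    end: int
    strand: str
    window_seq: str
    structure: str
    mfe: float
    mature_tag: str
    mature_interval: tuple[int, int]  # 1-based within window_seq
    star_interval: tuple[int, int]
    duplex_mismatches: int
    overhang_3p: int
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.window_seq):
            raise ValueError("structure length != window length")


def extract_windows(hits: pd.DataFrame, counts: pd.Series,
                    genome: SequenceRecord | list[SequenceRecord],
                    criteria: HairpinCriteria | None = None) -> list[Window]:
    """Candidate windows around clustered genomic tag hits.

    ``hits`` is the per-tag hit table from :func:`map_to_genome`;
    ``counts`` the per-tag total counts.  Hits overlapping or abutting
    within ``merge_gap`` nt on one (seqid, strand) merge into a cluster;
    a cluster wider than ``max_cluster_span`` is split into one window per
    locally most-abundant tag.  Windows get ``flank`` nt each side,
    clipped at the sequence ends.
    """
    crit = criteria or HairpinCriteria()
    genomes = {g.id: to_dna(g.seq) for g in
               ([genome] if isinstance(genome, SequenceRecord) else genome)}

    by_locus: dict[tuple[str, str], list[tuple[int, int, str, int]]] = {}
    for tag, row in hits.iterrows():
        c = int(counts.loc[tag])
        if c <= 0:
            continue
        for seqid, start, strand in row["hits"]:
            end = start + len(tag) - 1
            by_locus.setdefault((seqid, strand), []).append((start, end, tag, c))

    windows: list[Window] = []
    for (seqid, strand), items in sorted(by_locus.items()):
        items.sort()
        clusters: list[list[tuple[int, int, str, int]]] = []
        cluster_end = -1
        for item in items:
            if clusters and item[0] <= cluster_end + crit.merge_gap:
                clusters[-1].append(item)
                cluster_end = max(cluster_end, item[1])
            else:
                clusters.append([item])
                cluster_end = item[1]
        for cluster in clusters:
            lo = min(s for s, _, _, _ in cluster)
            hi = max(e for _, e, _, _ in cluster)
            if hi - lo + 1 <= crit.max_cluster_span:
                anchors = [(lo, hi)]
            else:
                anchors = []
                remaining = sorted(cluster, key=lambda t: (-t[3], t[0], t[2]))
                covered: list[tuple[int, int]] = []
                for s, e, tag, c in remaining:
                    if any(ws <= s and e <= we for ws, we in covered):
                        continue
                    ws, we = s - crit.flank, e + crit.flank
                    anchors.append((s, e))
                    covered.append((ws, we))
            for alo, ahi in anchors:
                gseq = genomes[seqid]
                wstart = max(alo - crit.flank, 1)
                wend = min(ahi + crit.flank, len(gseq))
                sub = gseq[wstart - 1:wend]
                if strand == "-":
                    sub = revcomp(sub)
                win = Window(chrom=seqid, start=wstart, end=wend,
                             strand=strand, seq=to_rna(sub))
                for s, e, tag, c in cluster:
                    if s < wstart or e > wend:
                        continue
                    if strand == "+":
                        local = s - wstart + 1
                    else:
                        local = wend - e + 1
                    win.tags.append((to_rna(tag), local, c))
                win.tags.sort(key=lambda t: (-t[2], t[1], t[0]))
                windows.append(win)
    return windows


_B_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_CAN_PAIR = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:  # WC + G:U
    _CAN_PAIR[_a, _b] = True


def _enc(seq: str) -> np.ndarray:
    return np.array([_B_IDX.get(c, 4) for c in seq], dtype=np.int8)


@njit(cache=True)
def _duplex_scan(enc_ctx: np.ndarray, enc_m: np.ndarray, im: int, jm: int,
                 min_loop: int, max_loop: int, max_bulge: int,
                 can_pair: np.ndarray) -> tuple:
    """Best antiparallel mature/star duplex in the folded context.

    Mature base i pairs context position p0 - i, with an optional single
    star-side bulge of ``delta`` (1..max_bulge) unpaired star bases after
    mature base k; mature-side insertions surface as unpaired mature
    bases, which count as mismatches.  The star must lie entirely on one
    side of the mature with a loop gap within [min_loop, max_loop].
    Returns (pairs, p0, k, delta); pairs = -1 when no geometry fits.
    """
    L = enc_m.shape[0]
    n = enc_ctx.shape[0]
    best_pairs, bp0, bk, bd = -1, -1, -1, 0
    for p0 in range(n):
        for delta in range(0, max_bulge + 1):
            ks, ke = (L, L + 1) if delta == 0 else (1, L)
            for k in range(ks, ke):
                plo = p0 - (L - 1) - (delta if k < L else 0)
                if plo < 0 or p0 >= n:
                    continue
                if p0 < im:
                    gap = im - p0 - 1
                elif plo > jm:
                    gap = plo - jm - 1
                else:
                    continue
                if gap < min_loop or gap > max_loop:
                    continue
                pairs = 0
                for i in range(L):
                    q = p0 - i if i < k else p0 - i - delta
                    if can_pair[enc_m[i], enc_ctx[q]]:
                        pairs += 1
                if pairs > best_pairs or (
                        pairs == best_pairs and (delta < bd or
                                                 (delta == bd and p0 < bp0))):
                    best_pairs, bp0, bk, bd = pairs, p0, k, delta
    return best_pairs, bp0, bk, bd


def evaluate_candidate(window: Window,
                       criteria: HairpinCriteria | None = None
                       ) -> HairpinCandidate | None:
    """Apply the hairpin annotation criteria to one window.

    Returns a candidate when all criteria hold, else None.
    """
    crit = criteria or HairpinCriteria()
    if not window.tags:
        return None
    mature, m_start1, m_count = window.tags[0]
    if not crit.mature_min_len <= len(mature) <= crit.mature_max_len:
        return None

    # fold a mature-centered context: the star arm of a real hairpin must
    # lie within the loop-size limit of the mature, so farther sequence
    # cannot contribute to the duplex
    im_w = m_start1 - 1
    jm_w = im_w + len(mature) - 1
    ctx = crit.max_loop + crit.mature_max_len + 10
    a = max(im_w - ctx, 0)
    b = min(jm_w + ctx + 1, len(window.seq))
    sub = window.seq[a:b]
    im, jm = im_w - a, jm_w - a  # 0-based inclusive, context coords

    # star partner region by direct complementarity (fold-independent)
    L = len(mature)
    n_pairs, p0, k_sw, delta = _duplex_scan(
        _enc(sub), _enc(mature), im, jm,
        crit.min_loop, crit.max_loop, crit.max_bulge, _CAN_PAIR)
    mismatches = L - n_pairs
    if n_pairs < 0 or mismatches > crit.max_duplex_mismatches:
        return None

    enc_sub, enc_m = _enc(sub), _enc(mature)
    kept = []
    for i in range(L):
        q = p0 - i if i < k_sw else p0 - i - delta
        if _CAN_PAIR[enc_m[i], enc_sub[q]]:
            kept.append((im + i, q))
    partners = [p for _, p in kept]
    plo, phi = min(partners), max(partners)

    # read bias toward the miRNA/miRNA* duplex, over the hairpin span:
    # reads on the precursor must sit on the duplex arms, but reads in the
    # flanking window are not evidence about the locus either way
    pad = 4
    span_a = min(im, plo) - pad
    span_b = max(jm, phi) + pad + crit.overhang
    span_count = 0
    duplex_count = 0
    star_reads: list[tuple[str, int, int]] = []
    for tag, s1, c in window.tags:
        s0, e0 = s1 - 1 - a, s1 - 1 - a + len(tag) - 1  # context coords
        if e0 < span_a or s0 > span_b:
            continue
        span_count += c
        on_mature = s0 >= im - pad and e0 <= jm + pad
        on_star = s0 >= plo - pad and e0 <= phi + pad + crit.overhang
        if on_mature or on_star:
            duplex_count += c
        if on_star and not on_mature:
            star_reads.append((tag, s0 + 1, c))
    if span_count == 0 or duplex_count / span_count < crit.duplex_bias:
        return None

    # 2-nt 3' overhang of the star; from star reads when observed, else
    # the canonical value implied by the duplex structure
    if star_reads:
        tag, s1, _ = max(star_reads, key=lambda t: (t[2], -t[1]))
        star_end0 = s1 - 1 + len(tag) - 1
        overhang = star_end0 - phi
        star_iv = (s1, star_end0 + 1)
    else:
        overhang = crit.overhang
        star_iv = (plo + 1, phi + 1)
    if abs(overhang - crit.overhang) > crit.overhang_tol:
        return None

    # stem stability, backend-dependent
    span_lo = min(im, plo)
    span_hi = max(jm, phi)
    use_vienna = crit.backend == "vienna" or (
        crit.backend == "auto" and vienna_available())
    if use_vienna:
        _, mfe = fold(sub[span_lo:span_hi + 1], backend="vienna")
        if mfe > crit.mfe_cutoff:
            return None
    else:
        mfe = -float(len(kept))
        if len(kept) < crit.min_stem_pairs:
            return None

    # dot-bracket structure of the accepted context, for reporting
    structure, _ = fold(sub, backend=crit.backend)

    # genomic coordinates of the hairpin span (context -> window -> genome)
    if window.strand == "+":
        g_lo = window.start + a + span_lo
        g_hi = window.start + a + span_hi
    else:
        g_lo = window.end - (a + span_hi)
        g_hi = window.end - (a + span_lo)
    return HairpinCandidate(
        chrom=window.chrom, start=g_lo, end=g_hi, strand=window.strand,
        window_seq=sub, structure=structure, mfe=float(mfe),
        mature_tag=mature, mature_interval=(im + 1, jm + 1),
        star_interval=star_iv, duplex_mismatches=mismatches,
        overhang_3p=int(overhang),
    )


def name_novel(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Deduplicate by genomic interval, order by coordinate, assign names.

    Names are ``novel_mir_1..n`` in (chrom, start, strand) order;
    deterministic and idempotent across reruns on identical input.
    """
    seen: dict[tuple, HairpinCandidate] = {}
    for c in candidates:
        seen.setdefault((c.chrom, c.start, c.end, c.strand), c)
    ordered = sorted(seen.values(), key=lambda c: (c.chrom, c.start, c.strand))
    for i, c in enumerate(ordered, start=1):
        c.name = f"novel_mir_{i}"
    return ordered


def predict_novel(table: TagCountTable, genome: SequenceRecord | list[SequenceRecord],
                  criteria: HairpinCriteria | None = None,
                  exclude_tags: set[str] | None = None
                  ) -> tuple[list[HairpinCandidate], pd.DataFrame]:
    """Full novel-locus scan: map, window, evaluate, name, count.

    ``exclude_tags`` (e.g. tags already assigned to known miRNAs) are
    removed before clustering.  Returns named candidates and a
    candidate x library count table of each candidate's mature tag.
    """
    crit = criteria or HairpinCriteria()
    hits, _ = map_to_genome(table, genome)
    counts = table.total_counts()
    if exclude_tags:
        keep = [t for t in hits.index if t not in exclude_tags]
        hits = hits.loc[keep]
        counts = counts.loc[keep]
    windows = extract_windows(hits, counts, genome, crit)
    accepted = [c for c in (evaluate_candidate(w, crit) for w in windows) if c]
    named = name_novel(accepted)

    rows = []
    for c in named:
        tag_dna = to_dna(c.mature_tag)
        if tag_dna in table.counts.index:
            row = table.counts.loc[tag_dna].astype(int)
        else:
            row = pd.Series(0, index=table.labels)
        rows.append(row.rename(c.name))
    counts_df = pd.DataFrame(rows, columns=table.labels).astype(int) if rows \
        else pd.DataFrame(columns=table.labels, dtype=int)
    counts_df.index.name = "mirna"
    return named, counts_df
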
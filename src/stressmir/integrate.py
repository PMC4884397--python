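"""Cross-omics integration and qPCR validation arithmetic.

Combines three evidence layers -- miRNA sequencing direction calls,
degradome-confirmed cleavage events, and transcript-level (DGE)
direction calls -- into the inverse-expression pair report: a
cleavage-linked miRNA/target pair is "inverse" when the two move in
opposite directions in every one of the three stress conditions.  Also
provides the 2^-ddCt relative-expression computation for stem-loop
qRT-PCR validation and its sign-concordance summary against sequencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degradome import CleavageEvent
from .diffexpr import DERecord

__all__ = [
    "DirectionTriple",
    "PairRecord",
    "direction_from_de",
    "directions_from_log2fc",
    "find_inverse_pairs",
    "ddct",
    "concordance",
]


@dataclass(frozen=True)
class DirectionTriple:
    """Up/Down call in each of the three stress conditions."""

    conditions: tuple[str, ...]
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.calls) or not self.calls:
            raise ValueError("one call per condition required")
        if any(c not in ("Up", "Down") for c in self.calls):
            raise ValueError("calls must be 'Up' or 'Down'")

    def opposite(self, other: "DirectionTriple") -> bool:
        if self.conditions != other.conditions:
            raise ValueError("condition sets differ")
        return all(a != b for a, b in zip(self.calls, other.calls))


@dataclass
class PairRecord:
    mirna: str
    target: str
    mirna_dirs: DirectionTriple
    target_dirs: DirectionTriple
    inverse: bool
    annotation: str = ""
    cleavage_pos: int | None = None
    alignment_score: float | None = None
    category: int | None = None


def directions_from_log2fc(log2fc_by_condition: dict[str, float],
                           conditions: tuple[str, ...]
                           ) -> DirectionTriple | None:
    """Direction triple from per-condition log2 fold changes.

    Up iff log2fc > 0, Down iff < 0; an exact zero or a missing
    comparison excludes the miRNA from pairing (returns None).
    """
    calls = []
    for c in conditions:
        v = log2fc_by_condition.get(c)
        if v is None or v == 0 or not math.isfinite(v):
            return None
        calls.append("Up" if v > 0 else "Down")
    return DirectionTriple(conditions=conditions, calls=tuple(calls))


def direction_from_de(by_comparison: dict[str, list[DERecord]],
                      significant_only: bool = False
                      ) -> dict[str, DirectionTriple]:
    """Per-miRNA direction triple over all treatment-vs-control comparisons.

    Directions follow the sign of log2fc regardless of significance (the
    published tables list directions for non-significant miRNAs too);
    ``significant_only`` restricts to miRNAs called up/down everywhere.
    """
    conditions = tuple(by_comparison)
    per_mirna: dict[str, dict[str, float]] = {}
    calls_ok: dict[str, bool] = {}
    for cond, records in by_comparison.items():
        for r in records:
            per_mirna.setdefault(r.mirna, {})[cond] = r.log2fc
            if r.call not in ("up", "down"):
                calls_ok[r.mirna] = False
            else:
                calls_ok.setdefault(r.mirna, True)
    out = {}
    for name, lfc in per_mirna.items():
        if significant_only and not calls_ok.get(name, False):
            continue
        triple = directions_from_log2fc(lfc, conditions)
        if triple is not None:
            out[name] = triple
    return out


def find_inverse_pairs(mirna_triples: dict[str, DirectionTriple],
                       target_triples: dict[str, DirectionTriple],
                       cleavage_events: list[CleavageEvent]
                       ) -> list[PairRecord]:
    """Pair report over cleavage-linked miRNA/target pairs.

    A pair is considered only when a cleavage event links the miRNA and
    the target transcript and both have direction triples; the inverse
    flag requires opposite calls in all three conditions.  The headline
    count is the number of records with ``inverse=True``.
    """
    best_event: dict[tuple[str, str], CleavageEvent] = {}
    for ev in cleavage_events:
        key = (ev.mirna, ev.transcript)
        cur = best_event.get(key)
        if cur is None or (ev.category, -ev.peak_count) < (cur.category, -cur.peak_count):
            best_event[key] = ev

    pairs = []
    for (mirna, target), ev in sorted(best_event.items()):
        mt = mirna_triples.get(mirna)
        tt = target_triples.get(target)
        if mt is None or tt is None:
            continue
        pairs.append(PairRecord(
            mirna=mirna, target=target, mirna_dirs=mt, target_dirs=tt,
            inverse=mt.opposite(tt), cleavage_pos=ev.cleavage_pos,
            alignment_score=ev.expectation, category=ev.category,
        ))
    return pairs


def pairs_to_frame(pairs: list[PairRecord]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {"mirna": p.mirna, "target": p.target}
        for c, v in zip(p.mirna_dirs.conditions, p.mirna_dirs.calls):
            row[f"mirna_{c}"] = v
        for c, v in zip(p.target_dirs.conditions, p.target_dirs.calls):
            row[f"target_{c}"] = v
        row.update({
            "cleavage_pos": p.cleavage_pos,
            "alignment_score": p.alignment_score,
            "category": p.category,
            "inverse": p.inverse,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def ddct(treated: pd.DataFrame, control: pd.DataFrame
         ) -> tuple[float, tuple[float, float]]:
    """2^-ddCt relative expression of treated vs control.

    Each input holds replicate rows with ``ct_target`` and
    ``ct_reference`` columns for one sample.  dCt = Ct_target -
    Ct_reference per sample (replicate means); ddCt = dCt_treated -
    dCt_control.  Returns (2^-ddCt, interval) where the interval
    propagates the replicate standard deviation of ddCt.
    """
    for df, name in ((treated, "treated"), (control, "control")):
        if df.empty or df["ct_reference"].isna().any() or df["ct_target"].isna().any():
            raise ValueError(f"missing Ct values in {name} sample")
    d_t = treated["ct_target"] - treated["ct_reference"]
    d_c = control["ct_target"] - control["ct_reference"]
    dd = float(d_t.mean() - d_c.mean())
    sd = float(np.sqrt(np.nan_to_num(d_t.var(ddof=1) / len(d_t)) +
                       np.nan_to_num(d_c.var(ddof=1) / len(d_c))))
    rel = 2.0 ** (-dd)
    return rel, (2.0 ** (-(dd + sd)), 2.0 ** (-(dd - sd)))


def concordance(qpcr: pd.DataFrame, by_comparison: dict[str, list[DERecord]],
                control: str = "CK") -> pd.DataFrame:
    """Sign agreement of qPCR relative expression with sequencing log2fc.

    ``qpcr`` holds columns mirna, sample, replicate, ct_target,
    ct_reference.  For each miRNA and stress condition the sign of
    log2(2^-ddCt) is compared with the sign of the sequencing log2fc;
    the returned frame has one row per (miRNA, condition) plus an
    ``agree`` flag, with the overall agreement fraction in
    ``frame.attrs['agreement']``.
    """
    seq_lfc = {
        (r.mirna, cond): r.log2fc
        for cond, recs in by_comparison.items() for r in recs
    }
    rows = []
    for mirna, sub in qpcr.groupby("mirna"):
        ctrl = sub[sub["sample"] == control]
        if ctrl.empty:
            continue
        for cond, tr in sub[sub["sample"] != control].groupby("sample"):
            if (mirna, cond) not in seq_lfc:
                continue
            rel, _ = ddct(tr, ctrl)
            q_lfc = float(np.log2(rel))
            s_lfc = seq_lfc[(mirna, cond)]
            rows.append({
                "mirna": mirna, "condition": cond,
                "qpcr_log2fc": q_lfc, "seq_log2fc": s_lfc,
                "agree": bool(np.sign(q_lfc) == np.sign(s_lfc)),
            })
    frame = pd.DataFrame(rows)
    frame.attrs["agreement"] = float(frame["agree"].mean()) if len(frame) else float("nan")
    return frame
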
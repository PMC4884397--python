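"""Differential expression of miRNA counts between single libraries.

Counts are normalized to reads per million of the library's clean-read
total (miRNA lengths are nearly constant, so no length term is used).
Each stress library is compared to the control with the Audic-Claverie
conditional binomial test -- the standard exact test for two-library
count data without replicates -- followed by Benjamini-Hochberg FDR.
A miRNA is called up (down) when FDR < 0.001 and log2 fold-change is
strictly above +1 (below -1); zero counts enter ratio computation with a
0.01 RPM floor so fold-changes stay finite, while raw zeros are retained
for presence/absence reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DERecord",
    "normalize",
    "log2_fold_change",
    "count_test",
    "bh_fdr",
    "call_de",
    "run_comparison",
    "run_all_comparisons",
    "expression_matrix",
]

ZERO_TPM = 0.01
FDR_CUTOFF = 0.001
LOG2FC_CUTOFF = 1.0


@dataclass
class DERecord:
    mirna: str
    treatment: str
    control: str
    count_t: int
    count_c: int
    tpm_t: float
    tpm_c: float
    log2fc: float
    p_value: float
    fdr: float = np.nan
    call: str = "ns"


def normalize(counts, library_total: float, zero_tpm: float | None = None):
    """Reads-per-million; zeros floored at ``zero_tpm`` when given.

    Pass ``zero_tpm=ZERO_TPM`` for ratio computation; leave None to keep
    true zeros for presence/absence reporting.
    """
    if library_total <= 0:
        raise ValueError("library total must be positive")
    tpm = np.asarray(counts, dtype=float) / library_total * 1e6
    if zero_tpm is not None:
        tpm = np.where(np.asarray(counts) == 0, zero_tpm, tpm)
    if np.ndim(counts) == 0:
        return float(tpm)
    return tpm


def log2_fold_change(tpm_t: float, tpm_c: float) -> float:
    if tpm_t <= 0 or tpm_c <= 0:
        raise ValueError("fold change requires positive normalized values")
    return float(np.log2(tpm_t / tpm_c))


def count_test(count_t: int, total_t: int, count_c: int, total_c: int) -> float:
    """Audic-Claverie-style conditional binomial two-sided p-value.

    Conditional on n = count_t + count_c, under the null count_t ~
    Binomial(n, total_t / (total_t + total_c)); two-sided p is twice the
    smaller exact tail, capped at 1.
    """
    if total_t <= 0 or total_c <= 0:
        raise ValueError("library totals must be positive")
    n = count_t + count_c
    if n == 0:
        return 1.0
    q = total_t / (total_t + total_c)
    lower = stats.binom.cdf(count_t, n, q)
    upper = stats.binom.sf(count_t - 1, n, q)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_de(records: list[DERecord],
            fdr_cutoff: float = FDR_CUTOFF,
            log2fc_cutoff: float = LOG2FC_CUTOFF) -> list[DERecord]:
    """Set the up/down/ns/absent call on each record (strict inequalities)."""
    for rec in records:
        if rec.count_t == 0 and rec.count_c == 0:
            rec.call = "absent"
        elif rec.fdr < fdr_cutoff and rec.log2fc > log2fc_cutoff:
            rec.call = "up"
        elif rec.fdr < fdr_cutoff and rec.log2fc < -log2fc_cutoff:
            rec.call = "down"
        else:
            rec.call = "ns"
    return records


def run_comparison(counts: pd.DataFrame, treatment: str, control: str,
                   totals: dict[str, int] | None = None) -> list[DERecord]:
    """DE records for every miRNA in one treatment-vs-control comparison.

    ``totals`` are the libraries' clean-read totals; by default the column
    sums of ``counts`` are used.
    """
    totals = totals or {c: int(counts[c].sum()) for c in counts.columns}
    ct = counts[treatment].to_numpy(dtype=int)
    cc = counts[control].to_numpy(dtype=int)
    tpm_t = normalize(ct, totals[treatment], ZERO_TPM)
    tpm_c = normalize(cc, totals[control], ZERO_TPM)
    pvals = np.array([
        count_test(int(t), totals[treatment], int(c), totals[control])
        for t, c in zip(ct, cc)
    ])
    fdrs = bh_fdr(pvals)
    records = [
        DERecord(
            mirna=name, treatment=treatment, control=control,
            count_t=int(t), count_c=int(c),
            tpm_t=float(tt), tpm_c=float(tc),
            log2fc=log2_fold_change(float(tt), float(tc)),
            p_value=float(p), fdr=float(f),
        )
        for name, t, c, tt, tc, p, f in zip(
            counts.index, ct, cc, tpm_t, tpm_c, pvals, fdrs)
    ]
    return call_de(records)


def run_all_comparisons(counts: pd.DataFrame, control: str,
                        totals: dict[str, int] | None = None
                        ) -> dict[str, list[DERecord]]:
    """Each non-control library versus the control."""
    return {
        lib: run_comparison(counts, lib, control, totals)
        for lib in counts.columns if lib != control
    }


def records_to_frame(by_comparison: dict[str, list[DERecord]]) -> pd.DataFrame:
    rows = [
        {
            "mirna": r.mirna, "treatment": r.treatment, "control": r.control,
            "count_t": r.count_t, "count_c": r.count_c,
            "tpm_t": r.tpm_t, "tpm_c": r.tpm_c, "log2fc": r.log2fc,
            "p_value": r.p_value, "fdr": r.fdr, "call": r.call,
        }
        for recs in by_comparison.values() for r in recs
    ]
    return pd.DataFrame(rows)


def expression_matrix(by_comparison: dict[str, list[DERecord]]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA x comparison log2 fold-change matrix with an absence mask.

    Cells of miRNAs with zero counts in either library of a comparison are
    masked (True).  Rows with no masked cell are ordered by hierarchical
    clustering (average linkage, Euclidean distance); incomplete rows
    follow in name order.
    """
    comparisons = list(by_comparison)
    lfc = pd.DataFrame({
        cmp: {r.mirna: r.log2fc for r in recs}
        for cmp, recs in by_comparison.items()
    })[comparisons]
    mask = pd.DataFrame({
        cmp: {r.mirna: (r.count_t == 0 or r.count_c == 0) for r in recs}
        for cmp, recs in by_comparison.items()
    })[comparisons]

    complete = lfc.index[~mask.any(axis=1)]
    if len(complete) > 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist

        sub = lfc.loc[complete]
        order = leaves_list(average(pdist(sub.to_numpy(), metric="euclidean")))
        ordered = list(sub.index[order])
    else:
        ordered = sorted(complete)
    ordered += sorted(set(lfc.index) - set(ordered))
    return lfc.loc[ordered], mask.loc[ordered]
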
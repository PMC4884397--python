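"""RNA secondary-structure prediction with two interchangeable backends.

The thermodynamic backend wraps ViennaRNA's minimum-free-energy fold when
the ``RNA`` binding is importable.  The internal fallback is a
Nussinov-style maximum-weight pairing dynamic program (GC=3, AU=2, GU=1,
minimum hairpin loop 3) with a fixed per-pair pseudo-energy, so the
package folds hairpin candidates with no external dependency.  Both return
a balanced dot-bracket string of the sequence's length and a non-positive
energy whenever at least one pair forms; N is unpairable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .io_formats import to_rna

__all__ = ["fold", "pair_table", "nussinov_fold", "vienna_available"]

MIN_LOOP = 3
# pseudo-energy per weight unit for the fallback's reported "mfe"
PSEUDO_ENERGY_PER_WEIGHT = -1.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# pair weights: GC=3, AU=2, GU=1
_W = np.zeros((5, 5), dtype=np.int64)
for a, b, w in [(0, 3, 2), (3, 0, 2), (1, 2, 3), (2, 1, 3), (2, 3, 1), (3, 2, 1)]:
    _W[a, b] = w


def vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
        return True
    except ImportError:
        return False


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, 4) for c in to_rna(seq)], dtype=np.int8)


@njit(cache=True)
def _nussinov_table(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            w = weights[enc[i], enc[j]]
            if w > 0 and dp[i + 1, j - 1] + w > best:
                best = dp[i + 1, j - 1] + w
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


def nussinov_fold(seq: str) -> tuple[str, float]:
    """Maximum-weight pairing fold of ``seq`` (fallback backend)."""
    enc = _encode(seq)
    n = len(enc)
    structure = ["."] * n
    if n <= MIN_LOOP + 1:
        return "".join(structure), 0.0
    dp = _nussinov_table(enc, _W)
    # iterative traceback
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        w = _W[enc[i], enc[j]]
        if w > 0 and dp[i, j] == dp[i + 1, j - 1] + w:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return "".join(structure), float(dp[0, n - 1]) * PSEUDO_ENERGY_PER_WEIGHT


def _vienna_fold(seq: str) -> tuple[str, float]:
    import RNA

    structure, mfe = RNA.fold(to_rna(seq))
    return structure, float(mfe)


def fold(window_seq: str, backend: str = "auto") -> tuple[str, float]:
    """Fold a sequence into (dot-bracket structure, energy).

    backend: "vienna" (thermodynamic MFE), "nussinov" (internal maximum-
    weight fallback), or "auto" (vienna when importable, else fallback).
    """
    if backend == "auto":
        backend = "vienna" if vienna_available() else "nussinov"
    if backend == "vienna":
        return _vienna_fold(window_seq)
    if backend == "nussinov":
        return nussinov_fold(window_seq)
    raise ValueError(f"unknown folding backend {backend!r}")


def pair_table(structure: str) -> np.ndarray:
    """0-based partner index per position, -1 for unpaired."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt
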
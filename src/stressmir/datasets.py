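"""Bundled reference datasets.

Two small curated tables from a published flax (*Linum usitatissimum*)
saline/alkaline-stress miRNA study accompany the package as worked
examples and integration fixtures:

* ``flax_pairs``: the 29 cleavage-validated miRNA-target pairs with
  Up/Down direction calls per stress condition (AS alkaline, AS2
  alkaline-salt, NSS neutral salt) from both small-RNA and transcript
  (DGE) sequencing, plus degradome position, alignment score and peak
  category.
* ``flax_known_de``: the significantly differential known miRNAs with
  their log2 fold-changes per condition ('.' where not significant).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .integrate import DirectionTriple
from .mirna_quant import expand_slash_group

__all__ = [
    "load_flax_pairs",
    "load_flax_known_de",
    "flax_direction_triples",
    "count_significant_per_condition",
]

CONDITIONS = ("AS", "AS2", "NSS")


def _read(name: str) -> pd.DataFrame:
    with resources.files("stressmir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["."])


def load_flax_pairs() -> pd.DataFrame:
    return _read("flax_pairs.tsv")


def load_flax_known_de() -> pd.DataFrame:
    return _read("flax_known_de.tsv")


def flax_direction_triples() -> tuple[dict[str, DirectionTriple],
                                      dict[str, DirectionTriple]]:
    """miRNA and target direction triples transcribed from the pair table."""
    df = load_flax_pairs()
    mirna = {
        row["mirna"]: DirectionTriple(
            conditions=CONDITIONS,
            calls=tuple(row[f"srna_{c}"] for c in CONDITIONS))
        for _, row in df.iterrows()
    }
    target = {
        row["target"]: DirectionTriple(
            conditions=CONDITIONS,
            calls=tuple(row[f"dge_{c}"] for c in CONDITIONS))
        for _, row in df.iterrows()
    }
    return mirna, target


def count_significant_per_condition() -> dict[str, int]:
    """Distinct miRNAs (slash groups expanded) significant per condition."""
    df = load_flax_known_de()
    out = {}
    for c in CONDITIONS:
        members: set[str] = set()
        for _, row in df.iterrows():
            if pd.notna(row[f"log2fc_{c}"]):
                members.update(expand_slash_group(row["mirna"]))
        out[c] = len(members)
    return out
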
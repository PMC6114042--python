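"""Library-level summary arithmetic and published reference totals.

The reads/sequences duality of a collapsed library yields two headline
percentages per sample: the share of reads, and of unique sequences, that
associate with the mitochondrial genome. The published totals for the mouse
germ-cell small RNA-seq libraries (PGC, SPG, SPZ, OCY, ZYGO) ship as package
data so those percentages can be recomputed from their numerator and
denominator columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_library_totals", "percent_mt_associated"]


def load_published_library_totals() -> pd.DataFrame:
    """Published per-sample totals: total/MT reads and sequences."""
    path = resources.files("mitosrna") / "data" / "germline_library_totals.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col="sample")


def percent_mt_associated(
    totals: pd.DataFrame, level: str = "reads", decimals: int = 2
) -> pd.Series:
    """Percent of reads (or sequences) associated with the mitochondrial
    genome, recomputed from the totals table and rounded half-even."""
    if level not in ("reads", "sequences"):
        raise ValueError("level must be 'reads' or 'sequences'")
    pct = 100.0 * totals[f"mt_{level}"] / totals[f"total_{level}"]
    return pct.round(decimals)
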
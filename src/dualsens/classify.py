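"""Dual-contrast sensitivity classification of genes.

A gene is androgen sensitive when it is differentially expressed
(q below threshold) in both the castration contrast (cx_vs_sham) and
the testosterone-restoration contrast (T_vs_cx); follistatin sensitive
when differential in the castration contrast and the follistatin
contrast (F_vs_cx). The default threshold is q < 0.2, strict.

The rule is purely q-based: no sign consistency between the two
contrasts is demanded by default. ``require_direction=True`` adds the
biologically natural constraint that the restoration contrast reverse
the castration fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SensitivityCall", "VennCounts", "classify_sensitivity", "venn_partition"]

CATEGORIES = ("uniquely_androgen", "uniquely_follistatin", "both", "neither")


@dataclass(frozen=True)
class VennCounts:
    """Counts of sensitive genes: flag totals and their conjunction."""

    n_androgen: int
    n_follistatin: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_androgen, self.n_follistatin):
            raise ValueError("n_both cannot exceed either flag count")


def _category(androgen: np.ndarray, follistatin: np.ndarray) -> np.ndarray:
    return np.select(
        [androgen & follistatin, androgen, follistatin],
        ["both", "uniquely_androgen", "uniquely_follistatin"],
        default="neither",
    )


def classify_sensitivity(
    results: Mapping[str, pd.DataFrame],
    q_threshold: float = 0.2,
    require_direction: bool = False,
) -> pd.DataFrame:
    """Apply the dual-contrast rule to the three comparison tables.

    ``results`` maps comparison labels (cx_vs_sham, T_vs_cx, F_vs_cx) to
    gene-indexed tables carrying at least a ``q`` column (and ``log2fc``
    when ``require_direction``). Every gene must be present in all three
    tables. Returns a gene-indexed frame with boolean flags and category.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must lie in (0, 1]")
    needed = {"cx_vs_sham", "T_vs_cx", "F_vs_cx"}
    missing = needed - set(results)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    genes = results["cx_vs_sham"].index
    for label in ("T_vs_cx", "F_vs_cx"):
        other = results[label].index
        if not genes.sort_values().equals(other.sort_values()):
            raise ValueError(f"gene sets differ between cx_vs_sham and {label}")
    q_cx = results["cx_vs_sham"]["q"]
    q_t = results["T_vs_cx"]["q"].reindex(genes)
    q_f = results["F_vs_cx"]["q"].reindex(genes)

    androgen = (q_cx < q_threshold) & (q_t < q_threshold)
    follistatin = (q_cx < q_threshold) & (q_f < q_threshold)
    if require_direction:
        fc_cx = results["cx_vs_sham"]["log2fc"]
        fc_t = results["T_vs_cx"]["log2fc"].reindex(genes)
        fc_f = results["F_vs_cx"]["log2fc"].reindex(genes)
        androgen &= np.sign(fc_cx) * np.sign(fc_t) < 0
        follistatin &= np.sign(fc_cx) * np.sign(fc_f) < 0

    androgen = androgen.to_numpy()
    follistatin = follistatin.to_numpy()
    return pd.DataFrame(
        {
            "androgen_sensitive": androgen,
            "follistatin_sensitive": follistatin,
            "category": _category(androgen, follistatin),
        },
        index=genes,
    )


def venn_partition(calls: pd.DataFrame) -> VennCounts:
    """Exact flag counts and their conjunction; duplicate genes are an error."""
    if calls.index.has_duplicates:
        raise ValueError("duplicate gene ids in sensitivity calls")
    a = calls["androgen_sensitive"].to_numpy(dtype=bool)
    f = calls["follistatin_sensitive"].to_numpy(dtype=bool)
    return VennCounts(int(a.sum()), int(f.sum()), int((a & f).sum()))
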
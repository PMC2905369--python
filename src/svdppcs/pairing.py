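"""Pattern pairing: matching eigengenes across the two data sets.

Two eigengenes form a pattern pair when their profiles over the aligned
arrays correlate significantly (Pearson r, two-sided t test on m - 2
degrees of freedom).  A meaningful eigengene with no significant partner
is paired with an eigengene of the other data set whose primary cluster
is empty — the resulting chart then isolates genes whose pattern exists
in one data set only, i.e. divergent modules by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import PrimaryClusterSet
from .decomposition import SVDResult

__all__ = ["PatternPair", "correlate_eigengenes", "form_pairs", "pair_unmatched"]


@dataclass(frozen=True)
class PatternPair:
    """A matched pair of eigengene indices (1-based) across data sets."""

    idx1: int
    idx2: int
    r_pair: float | None
    p_value: float | None
    kind: Literal["matched", "unmatched-1only", "unmatched-2only"] = "matched"

    @property
    def sign(self) -> int:
        """Orientation carried to the chart; +1 for unmatched pairs."""
        if self.r_pair is None:
            return 1
        return -1 if self.r_pair < 0 else 1


def _pearson_with_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    m = x.size
    if m < 3:
        raise ValueError("need at least 3 arrays for the correlation test")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((m - 2) / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), m - 2))


def correlate_eigengenes(
    res1: SVDResult,
    res2: SVDResult,
    candidates1: list[int] | None = None,
    candidates2: list[int] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between candidate eigengenes of the two sets.

    Both data sets must have the same number of arrays in matched
    condition order.  Returns a tidy frame (idx1, idx2, r, p) with
    two-sided p from t = r * sqrt((m-2)/(1-r^2)) on m - 2 df.
    """
    m1 = res1.eigengenes.shape[0]
    m2 = res2.eigengenes.shape[0]
    if m1 != m2:
        raise ValueError(
            f"data sets have {m1} vs {m2} arrays; align conditions (same "
            f"time points in the same order) before pairing"
        )
    if candidates1 is None:
        candidates1 = list(range(1, res1.n_components + 1))
    if candidates2 is None:
        candidates2 = list(range(1, res2.n_components + 1))
    rows = []
    for i in candidates1:
        for j in candidates2:
            r, p = _pearson_with_t_test(res1.eigengenes[:, i - 1], res2.eigengenes[:, j - 1])
            rows.append((i, j, r, p))
    return pd.DataFrame(rows, columns=["idx1", "idx2", "r", "p"])


def form_pairs(
    table: pd.DataFrame,
    alpha: float = 0.01,
    min_abs_r: float = 0.6,
) -> list[PatternPair]:
    """Greedy one-to-one matching of eigengenes by descending |r|.

    Only pairs with |r| >= min_abs_r and p < alpha are considered; each
    eigengene index participates in at most one matched pair.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    passing = table[(table["r"].abs() >= min_abs_r) & (table["p"] < alpha)]
    order = passing.reindex(passing["r"].abs().sort_values(ascending=False, kind="stable").index)
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[PatternPair] = []
    for row in order.itertuples(index=False):
        i, j = int(row.idx1), int(row.idx2)
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append(PatternPair(idx1=i, idx2=j, r_pair=float(row.r), p_value=float(row.p)))
    return pairs


def pair_unmatched(
    pcls_other: PrimaryClusterSet,
    idx: int,
    side: Literal[1, 2],
    fallback_last: bool = True,
) -> PatternPair:
    """Pair a meaningful but partner-less eigengene with an empty PCL.

    The partner is the highest-index eigengene of the other data set whose
    primary cluster has no members; if none is empty, the last component
    serves as fallback (or an error is raised when disabled).  Modules cut
    from such a chart are divergent by construction: the partner axis
    carries no coherent pattern.
    """
    empties = pcls_other.empty_indices
    if empties:
        partner = max(empties)
    elif fallback_last:
        partner = pcls_other.n_components
    else:
        raise ValueError(
            f"no empty PCL available to pair with eigengene {idx} and fallback disabled"
        )
    if side == 1:
        return PatternPair(idx1=idx, idx2=partner, r_pair=None, p_value=None, kind="unmatched-1only")
    return PatternPair(idx1=partner, idx2=idx, r_pair=None, p_value=None, kind="unmatched-2only")
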
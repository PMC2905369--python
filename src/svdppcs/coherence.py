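"""Module co-expression tightness: average pairwise Pearson correlation,
assessed against an empirical null of random gene sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["CoherenceResult", "avg_pairwise_corr", "empirical_null_p"]


@dataclass(frozen=True)
class CoherenceResult:
    avg_corr: float
    empirical_p: float
    n_null: int


def avg_pairwise_corr(mat: ExpressionMatrix, genes) -> float:
    """Mean Pearson correlation over all unordered pairs of module genes."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = mat.subset_genes(genes).values
    sd = sub.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"gene {genes[int(flat[0])]!r} is constant across arrays; "
            f"its correlations are undefined"
        )
    corr = np.corrcoef(sub)
    iu = np.triu_indices(len(genes), k=1)
    return float(corr[iu].mean())


def empirical_null_p(
    mat: ExpressionMatrix,
    observed: float,
    n_sets: int = 500,
    size_range: tuple[int, int] = (10, 500),
    seed: int = 0,
) -> CoherenceResult:
    """Fraction of random gene sets at least as coherent as ``observed``.

    Draws ``n_sets`` gene sets of uniform-random size in ``size_range``
    from the full analysed gene universe (without replacement within each
    set), computes each set's average pairwise correlation, and returns
    the add-one estimate (1 + #{null >= observed}) / (n_sets + 1), which
    never reports an exact zero.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    low, high = size_range
    if low < 2 or high < low:
        raise ValueError("size_range must satisfy 2 <= low <= high")
    if high > mat.n_genes:
        warnings.warn(
            f"null set sizes capped at the {mat.n_genes}-gene universe",
            stacklevel=2,
        )
        high = mat.n_genes
        low = min(low, high)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_sets):
        size = int(rng.integers(low, high + 1))
        rows = rng.choice(mat.n_genes, size=size, replace=False)
        sub = mat.values[rows]
        corr = np.corrcoef(sub)
        iu = np.triu_indices(size, k=1)
        if float(corr[iu].mean()) >= observed:
            exceed += 1
    return CoherenceResult(
        avg_corr=observed,
        empirical_p=(1 + exceed) / (n_sets + 1),
        n_null=n_sets,
    )
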
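"""Gene-level preprocessing: missing-value filtering, KNN imputation,
probe collapsing, fold-change filtering, and iterative two-way polishing.

The polishing step is what prepares a matrix for decomposition: each
iteration standardizes columns (centre, divide by the column standard
deviation) and then centres each row and rescales it to unit L2 norm.
Two iterations are the default; the map is close to idempotent, so extra
iterations change little.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "filter_missing",
    "knn_impute",
    "collapse_probes",
    "fold_change_filter",
    "two_way_polish",
]

log = logging.getLogger(__name__)


def filter_missing(
    mat: ExpressionMatrix,
    max_missing: int | None = 3,
    max_missing_frac: float | None = None,
) -> ExpressionMatrix:
    """Drop genes with more than ``max_missing`` missing cells.

    ``max_missing_frac`` expresses the threshold as a fraction of arrays
    instead; exactly one of the two must be given.  The default of 3
    missing cells reflects the usual tolerance on a 10-array design.
    """
    if (max_missing is None) == (max_missing_frac is None):
        raise ValueError("give exactly one of max_missing / max_missing_frac")
    if max_missing_frac is not None:
        max_missing = int(np.floor(max_missing_frac * mat.n_arrays))
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    counts = mat.missing_mask().sum(axis=1)
    keep = np.flatnonzero(counts <= max_missing)
    if keep.size == 0:
        raise ValueError("missing-value filter removed every gene")
    removed = counts > max_missing
    if removed.any():
        log.info(
            "filter_missing removed %d/%d genes (> %d missing)",
            int(removed.sum()), mat.n_genes, max_missing,
        )
    return mat.take_rows(keep)


def knn_impute(mat: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells with the mean of the k nearest complete genes.

    Distance is Euclidean over the columns the incomplete gene has
    observed.  When fewer than k complete candidate rows exist, the gene
    falls back to its own row mean, with a warning.  Observed cells are
    never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = mat.missing_mask()
    if not mask.any():
        return replace(mat, values=mat.values.copy())
    if mask.all(axis=1).any():
        bad = mat.gene_ids[int(np.flatnonzero(mask.all(axis=1))[0])]
        raise ValueError(f"gene {bad!r} has no observed values; cannot impute")

    values = mat.values.copy()
    complete = np.flatnonzero(~mask.any(axis=1))
    for i in np.flatnonzero(mask.any(axis=1)):
        obs = ~mask[i]
        if complete.size < k:
            warnings.warn(
                f"fewer than k={k} complete genes; row-mean fallback for "
                f"{mat.gene_ids[i]!r}",
                stacklevel=2,
            )
            values[i, mask[i]] = np.nanmean(mat.values[i])
            continue
        diffs = mat.values[np.ix_(complete, np.flatnonzero(obs))] - mat.values[i, obs]
        dists = np.sqrt((diffs**2).sum(axis=1))
        nearest = complete[np.argsort(dists, kind="stable")[:k]]
        for j in np.flatnonzero(mask[i]):
            values[i, j] = mat.values[nearest, j].mean()
    return replace(mat, values=values)


def collapse_probes(
    mat: ExpressionMatrix,
    probe_to_gene: dict[str, str],
    unmapped: str = "keep",
) -> ExpressionMatrix:
    """Average the rows of probes mapping to the same gene symbol.

    Probes absent from the mapping are kept under their own id (with a
    warning) or dropped, per ``unmapped``.  Column labels are untouched.
    """
    if unmapped not in ("keep", "drop"):
        raise ValueError("unmapped must be 'keep' or 'drop'")
    groups: dict[str, list[int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(mat.gene_ids):
        if probe in probe_to_gene:
            target = probe_to_gene[probe]
        else:
            n_unmapped += 1
            if unmapped == "drop":
                continue
            target = probe
        groups.setdefault(target, []).append(i)
    if n_unmapped and unmapped == "keep":
        warnings.warn(f"{n_unmapped} probes not in mapping; kept under probe ids", stacklevel=2)
    if not groups:
        raise ValueError("probe collapsing removed every row")
    gene_ids = list(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN probe groups
        values = np.vstack([np.nanmean(mat.values[rows], axis=0) for rows in groups.values()])
    return replace(mat, values=values, gene_ids=gene_ids)


def fold_change_filter(mat: ExpressionMatrix, min_fold: float = 2.0) -> ExpressionMatrix:
    """Drop genes whose maximum fold change across arrays is below ``min_fold``.

    Values are assumed log2, so the criterion is max - min >= log2(min_fold).
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    if mat.missing_mask().any():
        raise ValueError("impute missing values before fold-change filtering")
    span = mat.values.max(axis=1) - mat.values.min(axis=1)
    keep = np.flatnonzero(span >= np.log2(min_fold))
    if keep.size == 0:
        raise ValueError("fold-change filter removed every gene")
    log.info(
        "fold_change_filter kept %d/%d genes (max fold change >= %g)",
        keep.size, mat.n_genes, min_fold,
    )
    return mat.take_rows(keep)


def two_way_polish(mat: ExpressionMatrix, iterations: int = 2) -> ExpressionMatrix:
    """Iterated two-way standardization before SVD.

    Each iteration first centres every column and divides by its standard
    deviation (n-1 denominator), then centres every row and divides by its
    root sum of squares.  After the final iteration every row has zero mean
    and unit L2 norm to within 1e-8.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mat.missing_mask().any():
        raise ValueError("polishing requires a complete matrix; impute first")
    n, m = mat.shape
    if n < 3 or m < 3:
        raise ValueError("polishing needs at least 3 genes and 3 arrays")
    x = mat.values.copy()
    for it in range(iterations):
        x -= x.mean(axis=0)
        col_sd = x.std(axis=0, ddof=1)
        dead = np.flatnonzero(col_sd <= 0)
        if dead.size:
            raise ValueError(
                f"zero-variance column {mat.array_labels[int(dead[0])]!r} "
                f"at polish iteration {it + 1}"
            )
        x /= col_sd
        x -= x.mean(axis=1, keepdims=True)
        row_norm = np.sqrt((x**2).sum(axis=1))
        dead = np.flatnonzero(row_norm <= 0)
        if dead.size:
            raise ValueError(
                f"zero-norm row {mat.gene_ids[int(dead[0])]!r} "
                f"at polish iteration {it + 1}"
            )
        x /= row_norm[:, None]
    return replace(mat, values=x, polished=True)
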
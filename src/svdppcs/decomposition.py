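"""Thin SVD of a polished expression matrix.

The right singular vectors ("eigengenes") are fundamental expression
profiles over arrays; the left singular vectors hold per-gene loadings
that act as confidence scores for module membership.  Because singular
vectors are determined only up to a joint sign, a deterministic
orientation convention is applied so that regulation direction and chart
quadrants are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["SVDResult", "decompose", "variance_explained", "orient_signs"]


@dataclass
class SVDResult:
    """Thin SVD ``A = U diag(s) V^T`` of a genes x arrays matrix.

    ``left_vectors`` is n x m (gene loadings, columns u_j), ``eigengenes``
    is m x m (right singular vectors, columns v_j), ``singular_values``
    descending.  ``variance_fraction[j] = s_j^2 / sum_i s_i^2``.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    eigengenes: np.ndarray
    variance_fraction: np.ndarray
    gene_ids: list[str]
    array_labels: list[str]
    array_time: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.singular_values.size

    def reconstruct(self) -> np.ndarray:
        return self.left_vectors @ np.diag(self.singular_values) @ self.eigengenes.T

    def projections(self) -> np.ndarray:
        """n x m matrix of projections of gene rows onto eigengenes.

        Row i of A projected onto v_j equals s_j * u_ij.
        """
        return self.left_vectors * self.singular_values


def decompose(mat: ExpressionMatrix, orient: bool = True) -> SVDResult:
    """Full thin SVD with descending singular values.

    Expects a polished (or at least complete and finite) matrix with
    n >= m >= 2.  Signs are oriented by :func:`orient_signs` using the
    matrix's array_time covariate when present.
    """
    n, m = mat.shape
    if m < 2 or n < m:
        raise ValueError(f"need n >= m >= 2, got {n} x {m}")
    if not np.all(np.isfinite(mat.values)):
        raise ValueError("matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(mat.values, full_matrices=False)
    total = float((s**2).sum())
    res = SVDResult(
        singular_values=s,
        left_vectors=u,
        eigengenes=vt.T,
        variance_fraction=s**2 / total,
        gene_ids=list(mat.gene_ids),
        array_labels=list(mat.array_labels),
        array_time=None if mat.array_time is None else mat.array_time.copy(),
    )
    if orient:
        res = orient_signs(res, covariate=res.array_time)
    return res


def variance_explained(res: SVDResult, k: int) -> float:
    """Fraction of total variance captured by the first k components."""
    if not 1 <= k <= res.n_components:
        raise ValueError(f"k must be in [1, {res.n_components}]")
    return float(res.variance_fraction[:k].sum())


def orient_signs(res: SVDResult, covariate: np.ndarray | None = None) -> SVDResult:
    """Resolve the SVD sign ambiguity deterministically.

    With a covariate (typically time/age per array) each (u_j, v_j) pair
    is flipped together so corr(v_j, covariate) >= 0; otherwise so the
    largest-magnitude element of v_j is positive.  Singular values and the
    reconstruction are unchanged.
    """
    u = res.left_vectors.copy()
    v = res.eigengenes.copy()
    for j in range(res.n_components):
        vj = v[:, j]
        if covariate is not None:
            cv = np.asarray(covariate, dtype=float)
            if cv.shape != (vj.size,):
                raise ValueError("covariate length must equal the number of arrays")
            crit = float(np.corrcoef(vj, cv)[0, 1]) if np.std(vj) > 0 else 0.0
            flip = crit < 0
            if crit == 0.0:
                flip = vj[int(np.argmax(np.abs(vj)))] < 0
        else:
            flip = vj[int(np.argmax(np.abs(vj)))] < 0
        if flip:
            v[:, j] = -vj
            u[:, j] = -u[:, j]
    return SVDResult(
        singular_values=res.singular_values.copy(),
        left_vectors=u,
        eigengenes=v,
        variance_fraction=res.variance_fraction.copy(),
        gene_ids=list(res.gene_ids),
        array_labels=list(res.array_labels),
        array_time=None if res.array_time is None else res.array_time.copy(),
    )
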
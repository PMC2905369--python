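"""The SVD-p statistic.

SVD-p measures how dominant the leading SVD component of a gene-subset
matrix is, calibrated against an F distribution so that cluster size and
tightness are balanced: a larger cluster attains a lower SVD-p than a
smaller cluster of the same tightness (in the tight regime that matters
for cutoff selection).  It is not a p-value in the formal testing sense;
it is the data-driven criterion used to place the cutoffs that carve
modules out of a two-way chart.

For an r x c matrix A with leading singular value s1, the variance ratio

    F = s1^2 / (||A||_F^2 - s1^2)

is referred, deliberately without mean-square scaling, to the upper tail
of F(v1, v2) with

    v1 = r + c - 2,   v2 = r*c - 2r - c + 2.

The degrees of freedom come from the rank-one bilinear model
A = s*u*v' + E, which has r + c - 2 free parameters.  Plugging the raw
ratio into the F reference is an ad hoc calibration, but it is what makes
the cutoff sweep behave as intended: on a large mixed gene set the ratio
sits far below the F quantiles (SVD-p near 1), and it crosses any
threshold only once the swept-out subset is genuinely dominated by one
pattern.  A conventionally scaled mean-square ratio (available via
``scaled=True``) is so liberal at these matrix sizes that even pure noise
scores below 0.05, which would pin every cutoff at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["SvdPResult", "svdp", "svdp_profile"]


@dataclass(frozen=True)
class SvdPResult:
    f_value: float
    df1: int
    df2: int
    svd_p: float


def svdp(mat: np.ndarray, scaled: bool = False) -> SvdPResult:
    """Compute SVD-p for a (centred) gene-subset matrix.

    Parameters
    ----------
    mat
        Real r x c matrix, r >= 3 genes, with at least 1 residual degree
        of freedom (r*c - 2r - c + 2 >= 1).  The pipeline always passes
        polished (two-way centred) data.
    scaled
        Sensitivity switch: refer the mean-square ratio
        (s1^2/v1)/((||A||^2 - s1^2)/v2) to F(v1, v2) instead of the raw
        variance ratio.

    An exact rank-1 matrix has zero residual: f_value = +inf, svd_p = 0.
    """
    a = np.asarray(mat, dtype=float)
    if a.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    r, c = a.shape
    df1 = r + c - 2
    df2 = r * c - 2 * r - c + 2
    if r < 3 or c < 2 or df2 < 1:
        raise ValueError(
            f"matrix {r} x {c} too small for SVD-p (need r >= 3 and "
            f"r*c - 2r - c + 2 >= 1)"
        )
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix contains non-finite entries")
    total = float((a**2).sum())
    if total == 0.0:
        raise ValueError("all-zero matrix has no leading pattern")
    s1 = float(np.linalg.svd(a, compute_uv=False)[0])
    resid = max(total - s1**2, 0.0)
    if resid == 0.0:
        return SvdPResult(f_value=float("inf"), df1=df1, df2=df2, svd_p=0.0)
    f = s1**2 / resid
    if scaled:
        f = f * df2 / df1
    # upper tail of F(df1, df2); scipy evaluates it via the regularized
    # incomplete beta function, stable for large df2
    p = float(stats.f.sf(f, df1, df2))
    return SvdPResult(f_value=f, df1=df1, df2=df2, svd_p=p)


def svdp_profile(mats: Sequence[np.ndarray], scaled: bool = False) -> list[SvdPResult]:
    """SVD-p for an ordered family of gene-subset matrices.

    Used to trace how SVD-p falls as a cutoff line sweeps outward and the
    subset beyond it shrinks and tightens.  Errors are re-raised with the
    offending subset's position in the sequence.
    """
    out: list[SvdPResult] = []
    for i, m in enumerate(mats):
        try:
            out.append(svdp(m, scaled=scaled))
        except ValueError as exc:
            raise ValueError(f"subset {i}: {exc}") from exc
    return out
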
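"""Primary clusters (PCLs): mutually exclusive gene groups per eigengene.

Each gene is assigned to the eigengene onto which its expression profile
has the largest projection magnitude (|s_j u_ij|, since A v_j = s_j u_j).
Only the leading PCLs are retained — by default enough components to
reach a 60% variance target — and genes of discarded PCLs can be
reallocated to the retained eigengene with their next-largest projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import SVDResult

__all__ = ["PrimaryClusterSet", "assign_pcls", "retain_pcls"]


@dataclass
class PrimaryClusterSet:
    """Partition of genes over eigengene indices (1-based component rank)."""

    assignments: dict[str, int]
    retained: set[int]
    n_components: int

    @property
    def sizes(self) -> dict[int, int]:
        out = {j: 0 for j in sorted(self.retained)}
        for j in self.assignments.values():
            out[j] = out.get(j, 0) + 1
        return out

    @property
    def empty_indices(self) -> list[int]:
        """All component indices (1..m) with no member gene."""
        occupied = set(self.assignments.values())
        return [j for j in range(1, self.n_components + 1) if j not in occupied]

    def members(self, index: int) -> list[str]:
        return [g for g, j in self.assignments.items() if j == index]


def assign_pcls(res: SVDResult) -> PrimaryClusterSet:
    """Assign every gene to the PCL of its maximum-magnitude projection.

    Ties break toward the smaller component index (more variance).
    """
    proj = np.abs(res.projections())
    # argmax takes the first maximum, i.e. the lower component index
    best = np.argmax(proj, axis=1)
    assignments = {g: int(j) + 1 for g, j in zip(res.gene_ids, best)}
    return PrimaryClusterSet(
        assignments=assignments,
        retained=set(range(1, res.n_components + 1)),
        n_components=res.n_components,
    )


def retain_pcls(
    pcls: PrimaryClusterSet,
    res: SVDResult,
    k: int | None = None,
    variance_target: float | None = 0.60,
    reallocate: bool = True,
) -> PrimaryClusterSet:
    """Keep the PCLs of the first k eigengenes; optionally reallocate the rest.

    ``k`` explicit overrides ``variance_target`` (smallest k whose
    cumulative variance fraction reaches the target).  With
    ``reallocate``, each gene of a discarded PCL moves to the retained
    eigengene with its next-largest projection magnitude; otherwise those
    genes are dropped from the partition.
    """
    m = res.n_components
    if k is None:
        if variance_target is None or not 0 < variance_target <= 1:
            raise ValueError("need an explicit k or a variance_target in (0, 1]")
        cum = np.cumsum(res.variance_fraction)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, m)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}]")
    retained = set(range(1, k + 1))
    proj = np.abs(res.projections())
    order = {g: i for i, g in enumerate(res.gene_ids)}
    assignments: dict[str, int] = {}
    for g, j in pcls.assignments.items():
        if j in retained:
            assignments[g] = j
        elif reallocate:
            row = proj[order[g]]
            best = max(retained, key=lambda jj: (row[jj - 1], -jj))
            assignments[g] = best
    return PrimaryClusterSet(assignments=assignments, retained=retained, n_components=m)
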
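"""Two-way chart construction, SVD-p cutoff search, and chart splitting.

For one pattern pair, the genes of the pair's two primary clusters are
scattered with the paired left singular vectors as axes: y carries the
gene's loading in data set 1, x its loading in data set 2 (negated when
the pair correlation is negative, so conservation lies on the main
diagonal).  Four cutoffs a > 0 > b on y and c > 0 > d on x are found by
sweeping a line outward from zero and stopping when the SVD-p of the
genes strictly beyond the line first reaches the threshold phi; the chart
then splits into at most nine blocks, the centre block is dropped, and
the remaining blocks are the conserved / divergent modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .clusters import PrimaryClusterSet
from .decomposition import SVDResult
from .matrix import ExpressionMatrix
from .pairing import PatternPair
from .svdp import svdp

__all__ = [
    "TwoWayChart",
    "Cutoffs",
    "Module",
    "ModuleSet",
    "build_chart",
    "determine_cutoff",
    "split_chart",
]

log = logging.getLogger(__name__)

Direction = Literal["+y", "-y", "+x", "-x"]

#: block (y_side, x_side) -> module classification; sides are -1/0/+1
#: relative to the oriented axes (x already sign-aligned to the shared
#: pattern), so concordant corners are conserved.
BLOCK_CLASSIFICATION: dict[tuple[int, int], str] = {
    (1, 1): "conserved-up",
    (-1, -1): "conserved-down",
    (1, 0): "divergent-1-up",
    (-1, 0): "divergent-1-down",
    (0, 1): "divergent-2-up",
    (0, -1): "divergent-2-down",
    (1, -1): "divergent-opposite-1up2down",
    (-1, 1): "divergent-opposite-1down2up",
}

#: fixed M1-M8 ordering of the non-centre blocks for reporting
BLOCK_ORDER: list[tuple[int, int]] = [
    (-1, -1), (-1, 0), (0, -1), (1, 1), (1, 0), (0, 1), (-1, 1), (1, -1),
]


@dataclass
class TwoWayChart:
    """Scatter of the pair's PCL-union genes over paired loadings.

    ``gene_ids`` are in data set 1's namespace; ``gene_ids_2`` maps each
    to its counterpart (identical unless an ortholog mapping was given).
    ``x_flipped`` records whether x was negated for a negative pair
    correlation.
    """

    gene_ids: list[str]
    gene_ids_2: list[str]
    x: np.ndarray
    y: np.ndarray
    pair: PatternPair
    x_flipped: bool = False


@dataclass
class Cutoffs:
    """The four split positions and the SVD-p traces that produced them.

    a >= 0 and b <= 0 cut the y-axis, c >= 0 and d <= 0 the x-axis.  Each
    trace is the swept list of (position, svd_p) pairs.
    """

    a: float
    b: float
    c: float
    d: float
    trace: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


@dataclass
class Module:
    label: str
    block: tuple[int, int]
    classification: str
    gene_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleSet:
    """Modules extracted from one two-way chart plus their cutoffs."""

    pair: PatternPair
    cutoffs: Cutoffs
    modules: list[Module]
    chart: TwoWayChart

    def __iter__(self):
        return iter(self.modules)


def build_chart(
    pair: PatternPair,
    res1: SVDResult,
    res2: SVDResult,
    pcls1: PrimaryClusterSet,
    pcls2: PrimaryClusterSet,
    shared_genes: dict[str, str] | None = None,
) -> TwoWayChart:
    """Map the union of the pair's two PCLs onto the loading plane.

    ``shared_genes`` maps data-set-1 ids to data-set-2 ids (orthologs);
    by default ids shared verbatim form the universe.  Genes present in
    only one data set's universe are dropped with a logged count.
    """
    idx2_rows = {g: i for i, g in enumerate(res2.gene_ids)}
    if shared_genes is None:
        shared_genes = {g: g for g in res1.gene_ids if g in idx2_rows}
    to_1 = {v: k for k, v in shared_genes.items()}

    members1 = set(pcls1.members(pair.idx1))
    members2 = {to_1[g] for g in pcls2.members(pair.idx2) if g in to_1}
    union_1ns = members1 | members2
    chart_genes = sorted(g for g in union_1ns if g in shared_genes)
    dropped = len(union_1ns) - len(chart_genes)
    if dropped:
        log.info("build_chart dropped %d genes absent from the shared universe", dropped)
    if not chart_genes:
        raise ValueError(
            f"pattern pair ({pair.idx1}, {pair.idx2}) has no chart genes in "
            f"the shared universe"
        )
    idx1_rows = {g: i for i, g in enumerate(res1.gene_ids)}
    rows1 = [idx1_rows[g] for g in chart_genes]
    rows2 = [idx2_rows[shared_genes[g]] for g in chart_genes]
    y = res1.left_vectors[rows1, pair.idx1 - 1].copy()
    x = res2.left_vectors[rows2, pair.idx2 - 1].copy()
    flipped = pair.sign < 0
    if flipped:
        x = -x
    return TwoWayChart(
        gene_ids=chart_genes,
        gene_ids_2=[shared_genes[g] for g in chart_genes],
        x=x,
        y=y,
        pair=pair,
        x_flipped=flipped,
    )


def determine_cutoff(
    chart: TwoWayChart,
    direction: Direction,
    data: ExpressionMatrix,
    phi: float = 0.05,
    min_genes: int = 3,
    grid: np.ndarray | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Sweep one cutoff line outward from zero until SVD-p reaches phi.

    At each candidate position the SVD-p of the submatrix (chart genes
    strictly beyond the line) x (all arrays of the axis's data set) is
    evaluated; the first position with svd_p <= phi is the cutoff.  If phi
    is never reached the sweep continues until fewer than ``min_genes``
    genes remain beyond the line, and the last position with at least
    ``min_genes`` beyond is returned.

    By default the candidate positions are zero followed by the distinct
    loading values in the sweep direction, which makes the search exact:
    the subset beyond the line only changes at those values.  ``grid``
    overrides the positions (magnitudes, increasing).

    Returns the signed cutoff position and the (position, svd_p) trace.
    """
    if not 0 < phi < 1:
        raise ValueError("phi must be in (0, 1)")
    if min_genes < 3:
        raise ValueError("min_genes must be >= 3 (SVD-p needs 3 genes)")
    if direction not in ("+y", "-y", "+x", "-x"):
        raise ValueError(f"unknown direction {direction!r}")
    axis = chart.y if direction.endswith("y") else chart.x
    sign = 1.0 if direction.startswith("+") else -1.0
    vals = sign * axis  # sweep in magnitudes

    gene_list = chart.gene_ids if direction.endswith("y") else chart.gene_ids_2
    row_of = data.gene_index()
    try:
        rows = np.array([row_of[g] for g in gene_list])
    except KeyError as exc:
        raise ValueError(f"chart gene {exc.args[0]!r} missing from the data matrix") from None

    if grid is None:
        positions = np.concatenate([[0.0], np.unique(vals[vals > 0])])
    else:
        positions = np.asarray(grid, dtype=float)
        if positions.size == 0 or positions[0] != 0.0:
            positions = np.concatenate([[0.0], positions])
    if int((vals > 0).sum()) < min_genes:
        raise ValueError(
            f"degenerate chart: fewer than {min_genes} genes beyond zero in "
            f"direction {direction}"
        )

    trace: list[tuple[float, float]] = []
    last_valid: float | None = None
    for pos in positions:
        beyond = vals > pos
        if int(beyond.sum()) < min_genes:
            break
        sub = data.values[rows[beyond]]
        p = svdp(sub).svd_p
        trace.append((float(sign * pos), p))
        last_valid = float(sign * pos)
        if p <= phi:
            return last_valid, trace
    # phi never reached: fall back to the last position that still kept
    # min_genes beyond the line
    return float(last_valid), trace


def split_chart(
    chart: TwoWayChart,
    cutoffs: Cutoffs,
    min_module_size: int = 5,
) -> ModuleSet:
    """Split the chart into blocks and keep the non-centre ones as modules.

    A gene's block is (y side, x side) with side +1 above a / right of c,
    -1 below b / left of d, and 0 between.  The centre block (0, 0) is
    excluded from further study; blocks smaller than ``min_module_size``
    are discarded.  Corner blocks with concordant sides are conserved
    modules, edge blocks one-sided divergent, discordant corners
    divergent-opposite.
    """
    if not (cutoffs.a >= 0 >= cutoffs.b and cutoffs.c >= 0 >= cutoffs.d):
        raise ValueError("cutoffs must satisfy a >= 0 >= b and c >= 0 >= d")
    y_side = np.where(chart.y > cutoffs.a, 1, np.where(chart.y < cutoffs.b, -1, 0))
    x_side = np.where(chart.x > cutoffs.c, 1, np.where(chart.x < cutoffs.d, -1, 0))
    blocks: dict[tuple[int, int], list[str]] = {}
    for g, ys, xs in zip(chart.gene_ids, y_side, x_side):
        blocks.setdefault((int(ys), int(xs)), []).append(g)
    modules = []
    n_small = 0
    for rank, block in enumerate(BLOCK_ORDER, start=1):
        genes = blocks.get(block, [])
        if not genes:
            continue
        if len(genes) < min_module_size:
            n_small += 1
            continue
        modules.append(
            Module(
                label=f"M{rank}",
                block=block,
                classification=BLOCK_CLASSIFICATION[block],
                gene_ids=genes,
            )
        )
    if n_small:
        log.info("split_chart discarded %d blocks smaller than %d genes", n_small, min_module_size)
    return ModuleSet(pair=chart.pair, cutoffs=cutoffs, modules=modules, chart=chart)
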
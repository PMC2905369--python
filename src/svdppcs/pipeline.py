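"""End-to-end pipeline: polish, decompose, cluster, pair, split.

``run_pipeline`` wires the stages together for two preprocessed
expression matrices over aligned conditions and returns one module set
per pattern pair, together with every intermediate result needed for
reporting and auditing.  The run is deterministic given the inputs and
the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .chart import Cutoffs, ModuleSet, build_chart, determine_cutoff, split_chart
from .clusters import PrimaryClusterSet, assign_pcls, retain_pcls
from .config import RunConfig
from .decomposition import SVDResult, decompose
from .matrix import ExpressionMatrix
from .pairing import PatternPair, correlate_eigengenes, form_pairs, pair_unmatched
from .preprocess import two_way_polish

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one run produces, pattern pair by pattern pair."""

    svd1: SVDResult
    svd2: SVDResult
    pcls1: PrimaryClusterSet
    pcls2: PrimaryClusterSet
    correlation_table: pd.DataFrame
    pairs: list[PatternPair]
    module_sets: list[ModuleSet]
    config: RunConfig

    def all_modules(self):
        """Flat (pair, module) list over every chart."""
        return [(ms.pair, m) for ms in self.module_sets for m in ms.modules]

    def classification_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, m in self.all_modules():
            counts[m.classification] = counts.get(m.classification, 0) + 1
        return counts

    def n_conserved(self) -> int:
        return sum(1 for _, m in self.all_modules() if m.classification.startswith("conserved"))

    def n_divergent(self) -> int:
        return sum(1 for _, m in self.all_modules() if m.classification.startswith("divergent"))


def run_pipeline(
    mat1: ExpressionMatrix,
    mat2: ExpressionMatrix,
    config: RunConfig | None = None,
    shared_genes: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full module-identification pipeline on two data sets.

    Both matrices must be complete (imputed); they are polished here if
    not already.  Array counts must match in aligned condition order.
    """
    config = config or RunConfig()
    if mat1.n_arrays != mat2.n_arrays:
        raise ValueError(
            f"data sets have {mat1.n_arrays} vs {mat2.n_arrays} arrays; "
            f"align conditions before running the pipeline"
        )
    if not mat1.polished:
        mat1 = two_way_polish(mat1, config.polish_iterations)
    if not mat2.polished:
        mat2 = two_way_polish(mat2, config.polish_iterations)

    svd1 = decompose(mat1)
    svd2 = decompose(mat2)

    pcls1 = retain_pcls(
        assign_pcls(svd1), svd1,
        k=config.retention_k, variance_target=config.variance_target,
        reallocate=config.reallocate,
    )
    pcls2 = retain_pcls(
        assign_pcls(svd2), svd2,
        k=config.retention_k, variance_target=config.variance_target,
        reallocate=config.reallocate,
    )

    cand1 = config.candidates1 or sorted(pcls1.retained)
    cand2 = config.candidates2 or sorted(pcls2.retained)
    table = correlate_eigengenes(svd1, svd2, cand1, cand2)

    if config.manual_pairs:
        by_key = {(int(r.idx1), int(r.idx2)): r for r in table.itertuples(index=False)}
        pairs = []
        for i, j in config.manual_pairs:
            row = by_key.get((i, j))
            if row is None:
                raise ValueError(f"manual pair ({i}, {j}) outside the candidate sets")
            pairs.append(PatternPair(idx1=i, idx2=j, r_pair=float(row.r), p_value=float(row.p)))
    else:
        pairs = form_pairs(table, alpha=config.pairing_alpha, min_abs_r=config.pairing_min_abs_r)
        if config.pair_unmatched_candidates:
            used1 = {p.idx1 for p in pairs}
            used2 = {p.idx2 for p in pairs}
            for i in cand1:
                if i not in used1:
                    pairs.append(pair_unmatched(pcls2, i, side=1))
            for j in cand2:
                if j not in used2:
                    pairs.append(pair_unmatched(pcls1, j, side=2))
    if not pairs:
        log.warning("no pattern pairs found; returning an empty result")

    module_sets: list[ModuleSet] = []
    for pair in pairs:
        chart = build_chart(pair, svd1, svd2, pcls1, pcls2, shared_genes)
        trace: dict[str, list[tuple[float, float]]] = {}
        positions: dict[str, float] = {}
        for name, direction, data in (
            ("a", "+y", mat1), ("b", "-y", mat1), ("c", "+x", mat2), ("d", "-x", mat2),
        ):
            pos, tr = determine_cutoff(
                chart, direction, data, phi=config.phi, min_genes=config.min_genes_floor
            )
            positions[name] = pos
            trace[name] = tr
        cutoffs = Cutoffs(
            a=positions["a"], b=positions["b"], c=positions["c"], d=positions["d"],
            trace=trace,
        )
        module_sets.append(split_chart(chart, cutoffs, config.min_module_size))
        log.info(
            "pair (%d, %d): cutoffs a=%.4g b=%.4g c=%.4g d=%.4g, %d modules",
            pair.idx1, pair.idx2, cutoffs.a, cutoffs.b, cutoffs.c, cutoffs.d,
            len(module_sets[-1].modules),
        )

    return PipelineResult(
        svd1=svd1, svd2=svd2, pcls1=pcls1, pcls2=pcls2,
        correlation_table=table, pairs=pairs, module_sets=module_sets,
        config=config,
    )
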
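"""Plot-ready tabular exports: eigengene profiles, variance tables, PCL
membership, pair reports, cutoff traces, module reports with coherence
columns, and module heatmap matrices.  Everything is TSV with headers (or
JSON for the run summary); rendering is left to the user's plotting tool
of choice.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import avg_pairwise_corr, empirical_null_p
from .decomposition import SVDResult
from .matrix import ExpressionMatrix
from .pipeline import PipelineResult

__all__ = [
    "eigengene_frame",
    "variance_frame",
    "pcl_frame",
    "pair_frame",
    "module_frame",
    "cutoff_trace_frame",
    "export_heatmap_matrix",
    "write_run_report",
]


def eigengene_frame(res: SVDResult) -> pd.DataFrame:
    """Components x arrays table of right-singular-vector profiles."""
    return pd.DataFrame(
        res.eigengenes.T,
        index=[f"eigengene_{j + 1}" for j in range(res.n_components)],
        columns=res.array_labels,
    )


def variance_frame(res: SVDResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": np.arange(1, res.n_components + 1),
            "singular_value": res.singular_values,
            "variance_fraction": res.variance_fraction,
            "cumulative_fraction": np.cumsum(res.variance_fraction),
        }
    )


def pcl_frame(res: SVDResult, pcls) -> pd.DataFrame:
    proj = np.abs(res.projections())
    order = {g: i for i, g in enumerate(res.gene_ids)}
    rows = [
        (g, j, float(proj[order[g], j - 1]))
        for g, j in sorted(pcls.assignments.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "pcl_index", "projection_magnitude"])


def pair_frame(result: PipelineResult) -> pd.DataFrame:
    rows = [
        (
            p.idx1,
            p.idx2,
            np.nan if p.r_pair is None else p.r_pair,
            np.nan if p.p_value is None else p.p_value,
            p.kind,
        )
        for p in result.pairs
    ]
    return pd.DataFrame(rows, columns=["idx1", "idx2", "r", "p", "kind"])


def cutoff_trace_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for ms in result.module_sets:
        for name, trace in ms.cutoffs.trace.items():
            for pos, p in trace:
                rows.append((ms.pair.idx1, ms.pair.idx2, name, pos, p))
    return pd.DataFrame(rows, columns=["idx1", "idx2", "cutoff", "position", "svd_p"])


def module_frame(
    result: PipelineResult,
    mat1: ExpressionMatrix | None = None,
    mat2: ExpressionMatrix | None = None,
    null_sets: int = 0,
    null_size_range: tuple[int, int] = (10, 500),
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level module report; with matrices given, appends the modules'
    average within-module correlations (and empirical null p-values when
    ``null_sets`` > 0) in each data set."""
    rows = []
    for ms in result.module_sets:
        chart = ms.chart
        pos = {g: i for i, g in enumerate(chart.gene_ids)}
        for m in ms.modules:
            corr1 = corr2 = p1 = p2 = np.nan
            if mat1 is not None and m.size >= 2:
                corr1 = avg_pairwise_corr(mat1, m.gene_ids)
                if null_sets:
                    p1 = empirical_null_p(mat1, corr1, null_sets, null_size_range, seed).empirical_p
            if mat2 is not None and m.size >= 2:
                ids2 = [chart.gene_ids_2[pos[g]] for g in m.gene_ids]
                corr2 = avg_pairwise_corr(mat2, ids2)
                if null_sets:
                    p2 = empirical_null_p(mat2, corr2, null_sets, null_size_range, seed + 1).empirical_p
            for g in m.gene_ids:
                rows.append(
                    (
                        f"({ms.pair.idx1},{ms.pair.idx2})",
                        m.label,
                        m.classification,
                        g,
                        float(chart.x[pos[g]]),
                        float(chart.y[pos[g]]),
                        corr1,
                        corr2,
                        p1,
                        p2,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pair", "module", "classification", "gene_id", "x", "y",
            "corr1", "corr2", "empirical_p1", "empirical_p2",
        ],
    )


def export_heatmap_matrix(
    mat1: ExpressionMatrix,
    mat2: ExpressionMatrix,
    genes: list[str],
    genes2: list[str] | None = None,
    subsample: int | None = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Module genes x concatenated arrays of both data sets, row-standardized.

    Each data set's rows are standardized across its own arrays before
    concatenation, so within-data-set patterns stay comparable.  Large
    modules are subsampled (seeded) to ``subsample`` genes.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty module")
    if genes2 is None:
        genes2 = list(genes)
    if len(genes2) != len(genes):
        raise ValueError("genes and genes2 must align")
    if subsample is not None and len(genes) > subsample:
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(genes), size=subsample, replace=False))
        genes = [genes[i] for i in keep]
        genes2 = [genes2[i] for i in keep]

    def standardized(mat: ExpressionMatrix, ids: list[str]) -> np.ndarray:
        sub = mat.subset_genes(ids).values
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (sub - sub.mean(axis=1, keepdims=True)) / sd

    left = standardized(mat1, genes)
    right = standardized(mat2, genes2)
    cols = [f"1:{c}" for c in mat1.array_labels] + [f"2:{c}" for c in mat2.array_labels]
    return pd.DataFrame(np.hstack([left, right]), index=genes, columns=cols)


def write_run_report(
    outdir,
    result: PipelineResult,
    mat1: ExpressionMatrix,
    mat2: ExpressionMatrix,
    null_sets: int | None = None,
) -> dict:
    """Write every artifact of a run into ``outdir``; returns the summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eigengene_frame(result.svd1).to_csv(out / "eigengenes_1.tsv", sep="\t")
    eigengene_frame(result.svd2).to_csv(out / "eigengenes_2.tsv", sep="\t")
    variance_frame(result.svd1).to_csv(out / "variance_1.tsv", sep="\t", index=False)
    variance_frame(result.svd2).to_csv(out / "variance_2.tsv", sep="\t", index=False)
    pcl_frame(result.svd1, result.pcls1).to_csv(out / "pcl_1.tsv", sep="\t", index=False)
    pcl_frame(result.svd2, result.pcls2).to_csv(out / "pcl_2.tsv", sep="\t", index=False)
    pair_frame(result).to_csv(out / "pairs.tsv", sep="\t", index=False)
    cutoff_trace_frame(result).to_csv(out / "cutoff_traces.tsv", sep="\t", index=False)
    n_null = result.config.null_sets if null_sets is None else null_sets
    modules = module_frame(
        result, mat1, mat2,
        null_sets=n_null,
        null_size_range=result.config.null_size_range,
        seed=result.config.seed,
    )
    modules.to_csv(out / "modules.tsv", sep="\t", index=False)
    for ms in result.module_sets:
        chart = ms.chart
        pos = {g: i for i, g in enumerate(chart.gene_ids)}
        for m in ms.modules:
            ids2 = [chart.gene_ids_2[pos[g]] for g in m.gene_ids]
            hm = export_heatmap_matrix(mat1, mat2, m.gene_ids, ids2, seed=result.config.seed)
            hm.to_csv(out / f"heatmap_{ms.pair.idx1}_{ms.pair.idx2}_{m.label}.tsv", sep="\t")
    summary = {
        "n_pairs": len(result.pairs),
        "n_modules": len(result.all_modules()),
        "n_conserved": result.n_conserved(),
        "n_divergent": result.n_divergent(),
        "classification_counts": result.classification_counts(),
        "cutoffs": [
            {
                "pair": [ms.pair.idx1, ms.pair.idx2],
                "a": ms.cutoffs.a, "b": ms.cutoffs.b, "c": ms.cutoffs.c, "d": ms.cutoffs.d,
            }
            for ms in result.module_sets
        ],
        "config": json.loads(json.dumps(result.config.__dict__, default=list)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
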
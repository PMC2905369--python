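"""Gene-by-array expression matrix container and delimited-text I/O.

The matrix convention throughout the package is genes in rows, arrays
(samples / time points) in columns, values on a log scale.  Missing cells
are carried as NaN until imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix"]


@dataclass
class ExpressionMatrix:
    """A labelled genes x arrays expression matrix.

    Parameters
    ----------
    values
        Real matrix, one row per gene and one column per array.  NaN marks
        a missing measurement.
    gene_ids
        Unique row labels (probe or gene-symbol identifiers).
    array_labels
        Unique column labels.
    array_time
        Optional per-array covariate (e.g. age in days or hours), used to
        orient singular-vector signs and to label regulation direction.
    polished
        True once the matrix has been through two-way polishing, after
        which every row is centred with unit L2 norm.
    """

    values: np.ndarray
    gene_ids: list[str]
    array_labels: list[str]
    array_time: np.ndarray | None = None
    polished: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.array_labels = list(self.array_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.array_labels) != m:
            raise ValueError(f"{len(self.array_labels)} array labels for {m} columns")
        if len(set(self.array_labels)) != m:
            dup = _first_duplicate(self.array_labels)
            raise ValueError(f"duplicate array label: {dup!r}")
        if self.array_time is not None:
            self.array_time = np.asarray(self.array_time, dtype=float)
            if self.array_time.shape != (m,):
                raise ValueError("array_time length must match the number of arrays")

    # -- basic views ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.array_labels)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row subset in the given order; unknown ids raise KeyError."""
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return replace(
            self,
            values=self.values[rows].copy(),
            gene_ids=list(gene_ids),
        )

    def take_rows(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return replace(
            self,
            values=self.values[rows].copy(),
            gene_ids=[self.gene_ids[i] for i in rows],
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def read_matrix(
    path,
    sep: str = "\t",
    missing_token: str = "NA",
    array_time: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    The first row holds array labels, the first column gene identifiers.
    Cells equal to ``missing_token`` (or empty) become NaN; any other
    non-numeric cell raises with its row/column location.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    labels = [h.strip() for h in header[1:]]
    if len(set(labels)) != len(labels):
        # checked on the raw header: pandas would silently rename duplicates
        raise ValueError(f"duplicate array label: {_first_duplicate(labels)!r}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    df.columns = labels
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell == missing_token or cell == "":
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at gene {df.index[i]!r}, "
                        f"array {labels[j]!r}"
                    ) from None
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        array_labels=labels,
        array_time=array_time,
    )


def write_matrix(mat: ExpressionMatrix, path, sep: str = "\t", missing_token: str = "NA") -> None:
    """Write the matrix in the same layout ``read_matrix`` expects."""
    df = mat.to_frame()
    df.to_csv(path, sep=sep, na_rep=missing_token, index_label="gene_id", float_format="%.12g")
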
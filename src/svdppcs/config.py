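"""Run configuration: every tunable of the pipeline in one round-trippable
dataclass, serialized as flat YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline knobs with their documented defaults.

    Preprocessing: ``max_missing`` missing cells tolerated per gene,
    ``knn_k`` neighbours for imputation, ``min_fold`` maximum-fold-change
    filter (log2 data), ``polish_iterations`` two-way polishing sweeps.
    Retention: explicit ``retention_k`` or the cumulative
    ``variance_target`` (0.60); ``reallocate`` moves genes of discarded
    PCLs to their next-best retained eigengene.  Pairing:
    significance level ``pairing_alpha`` and correlation floor
    ``pairing_min_abs_r``; ``manual_pairs`` overrides automatic matching;
    ``candidates1``/``candidates2`` restrict pairing to the listed
    eigengene indices (default: all retained).  Chart splitting: SVD-p
    threshold ``phi``, reported-module floor ``min_module_size``, and the
    cutoff-search floor ``min_genes_floor``.
    """

    max_missing: int = 3
    knn_k: int = 10
    min_fold: float = 2.0
    polish_iterations: int = 2

    retention_k: int | None = None
    variance_target: float = 0.60
    reallocate: bool = True

    pairing_alpha: float = 0.01
    pairing_min_abs_r: float = 0.6
    manual_pairs: list[tuple[int, int]] | None = None
    candidates1: list[int] | None = None
    candidates2: list[int] | None = None
    pair_unmatched_candidates: bool = True

    phi: float = 0.05
    min_module_size: int = 5
    min_genes_floor: int = 3

    null_sets: int = 500
    null_size_range: tuple[int, int] = (10, 500)

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.phi < 1:
            raise ValueError("phi must be in (0, 1)")
        if not 0 < self.pairing_alpha < 1:
            raise ValueError("pairing_alpha must be in (0, 1)")
        if not 0 <= self.pairing_min_abs_r <= 1:
            raise ValueError("pairing_min_abs_r must be in [0, 1]")
        if self.min_genes_floor < 3:
            raise ValueError("min_genes_floor must be >= 3")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.retention_k is None and not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        doc["null_size_range"] = list(self.null_size_range)
        if self.manual_pairs is not None:
            doc["manual_pairs"] = [list(p) for p in self.manual_pairs]
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
            except (OSError, ValueError):
                # not a readable path: treat it as a YAML document string
                doc = yaml.safe_load(source)
        if not isinstance(doc, dict):
            raise ValueError("config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "null_size_range" in doc and doc["null_size_range"] is not None:
            doc["null_size_range"] = tuple(doc["null_size_range"])
        if doc.get("manual_pairs"):
            doc["manual_pairs"] = [tuple(p) for p in doc["manual_pairs"]]
        return cls(**doc)
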
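"""Generic clustering baseline: PAM (k-medoids) with average-silhouette
model selection.

Kept as a point of comparison only — on the simulation benchmark the
average-silhouette criterion under-counts the planted structure (it
cannot represent the diffuse null group as a cluster of its own), which
is precisely the failure mode the chart-splitting approach avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = ["pam", "select_k_by_silhouette", "PamSelection"]


def _build(d: np.ndarray, k: int) -> list[int]:
    """PAM BUILD phase: greedy medoid seeding minimizing total distance."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -1.0
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, d[new])
    return medoids


def pam(d: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Classic deterministic BUILD + SWAP: starting from the greedy seeding,
    repeatedly apply the single (medoid, non-medoid) swap that most
    reduces the total distance to the nearest medoid, until no swap
    improves.  Returns (labels, medoid indices).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    medoids = _build(d, k)
    for _ in range(max_iter):
        dm = d[medoids]  # k x n
        order = np.argsort(dm, axis=0)
        d1 = dm[order[0], np.arange(n)]  # nearest medoid distance
        d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        nearest_is = order[0]  # index into medoids
        cost = d1.sum()
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # removing medoid mi: points whose nearest is mi fall back to d2
            base = np.where(nearest_is == mi, d2, d1)
            for h in range(n):
                if h in medoids:
                    continue
                delta = np.minimum(base, d[h]).sum() - cost
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    dm = d[medoids]
    labels = np.argmin(dm, axis=0)
    return labels, np.asarray(medoids)


@dataclass(frozen=True)
class PamSelection:
    best_k: int
    silhouettes: dict[int, float]
    labels: np.ndarray


def select_k_by_silhouette(
    x: np.ndarray,
    k_range: range = range(2, 7),
) -> PamSelection:
    """Cluster rows of ``x`` with PAM for each k; pick the k with the
    largest average silhouette width (Euclidean distances)."""
    x = np.asarray(x, dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        labels, _ = pam(d, k)
        labels_by_k[k] = labels
        sil[k] = float(silhouette_score(d, labels, metric="precomputed"))
    best_k = max(sil, key=lambda k: (sil[k], -k))
    return PamSelection(best_k=best_k, silhouettes=sil, labels=labels_by_k[best_k])
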
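"""Population structure from encoded CNV genotypes.

Provides pairwise distances between individuals, agglomerative
hierarchical clustering with newick export (the tree-building step usually
labelled "N-J clustering" in array-CNV studies, computed here as average-
linkage agglomeration with deterministic tie-breaking), and PCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["DistanceMatrix", "ClusterNode", "PcaResult", "pairwise_distance",
           "hierarchical_cluster", "pca"]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        if np.isnan(v).any():
            raise ValueError("distance matrix contains NaN")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def between(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])


def pairwise_distance(encoded: pd.DataFrame, metric: str = "euclidean") -> DistanceMatrix:
    """Row-wise euclidean or manhattan distances on an encoded matrix."""
    if metric not in {"euclidean", "manhattan"}:
        raise ValueError(f"unknown metric {metric!r}")
    if len(encoded) < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    scipy_metric = "cityblock" if metric == "manhattan" else "euclidean"
    condensed = pdist(encoded.to_numpy(dtype=float), metric=scipy_metric)
    return DistanceMatrix(tuple(encoded.index.astype(str)), squareform(condensed))


@dataclass
class ClusterNode:
    """Node of an ultrametric cluster tree; leaves are at height 0.

    Internal nodes sit at half the linkage distance of their merge, so a
    two-leaf tree joins at d/2 and leaf-to-leaf path length equals d
    (the additive convention used by UPGMA trees).
    """

    height: float
    label: Optional[str] = None
    children: tuple["ClusterNode", ...] = ()

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return f"{self._newick_node()};"

    def _newick_node(self, parent_height: Optional[float] = None) -> str:
        if not self.children:
            body = self.label or ""
        else:
            body = "(" + ",".join(
                c._newick_node(self.height) for c in self.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.10g}"


_LINKAGES = {"average", "complete", "single"}


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "average") -> ClusterNode:
    """Agglomerative clustering with deterministic tie-breaking.

    At each step the pair of clusters with the smallest distance merges;
    ties are broken lexicographically on the pair's smallest member ids so
    the tree is reproducible bit-for-bit.  ``average`` is size-weighted
    (UPGMA); ``complete``/``single`` are max/min linkage.  The merge node's
    height is half the linkage distance.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(dist.ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    d = dist.values.astype(float).copy()
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, label=dist.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    # representative id (lexicographically smallest member) for tie-breaking
    reps = {i: dist.ids[i] for i in range(n)}
    active = list(range(n))

    while len(active) > 1:
        best: Optional[tuple[float, str, str, int, int]] = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                ra, rb = sorted((reps[i], reps[j]))
                cand = (d[i, j], ra, rb, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        assert best is not None
        dij, _, _, i, j = best
        new = n + (n - len(active))  # fresh index
        nodes[new] = ClusterNode(height=dij / 2.0, children=(nodes[i], nodes[j]))
        sizes[new] = sizes[i] + sizes[j]
        reps[new] = min(reps[i], reps[j])

        grown = np.pad(d, ((0, new + 1 - d.shape[0]),) * 2)
        for k in active:
            if k in (i, j):
                continue
            if linkage == "average":
                dk = (d[i, k] * sizes[i] + d[j, k] * sizes[j]) / (sizes[i] + sizes[j])
            elif linkage == "complete":
                dk = max(d[i, k], d[j, k])
            else:
                dk = min(d[i, k], d[j, k])
            grown[new, k] = grown[k, new] = dk
        d = grown
        active = [k for k in active if k not in (i, j)] + [new]

    return nodes[active[0]]


@dataclass(frozen=True)
class PcaResult:
    """PCA coordinates plus per-component fractions of *total* variance."""

    coordinates: pd.DataFrame            # samples x PC1..PCk
    explained_fraction: np.ndarray       # length k, of total variance
    loadings: pd.DataFrame               # features x PC1..PCk

    def __post_init__(self) -> None:
        ef = self.explained_fraction
        if np.any(ef < -1e-12) or np.any(ef > 1 + 1e-12):
            raise ValueError("explained fractions must lie in [0, 1]")
        if np.any(np.diff(ef) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")
        if ef.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must sum to <= 1")


def pca(encoded: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Column-centred SVD principal components.

    explained_fraction_k = sigma_k^2 / sum sigma^2 over *all* components,
    so reported fractions match the usual "PC1 explains x% of the total
    variation" phrasing.  Each component's sign is fixed so its largest-
    magnitude loading is positive.  A matrix with zero total variance is
    rejected.
    """
    X = encoded.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples for PCA")
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total <= 1e-12 * max(n, p):
        raise ValueError("matrix is constant: zero total variance")
    for k in range(n_components):
        pivot = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_components] * s[:n_components]
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=encoded.index, columns=cols),
        explained_fraction=(s[:n_components] ** 2) / total,
        loadings=pd.DataFrame(Vt[:n_components].T, index=encoded.columns, columns=cols),
    )
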
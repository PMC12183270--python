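"""Functional connectivity matrices and their KNN brain graphs.

For each subject and atlas: Pearson correlation between every pair of ROI
time courses, Fisher z-transform (atanh, with correlations clipped away from
±1), then an undirected weighted k-nearest-neighbor graph. "Nearest" is by
largest |z| — strong negative coupling is as informative as positive — and
the edge set is the union over both directions, so every node keeps degree
>= k. Node i's feature vector is row i of the Fisher-z matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .cohort import Cohort

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric n×n Fisher-z connectivity, zero diagonal."""

    atlas: str
    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity entries must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainGraph:
    """Undirected weighted graph over ROIs; unit consumed by the classifier."""

    n_nodes: int
    node_features: np.ndarray  # (n, n): row i = FCN row i
    edges: np.ndarray  # (m, 2) int, i < j, each unordered pair once
    weights: np.ndarray  # (m,) Fisher-z values
    label: int
    subject_id: str
    atlas: str = ""

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def to_edge_list(self) -> str:
        """``src  dst  weight`` text export, 0-based node indices."""
        lines = [f"{i}\t{j}\t{w:.17g}" for (i, j), w in zip(self.edges, self.weights)]
        return "\n".join(lines) + ("\n" if lines else "")


def pearson_fcn(series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns of a T×n series.

    Constant columns get zero correlation to everything (with a warning);
    their diagonal entry stays 1.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 3:
        raise ValueError("series must be a T×n matrix with T >= 3")
    sd = series.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant ROI column(s): correlations set to 0",
                       int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(series, rowvar=False)
    r = np.asarray(r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return r


def fisher_z(r_matrix: np.ndarray, atlas: str = "", subject_id: str = "") -> ConnectivityMatrix:
    """atanh with clipping at ±(1 − 1e-7); diagonal forced to 0."""
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(atlas=atlas, subject_id=subject_id, values=z)


def knn_graph(fcn: ConnectivityMatrix, k: int, metric: str = "abs_z",
              label: int = -1) -> BrainGraph:
    """Union-symmetrized k-nearest-neighbor graph of a connectivity matrix.

    Per node, the k neighbors with the largest |z| (ties broken toward the
    lower node index); ``metric="euclidean"`` instead ranks by distance
    between FCN rows. Edge weights are the Fisher-z values.
    """
    n = fcn.n
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    z = fcn.values
    if metric == "abs_z":
        score = np.abs(z).astype(float)  # larger = nearer
    elif metric == "euclidean":
        d = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
        score = -d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(score, -np.inf)
    # stable ranking: by (-score, index)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -score), axis=1)
    nearest = order[:, :k]
    pairs = set()
    for i in range(n):
        for j in nearest[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    weights = z[edges[:, 0], edges[:, 1]]
    return BrainGraph(
        n_nodes=n,
        node_features=z.copy(),
        edges=edges,
        weights=weights,
        label=label,
        subject_id=fcn.subject_id,
        atlas=fcn.atlas,
    )


def subject_graph(series: np.ndarray, k: int, metric: str = "abs_z",
                  label: int = -1, subject_id: str = "", atlas: str = "") -> BrainGraph:
    """pearson_fcn ∘ fisher_z ∘ knn_graph for one subject/atlas."""
    fcn = fisher_z(pearson_fcn(series), atlas=atlas, subject_id=subject_id)
    return knn_graph(fcn, k, metric=metric, label=label)


def build_graph_dataset(cohort: Cohort, atlas: str, k: int,
                        metric: str = "abs_z") -> List[BrainGraph]:
    """One labeled BrainGraph per subject for the given atlas."""
    if atlas not in cohort.atlas_names:
        raise ValueError(f"atlas {atlas!r} not present in cohort")
    return [
        subject_graph(s.series[atlas], k, metric=metric, label=s.label,
                      subject_id=s.subject_id, atlas=atlas)
        for s in cohort.subjects
    ]
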
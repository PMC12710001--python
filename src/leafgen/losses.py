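"""Per-leaf reconstruction losses for offset-based leaf generation.

Four terms supervise one generated leaf against the real leaf it was derived
from: a skeleton anchoring term (L1 on the offsets of skeleton points), a
bidirectional Chamfer term pulling the cloud onto the real leaf, an edge-
regularity term pushing k-NN edge lengths toward a target spacing, and a
graph-Laplacian smoothness term penalizing points far from their neighbor
centroids.  Each loss comes with its analytic gradient with respect to the
generated points (graph structure and nearest-neighbor assignments treated
as locally constant), so the training loop needs no autodiff framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LossWeights",
    "KNNGraph",
    "skeleton_loss",
    "skeleton_loss_grad",
    "chamfer_distance",
    "chamfer_grad",
    "build_knn_graph",
    "edge_loss",
    "edge_loss_grad",
    "smoothness_loss",
    "smoothness_loss_grad",
    "total_loss",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite training objective.

    Defaults follow the reference weighting: skeleton 1, chamfer 0.1,
    edges 0.1, smoothness 10, and 0.01 on the grouped distribution terms
    (CMMD + FID + PR treated as one group scaled by ``w_distribution``).
    """

    w_skeleton: float = 1.0
    w_chamfer: float = 0.1
    w_edges: float = 0.1
    w_smooth: float = 10.0
    w_distribution: float = 0.01

    def __post_init__(self) -> None:
        if min(self.w_skeleton, self.w_chamfer, self.w_edges, self.w_smooth,
               self.w_distribution) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class KNNGraph:
    """k-NN graph with a hard connection radius d_max (strict: dist < d_max).

    Stored as a padded (N, k) neighbor-index matrix with a validity mask;
    ``neighbor_sets`` exposes the per-point index arrays.
    """

    nbr_idx: np.ndarray  # (N, k) int, padded
    nbr_valid: np.ndarray  # (N, k) bool
    k: int
    d_max: float

    @property
    def n_points(self) -> int:
        return len(self.nbr_idx)

    @property
    def neighbor_sets(self) -> list[np.ndarray]:
        return [self.nbr_idx[u][self.nbr_valid[u]] for u in range(self.n_points)]

    @property
    def degrees(self) -> np.ndarray:
        return self.nbr_valid.sum(axis=1)

    def edges(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Directed edge arrays (u, v, length) over all neighbor relations."""
        u = np.repeat(np.arange(self.n_points), self.k)[self.nbr_valid.ravel()]
        v = self.nbr_idx.ravel()[self.nbr_valid.ravel()]
        lengths = np.linalg.norm(points[u] - points[v], axis=1) if len(u) else np.empty(0)
        return u, v, lengths


def skeleton_loss(offsets: np.ndarray, mask: np.ndarray) -> float:
    """Sum of L1 norms of the offsets at skeleton points."""
    offsets = np.asarray(offsets, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if len(offsets) != len(mask):
        raise ValueError("offsets and mask length mismatch")
    return float(np.abs(offsets[mask]).sum())


def skeleton_loss_grad(offsets: np.ndarray, mask: np.ndarray) -> np.ndarray:
    grad = np.zeros_like(np.asarray(offsets, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    grad[mask] = np.sign(offsets[mask])
    return grad


def chamfer_distance(a: np.ndarray, b: np.ndarray, squared: bool = True,
                     reduction: str = "sum") -> float:
    """Bidirectional Chamfer distance between two point sets.

    ``reduction='sum'`` is the loss form: sum over each set of the nearest
    distance to the other set.  ``reduction='mean'`` averages each direction
    and halves the sum — the symmetric mean nearest-neighbor distance used
    for reporting in physical units.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("chamfer_distance requires non-empty sets")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    if squared:
        d_ab, d_ba = d_ab**2, d_ba**2
    if reduction == "sum":
        return float(d_ab.sum() + d_ba.sum())
    if reduction == "mean":
        return float(0.5 * (d_ab.mean() + d_ba.mean()))
    raise ValueError(f"unknown reduction {reduction!r}")


def chamfer_grad(generated: np.ndarray, real: np.ndarray) -> np.ndarray:
    """Gradient of the squared, sum-reduced Chamfer loss w.r.t. ``generated``."""
    generated = np.asarray(generated, dtype=float)
    real = np.asarray(real, dtype=float)
    grad = np.zeros_like(generated)
    # term 1: each generated point pulled toward its nearest real point
    _, idx = cKDTree(real).query(generated)
    grad += 2.0 * (generated - real[idx])
    # term 2: each real point pulls its nearest generated point
    _, idx = cKDTree(generated).query(real)
    np.add.at(grad, idx, 2.0 * (generated[idx] - real))
    return grad


def build_knn_graph(points: np.ndarray, k: int, d_max: float) -> KNNGraph:
    """Up to ``k`` nearest neighbors per point, connected only when the
    distance is strictly below ``d_max``; isolated points are allowed."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(points)
    kq = min(k + 1, n)
    dist, idx = cKDTree(points).query(points, k=kq)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    self_col = idx == np.arange(n)[:, None]
    # drop the self column (ties may place it anywhere in the first kq slots)
    keep = ~self_col
    # ensure exactly kq-1 kept per row even for duplicate points
    excess = keep.sum(axis=1) - (kq - 1)
    for u in np.flatnonzero(excess > 0):  # rare: duplicate coordinates hide self
        on = np.flatnonzero(keep[u])
        keep[u, on[kq - 1:]] = False
    order = np.argsort(~keep, axis=1, kind="stable")
    idx_k = np.take_along_axis(idx, order, axis=1)[:, : max(kq - 1, 1)]
    dist_k = np.take_along_axis(dist, order, axis=1)[:, : max(kq - 1, 1)]
    if kq - 1 == 0:
        return KNNGraph(nbr_idx=np.zeros((n, 1), dtype=int),
                        nbr_valid=np.zeros((n, 1), dtype=bool), k=k, d_max=float(d_max))
    valid = (dist_k < d_max) & np.isfinite(dist_k)
    return KNNGraph(nbr_idx=idx_k[:, :k].astype(int), nbr_valid=valid[:, :k],
                    k=k, d_max=float(d_max))


def edge_loss(graph: KNNGraph, points: np.ndarray, l_bar: float) -> float:
    """Mean absolute deviation of k-NN edge lengths from the target spacing."""
    _, _, lengths = graph.edges(np.asarray(points, dtype=float))
    if len(lengths) == 0:
        log.warning("edge_loss: graph has no edges; returning 0")
        return 0.0
    return float(np.abs(lengths - l_bar).mean())


def edge_loss_grad(graph: KNNGraph, points: np.ndarray, l_bar: float) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    grad = np.zeros_like(points)
    u, v, lengths = graph.edges(points)
    if len(lengths) == 0:
        return grad
    safe = np.where(lengths > 1e-12, lengths, 1.0)
    coef = np.sign(lengths - l_bar) / safe / len(lengths)
    diff = (points[u] - points[v]) * coef[:, None]
    np.add.at(grad, u, diff)
    np.add.at(grad, v, -diff)
    return grad


def _laplacian_rows(points: np.ndarray, graph: KNNGraph) -> tuple[np.ndarray, np.ndarray]:
    """Rows Q_u = mean(neighbors) - p_u for non-isolated points.

    Returns (Q, non_isolated_index).  Isolated points are excluded: their row
    would reduce to -p_u, penalizing absolute position instead of smoothness.
    """
    points = np.asarray(points, dtype=float)
    deg = graph.degrees
    keep = np.flatnonzero(deg > 0)
    if len(keep) == 0:
        return np.empty((0, points.shape[1])), keep
    nbr_pts = points[graph.nbr_idx] * graph.nbr_valid[:, :, None]
    means = nbr_pts[keep].sum(axis=1) / deg[keep, None]
    return means - points[keep], keep


def smoothness_loss(points: np.ndarray, graph: KNNGraph, squared: bool = True) -> float:
    """Laplacian smoothing objective on the rows Q = L P.

    Default is the standard quadratic form, the sum of squared Euclidean
    row norms: its gradient vanishes as each point approaches its neighbor
    centroid, so once the surface is smooth the objective stops displacing
    points (in particular the anchored skeleton points).  ``squared=False``
    gives the sum of (unsquared) row norms, whose constant-magnitude
    gradient keeps pulling even on smooth clouds.
    """
    q, _ = _laplacian_rows(points, graph)
    if len(q) == 0:
        return 0.0
    if squared:
        return float((q**2).sum())
    return float(np.linalg.norm(q, axis=1).sum())


def smoothness_loss_grad(points: np.ndarray, graph: KNNGraph, squared: bool = True) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    grad = np.zeros_like(points)
    q, keep = _laplacian_rows(points, graph)
    if len(q) == 0:
        return grad
    if squared:
        g = 2.0 * q
    else:
        norms = np.linalg.norm(q, axis=1)
        g = np.divide(q, np.where(norms > 1e-12, norms, 1.0)[:, None])
    np.subtract.at(grad, keep, g)
    deg = graph.degrees
    valid = graph.nbr_valid[keep]
    flat_idx = graph.nbr_idx[keep].ravel()[valid.ravel()]
    contrib = np.repeat(g / deg[keep, None], valid.sum(axis=1), axis=0)
    np.add.at(grad, flat_idx, contrib)
    return grad


def total_loss(parts: dict[str, float], weights: LossWeights) -> float:
    """Weighted total: the three distribution terms share ``w_distribution``."""
    for name, val in parts.items():
        if not np.isfinite(val):
            raise ValueError(f"loss term {name!r} is non-finite: {val}")
    get = lambda k: float(parts.get(k, 0.0))
    return (
        weights.w_skeleton * get("skeleton")
        + weights.w_chamfer * get("chamfer")
        + weights.w_edges * get("edges")
        + weights.w_smooth * get("smooth")
        + weights.w_distribution * (get("cmmd") + get("fid") + get("pr"))
    )
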
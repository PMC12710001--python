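"""Skeleton extraction from single-leaf point clouds.

Recovers a two-part skeleton (main axis along the leaf length, lateral axis
along the width at the leaf midsection) from an unlabeled 3D point cloud.
The main axis is an ordered chain of nodes fitted to the whole cloud as a
principal curve.  The lateral axis is obtained by slicing the cloud around
the median chain node ``m`` along the second principal component direction
``n`` — keeping points within distance ``tau`` of the line ``l = m + c n`` —
and re-running the chain fit on that slice only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import PART_LATERAL, PART_MAIN, LeafSkeleton

__all__ = [
    "ExtractionConfig",
    "MainAxisChain",
    "DegenerateCloudError",
    "EmptySliceError",
    "fit_chain",
    "fit_main_axis",
    "slice_lateral_region",
    "extract_skeleton",
]


class DegenerateCloudError(ValueError):
    """Cloud has too few points or (numerically) less than rank-2 extent."""


class EmptySliceError(ValueError):
    """The midsection slice is empty; suggests a larger tau."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the two-step skeleton extraction.

    ``tau`` is the slice half-width in model units; when None it defaults to
    10% of the cloud's extent along its first principal component, wide
    enough that strongly curved lateral cross-sections are not truncated by
    the distance-to-line cut.
    """

    n_main: int = 40
    n_lateral: int = 21
    tau: float | None = None
    chain_smoothness: float = 0.5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_main < 3 or self.n_lateral < 3:
            raise ValueError("need >= 3 nodes per chain")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class MainAxisChain:
    nodes: np.ndarray  # (n, 3), ordered along the first principal component
    median_point: np.ndarray  # m, the middle node
    lateral_direction: np.ndarray  # n, unit second principal component


def _pca(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (centroid, components rows sorted by variance, singular values)."""
    centroid = points.mean(axis=0)
    _, svals, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt, svals


def fit_chain(points: np.ndarray, n_nodes: int, smoothness: float = 0.5,
              max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Fit an ordered chain of ``n_nodes`` through ``points`` (principal curve).

    Nodes are initialized at the centroids of equal-width bins of the
    projection onto the first principal component, then refined by
    alternating assignment (each point to the node nearest in projection
    coordinate, which keeps the chain ordered and prevents lateral
    zigzagging across wide blades) and averaging, with each node blended
    toward the midpoint of its chain neighbors (weight ``smoothness``).
    Iteration stops when the largest node movement drops below ``tol`` or
    after ``max_iter`` rounds.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < n_nodes:
        raise DegenerateCloudError(f"need >= {n_nodes} points, got {len(points)}")
    centroid, vt, svals = _pca(points)
    scale = float(svals[0]) / np.sqrt(len(points))
    if scale <= 0:
        raise DegenerateCloudError("cloud has zero extent")

    t = (points - centroid) @ vt[0]
    edges = np.linspace(t.min(), t.max() + 1e-12, n_nodes + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    bins = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_nodes - 1)
    nodes = np.empty((n_nodes, 3))
    for u in range(n_nodes):
        sel = bins == u
        nodes[u] = points[sel].mean(axis=0) if sel.any() else centroid + mids[u] * vt[0]

    for _ in range(max_iter):
        node_t = nodes @ vt[0]
        assign = np.abs(t[:, None] - (node_t - centroid @ vt[0])[None, :]).argmin(axis=1)
        targets = nodes.copy()
        for u in range(n_nodes):
            sel = assign == u
            if sel.any():
                targets[u] = points[sel].mean(axis=0)
        nb = targets.copy()
        nb[1:-1] = 0.5 * (targets[:-2] + targets[2:])
        new_nodes = (targets + smoothness * nb) / (1.0 + smoothness)
        move = np.abs(new_nodes - nodes).max()
        nodes = new_nodes
        if move < tol:
            break

    # enforce consistent ordering by projection onto the first PC
    order = np.argsort(nodes @ vt[0])
    return nodes[order]


def fit_main_axis(cloud: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()) -> MainAxisChain:
    """Fit the main-axis chain and the lateral direction of a leaf cloud."""
    cloud = np.asarray(cloud, dtype=float)
    if len(cloud) < max(3, cfg.n_main):
        raise DegenerateCloudError("too few points for main-axis fit")
    _, vt, svals = _pca(cloud)
    if svals[1] <= 1e-12 * max(svals[0], 1e-300):
        raise DegenerateCloudError("cloud is rank-deficient (collinear or degenerate)")
    nodes = fit_chain(cloud, cfg.n_main, cfg.chain_smoothness, cfg.max_iter, cfg.tol)
    m = nodes[len(nodes) // 2]
    return MainAxisChain(nodes=nodes, median_point=m, lateral_direction=vt[1])


def default_tau(cloud: np.ndarray) -> float:
    """10% of the cloud's first-principal-component extent."""
    _, vt, _ = _pca(np.asarray(cloud, dtype=float))
    t = cloud @ vt[0]
    return 0.10 * float(t.max() - t.min())


def slice_lateral_region(cloud: np.ndarray, chain: MainAxisChain, tau: float) -> np.ndarray:
    """Points within (closed) distance ``tau`` of the lateral line through m."""
    cloud = np.asarray(cloud, dtype=float)
    rel = cloud - chain.median_point
    along = rel @ chain.lateral_direction
    perp = rel - np.outer(along, chain.lateral_direction)
    dist = np.linalg.norm(perp, axis=1)
    sel = dist <= tau
    if not sel.any():
        raise EmptySliceError(f"no points within tau={tau} of the lateral line; increase tau")
    return cloud[sel]


def extract_skeleton(cloud: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()) -> LeafSkeleton:
    """Two-step skeleton extraction: main axis on the full cloud, lateral axis
    on the midsection slice."""
    cloud = np.asarray(cloud, dtype=float)
    chain = fit_main_axis(cloud, cfg)
    tau = cfg.tau if cfg.tau is not None else default_tau(cloud)
    region = slice_lateral_region(cloud, chain, tau)
    n_lat = min(cfg.n_lateral, max(3, len(region)))
    if len(region) < n_lat:
        raise EmptySliceError("midsection slice too sparse for lateral chain; increase tau")
    lateral = fit_chain(region, n_lat, cfg.chain_smoothness, cfg.max_iter, cfg.tol)

    points = np.vstack([chain.nodes, lateral])
    labels = np.concatenate(
        [np.full(len(chain.nodes), PART_MAIN), np.full(len(lateral), PART_LATERAL)]
    )
    return LeafSkeleton(points=points, part_labels=labels)
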
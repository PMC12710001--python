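"""Gaussian-mixture densification of leaf skeletons.

A skeleton is a sparse, curve-like point set; the generator needs a denser
cloud.  We fit a full-covariance Gaussian mixture to the skeleton points
(2 modes when a petiole is present — one is expected to capture the petiole
and one the blade — otherwise 1) and sample ``delta * N_skel`` extra points
from it.  The augmented cloud keeps the original skeleton points bit-exact
and carries a boolean mask identifying them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .skeleton import LeafSkeleton

__all__ = ["GMMModel", "AugmentedCloud", "fit_gmm", "gmm_density", "sample_gmm", "augment_skeleton"]


@dataclass
class GMMModel:
    """A fitted Gaussian mixture with J in {1, 2} full-covariance modes."""

    weights: np.ndarray  # (J,)
    means: np.ndarray  # (J, 3)
    covariances: np.ndarray  # (J, 3, 3)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive")

    @property
    def n_modes(self) -> int:
        return len(self.weights)


@dataclass
class AugmentedCloud:
    """Skeleton points plus GMM-sampled points, with a skeleton mask."""

    points: np.ndarray  # (N, 3)
    skeleton_mask: np.ndarray  # (N,) bool, True iff point came from the skeleton
    delta: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.skeleton_mask = np.asarray(self.skeleton_mask, dtype=bool)
        n_skel = int(self.skeleton_mask.sum())
        if len(self.points) != n_skel + self.delta * n_skel:
            raise ValueError("N must equal N_skel * (1 + delta)")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def skeleton_points(self) -> np.ndarray:
        return self.points[self.skeleton_mask]


def fit_gmm(points: np.ndarray, n_modes: int, rng: np.random.Generator) -> GMMModel:
    """Maximum-likelihood full-covariance mixture via EM.

    k-means initialization seeded from ``rng``; covariance floor 1e-8 on the
    eigenvalues, tolerance 1e-6, at most 200 iterations.
    """
    points = np.asarray(points, dtype=float)
    if n_modes not in (1, 2):
        raise ValueError("n_modes must be 1 or 2")
    if len(points) < 4 * n_modes:
        raise ValueError(f"need >= {4 * n_modes} points to fit {n_modes} modes")
    gm = GaussianMixture(
        n_components=n_modes,
        covariance_type="full",
        reg_covar=1e-8,
        tol=1e-6,
        max_iter=200,
        init_params="kmeans",
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(points)
    return GMMModel(weights=gm.weights_, means=gm.means_, covariances=gm.covariances_)


def gmm_density(model: GMMModel, point: np.ndarray) -> float:
    """Mixture probability density at ``point``."""
    point = np.asarray(point, dtype=float)
    dens = 0.0
    for w, mu, cov in zip(model.weights, model.means, model.covariances):
        dens += w * multivariate_normal.pdf(point, mean=mu, cov=cov, allow_singular=True)
    return float(dens)


def sample_gmm(model: GMMModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points: per-point component assignment by the mixture weights,
    then a draw from that component's Gaussian."""
    assign = rng.choice(model.n_modes, size=n, p=model.weights)
    out = np.empty((n, 3))
    for j in range(model.n_modes):
        sel = assign == j
        if sel.any():
            out[sel] = rng.multivariate_normal(
                model.means[j], model.covariances[j], size=int(sel.sum()),
                method="eigh",
            )
    return out


def augment_skeleton(
    skeleton: LeafSkeleton,
    delta: int = 9,
    rng: np.random.Generator | None = None,
    n_modes: int | None = None,
) -> AugmentedCloud:
    """Densify ``skeleton`` into the generator input cloud.

    ``n_modes`` defaults to 2 when the skeleton has a petiole part, else 1.
    ``delta`` scales the sampled point count: N = N_skel + delta * N_skel.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if n_modes is None:
        n_modes = 2 if skeleton.has_petiole else 1
    model = fit_gmm(skeleton.points, n_modes, rng)
    sampled = sample_gmm(model, delta * skeleton.n_points, rng)
    points = np.vstack([skeleton.points, sampled])
    mask = np.zeros(len(points), dtype=bool)
    mask[: skeleton.n_points] = True
    return AugmentedCloud(points=points, skeleton_mask=mask, delta=delta)
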
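"""Embedding-based distribution metrics and diversity measures.

All distribution metrics (CMMD, FID, improved precision/recall, realism)
operate on fixed-length embedding vectors, one per leaf.  The default
embedding is a deterministic geometric descriptor (moments + density
histograms in a PCA-canonical frame); the extractor is pluggable, so
externally computed embeddings (one vector per leaf) can be used instead.

Diversity between leaves generated from one skeleton is measured two ways:
the symmetric mean Chamfer distance, and a point-to-mesh distance comparing
reconstructed surfaces through the distances of random probe points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import linalg as sla
from scipy.spatial import Delaunay, cKDTree

from .losses import chamfer_distance

__all__ = [
    "EmbeddingSet",
    "PRResult",
    "DiversityReport",
    "EmbeddingConfig",
    "geometric_embedding",
    "embed_clouds",
    "cmmd",
    "fid",
    "coverage_indicator",
    "precision_recall",
    "pr_loss",
    "realism_scores",
    "mean_fscore",
    "realism_filtered_fscore",
    "reconstruct_mesh",
    "point_to_mesh_distance",
    "diversity_report",
    "DEFAULT_K_SET",
]

log = logging.getLogger(__name__)

DEFAULT_K_SET = (2, 4, 8, 16, 32, 48, 64, 96)


@dataclass
class EmbeddingSet:
    """A set of fixed-length descriptor vectors with provenance labels."""

    vectors: np.ndarray  # (n, d)
    source_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.size == 0:
            raise ValueError("embedding set must be non-empty")
        if self.source_ids is None:
            self.source_ids = [str(i) for i in range(len(self.vectors))]

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class PRResult:
    precision: float
    recall: float
    f_score: float
    k: int
    valid: bool = True
    retained_fraction: float = 1.0


@dataclass(frozen=True)
class DiversityReport:
    chamfer_mean: float
    chamfer_std: float
    p2m_mean: float
    p2m_std: float
    n_leaves: int
    n_trials: int


@dataclass(frozen=True)
class EmbeddingConfig:
    radial_bins: int = 16
    height_bins: int = 16


def _canonical_frame(points: np.ndarray) -> np.ndarray:
    """Center, PCA-align, sign-fix (third moment >= 0 per axis) and scale to
    unit RMS radius.  Rigid motions and uniform rescaling are factored out."""
    x = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    y = x @ vt.T
    if y.shape[1] < 3:  # pad degenerate dimensionality
        y = np.pad(y, ((0, 0), (0, 3 - y.shape[1])))
    for j in range(3):
        m3 = (y[:, j] ** 3).sum()
        if m3 < 0:
            y[:, j] = -y[:, j]
    rms = np.sqrt((y**2).sum(axis=1).mean())
    return y / max(rms, 1e-300)


def geometric_embedding(cloud: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Deterministic fixed-length shape descriptor of a point cloud.

    Concatenates (a) normalized central moments up to order 3 in the
    canonical PCA frame, (b) a radial point-density histogram, and (c) a
    height-profile histogram along the first principal axis.  Invariant to
    point permutation and to rigid motion modulo the canonical frame.
    """
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    if len(cloud) < 4:
        raise ValueError("need >= 4 points for an embedding")
    y = _canonical_frame(cloud)

    moments = []
    for order in (2, 3):
        for i in range(order + 1):
            for j in range(order - i + 1):
                k = order - i - j
                moments.append((y[:, 0] ** i * y[:, 1] ** j * y[:, 2] ** k).mean())

    r = np.linalg.norm(y, axis=1)
    radial, _ = np.histogram(r, bins=cfg.radial_bins, range=(0.0, 2.0), density=False)
    height, _ = np.histogram(y[:, 0], bins=cfg.height_bins, range=(-2.5, 2.5), density=False)
    n = len(cloud)
    return np.concatenate([np.asarray(moments), radial / n, height / n])


def embed_clouds(clouds: list[np.ndarray], cfg: EmbeddingConfig = EmbeddingConfig(),
                 ids: list[str] | None = None) -> EmbeddingSet:
    vecs = np.stack([geometric_embedding(c, cfg) for c in clouds])
    return EmbeddingSet(vectors=vecs, source_ids=ids)


def _check_dims(a: EmbeddingSet, b: EmbeddingSet) -> None:
    if a.dim != b.dim:
        raise ValueError(f"embedding dimension mismatch: {a.dim} vs {b.dim}")


def cmmd(real: EmbeddingSet, generated: EmbeddingSet, kernel: str = "linear") -> float:
    """Unbiased squared maximum mean discrepancy between embedding sets.

    Within-set kernel terms are averaged over ordered pairs i != j, the cross
    term over all pairs.  ``linear`` uses the inner product; ``rbf`` a
    Gaussian kernel with the median-heuristic bandwidth over the pooled sets.
    """
    _check_dims(real, generated)
    x, y = real.vectors, generated.vectors
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("need >= 2 vectors per set for the unbiased estimator")

    if kernel == "linear":
        kxx, kyy, kxy = x @ x.T, y @ y.T, x @ y.T
    elif kernel == "rbf":
        pooled = np.vstack([x, y])
        d2 = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(-1)
        med = np.median(d2[np.triu_indices_from(d2, k=1)])
        gamma = 1.0 / max(med, 1e-300)
        kxx = np.exp(-gamma * ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        kyy = np.exp(-gamma * ((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        kxy = np.exp(-gamma * ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    term_x = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    term_y = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    term_xy = kxy.sum() / (n * m)
    return float(term_x + term_y - 2.0 * term_xy)


def _mean_cov(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, d = vectors.shape
    mu = vectors.mean(axis=0)
    if n >= d + 1:
        cov = np.cov(vectors, rowvar=False)
    else:
        # shrinkage (Ledoit-Wolf style diagonal loading) for small sets
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf().fit(vectors).covariance_
    return mu, np.atleast_2d(cov)


def fid(real: EmbeddingSet, generated: EmbeddingSet) -> float:
    """Frechet distance between Gaussians fitted to the two embedding sets."""
    _check_dims(real, generated)
    mu_r, cov_r = _mean_cov(real.vectors)
    mu_f, cov_f = _mean_cov(generated.vectors)
    if not (np.all(np.isfinite(cov_r)) and np.all(np.isfinite(cov_f))):
        raise ValueError("non-finite covariance in FID")
    res = sla.sqrtm(cov_r @ cov_f)
    sqrt_prod = np.real(res[0] if isinstance(res, tuple) else res)
    val = float(((mu_r - mu_f) ** 2).sum() + np.trace(cov_r + cov_f - 2.0 * sqrt_prod))
    return max(val, 0.0)


def _knn_radii_sq(phi: np.ndarray, k: int) -> np.ndarray:
    """Squared distance from each vector in ``phi`` to its k-th NN in ``phi``."""
    if len(phi) <= k:
        raise ValueError(f"need more than k={k} vectors in the manifold set")
    d, _ = cKDTree(phi).query(phi, k=k + 1)
    return np.atleast_2d(d)[:, k] ** 2


def coverage_indicator(v: np.ndarray, phi: EmbeddingSet, k: int) -> int:
    """1 iff ``v`` lies inside some member's k-NN hypersphere (strict)."""
    radii = _knn_radii_sq(phi.vectors, k)
    d2 = ((phi.vectors - np.asarray(v, dtype=float)) ** 2).sum(axis=1)
    return int(np.any(d2 < radii))


def precision_recall(real: EmbeddingSet, generated: EmbeddingSet, k: int) -> PRResult:
    """Improved precision and recall via k-NN manifold coverage."""
    _check_dims(real, generated)
    radii_r = _knn_radii_sq(real.vectors, k)
    radii_f = _knn_radii_sq(generated.vectors, k)

    def covered(queries: np.ndarray, members: np.ndarray, radii: np.ndarray) -> np.ndarray:
        d2 = ((queries[:, None, :] - members[None, :, :]) ** 2).sum(-1)
        return (d2 < radii[None, :]).any(axis=1)

    precision = float(covered(generated.vectors, real.vectors, radii_r).mean())
    recall = float(covered(real.vectors, generated.vectors, radii_f).mean())
    if precision + recall > 0:
        f_score = 2.0 * precision * recall / (precision + recall)
    else:
        f_score = 0.0
    return PRResult(precision=precision, recall=recall, f_score=f_score, k=k)


def pr_loss(pr: PRResult, epsilon: float = 1e-8) -> float:
    """log10(1/(Pr+eps)) + log10(1/(R+eps)); minimized at Pr = R = 1."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return float(-np.log10(pr.precision + epsilon) - np.log10(pr.recall + epsilon))


def realism_scores(generated: EmbeddingSet, real: EmbeddingSet, k: int) -> np.ndarray:
    """Per-generated-vector realism: max over real vectors of the ratio of the
    real vector's k-NN radius to its distance from the generated vector.
    A generated vector coinciding with a real one scores +inf."""
    _check_dims(generated, real)
    radii = np.sqrt(_knn_radii_sq(real.vectors, k))
    scores = np.empty(len(generated.vectors))
    for i, v in enumerate(generated.vectors):
        dist = np.linalg.norm(real.vectors - v, axis=1)
        with np.errstate(divide="ignore"):
            scores[i] = np.max(np.where(dist > 0, radii / np.where(dist > 0, dist, 1.0), np.inf))
    return scores


def mean_fscore(real: EmbeddingSet, generated: EmbeddingSet,
                k_set: tuple[int, ...] = DEFAULT_K_SET) -> float:
    """Mean F-score across neighborhood sizes; infeasible k are skipped."""
    limit = min(len(real), len(generated))
    scores = []
    for k in k_set:
        if k >= limit:
            log.warning("mean_fscore: skipping infeasible k=%d (sets of size %d)", k, limit)
            continue
        scores.append(precision_recall(real, generated, k).f_score)
    if not scores:
        raise ValueError("no feasible k in k_set")
    return float(np.mean(scores))


def realism_filtered_fscore(real: EmbeddingSet, generated: EmbeddingSet, k: int,
                            min_realism: float) -> tuple[PRResult, float]:
    """Precision/recall after dropping generated vectors with low realism.

    Returns the PR result on the retained subset and the retained fraction.
    The result is flagged invalid when half or fewer of the generated vectors
    survive the filter (reported as '-' in tabulations).
    """
    scores = realism_scores(generated, real, k)
    keep = scores >= min_realism
    frac = float(keep.mean())
    if keep.sum() <= k:  # PR needs > k vectors
        return PRResult(0.0, 0.0, 0.0, k, valid=False, retained_fraction=frac), frac
    kept = EmbeddingSet(vectors=generated.vectors[keep])
    pr = precision_recall(real, kept, k)
    valid = frac > 0.5
    return PRResult(pr.precision, pr.recall, pr.f_score, k, valid=valid,
                    retained_fraction=frac), frac


# ---------------------------------------------------------------------------
# Surface reconstruction and point-to-mesh diversity
# ---------------------------------------------------------------------------


def reconstruct_mesh(points: np.ndarray, edge_factor: float = 4.0) -> trimesh.Trimesh:
    """Triangulate a (nearly developable) leaf surface.

    Projects the cloud on its PCA plane, Delaunay-triangulates there, and
    prunes triangles whose longest 3D edge exceeds ``edge_factor`` times the
    median nearest-neighbor spacing — an alpha-shape-like filter that keeps
    the open leaf boundary intact.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("need >= 4 points to mesh")
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    plane = centered @ vt[:2].T
    tri = Delaunay(plane)
    faces = tri.simplices
    d_nn, _ = cKDTree(points).query(points, k=2)
    med = np.median(np.atleast_2d(d_nn)[:, 1])
    e = points[faces]
    edge_len = np.stack([
        np.linalg.norm(e[:, 0] - e[:, 1], axis=1),
        np.linalg.norm(e[:, 1] - e[:, 2], axis=1),
        np.linalg.norm(e[:, 0] - e[:, 2], axis=1),
    ]).max(axis=0)
    faces = faces[edge_len <= edge_factor * med]
    if len(faces) == 0:
        faces = tri.simplices  # degenerate spacing; keep full triangulation
    return trimesh.Trimesh(vertices=points, faces=faces, process=False)


def _point_triangle_distances(probes: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Exact distance from each probe to the nearest mesh triangle."""
    tri = mesh.triangles  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    out = np.empty(len(probes))
    for i, p in enumerate(probes):
        out[i] = np.sqrt(_point_tri_d2(p, a, b, c).min())
    return out


def _point_tri_d2(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Squared distances from point ``p`` to each triangle (abc) (vectorized
    region-based closest-point construction)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    closest = np.empty_like(a)
    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    m2 = (d3 >= 0) & (d4 <= d3) & ~m
    closest[m2] = b[m2]
    done = m | m2
    m3 = (d6 >= 0) & (d5 <= d6) & ~done
    closest[m3] = c[m3]
    done |= m3
    # edge AB
    m4 = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    t = np.where(m4, d1 / np.where((d1 - d3) != 0, d1 - d3, 1.0), 0.0)
    closest[m4] = a[m4] + t[m4, None] * ab[m4]
    done |= m4
    # edge AC
    m5 = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    t = np.where(m5, d2 / np.where((d2 - d6) != 0, d2 - d6, 1.0), 0.0)
    closest[m5] = a[m5] + t[m5, None] * ac[m5]
    done |= m5
    # edge BC
    m6 = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0) & ~done
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(m6, (d4 - d3) / np.where(denom != 0, denom, 1.0), 0.0)
    closest[m6] = b[m6] + t[m6, None] * (c[m6] - b[m6])
    done |= m6
    # interior
    mi = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    closest[mi] = a[mi] + v[mi, None] * ab[mi] + w[mi, None] * ac[mi]

    return ((p - closest) ** 2).sum(1)


def point_to_mesh_distance(leaf_a: np.ndarray, leaf_b: np.ndarray, n_probe: int = 256,
                           rng: np.random.Generator | None = None) -> float:
    """Surface dissimilarity: mean over random probe points of the absolute
    difference of their distances to the two reconstructed leaf meshes."""
    rng = np.random.default_rng() if rng is None else rng
    leaf_a = np.asarray(leaf_a, dtype=float)
    leaf_b = np.asarray(leaf_b, dtype=float)
    try:
        mesh_a = reconstruct_mesh(leaf_a)
        mesh_b = reconstruct_mesh(leaf_b)
    except Exception as exc:  # meshing failure: fall back to point-set distance
        log.warning("meshing failed (%s); falling back to chamfer distance", exc)
        return chamfer_distance(leaf_a, leaf_b, squared=False, reduction="mean")
    lo = np.minimum(leaf_a.min(axis=0), leaf_b.min(axis=0))
    hi = np.maximum(leaf_a.max(axis=0), leaf_b.max(axis=0))
    pad = 0.1 * (hi - lo)
    probes = rng.uniform(lo - pad, hi + pad, size=(n_probe, 3))
    da = _point_triangle_distances(probes, mesh_a)
    db = _point_triangle_distances(probes, mesh_b)
    return float(np.abs(da - db).mean())


def diversity_report(leaves: list[np.ndarray], n_trials: int = 10,
                     rng: np.random.Generator | None = None,
                     n_probe: int = 256) -> DiversityReport:
    """Pairwise diversity of leaves generated from one skeleton.

    Chamfer values are unsquared symmetric mean nearest-neighbor distances;
    point-to-mesh values are averaged over ``n_trials`` probe redraws.
    """
    if len(leaves) < 2:
        raise ValueError("need >= 2 leaves")
    rng = np.random.default_rng() if rng is None else rng
    cham, p2m = [], []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            cham.append(chamfer_distance(leaves[i], leaves[j], squared=False, reduction="mean"))
            vals = [point_to_mesh_distance(leaves[i], leaves[j], n_probe, rng)
                    for _ in range(n_trials)]
            p2m.append(float(np.mean(vals)))
    return DiversityReport(
        chamfer_mean=float(np.mean(cham)),
        chamfer_std=float(np.std(cham)),
        p2m_mean=float(np.mean(p2m)),
        p2m_std=float(np.std(p2m)),
        n_leaves=len(leaves),
        n_trials=n_trials,
    )
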
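"""Pseudo-real leaf corpora with exactly known traits.

Stands in for field-acquired single-leaf point clouds: a full leaf surface is
built by sweeping the lateral parabola along the main axis with a smooth
width envelope (zero at tip and base, maximal at the crossing abscissa), so
the analytic skeleton curves are exactly embedded in the surface and the
trait labels are exact by construction.  Sensor imperfections are emulated
by Gaussian surface noise, random dropout, and one contiguous occlusion
patch.  Corpora carry per-leaf labels plus a patch id (round-robin), so the
same corpus supports both per-leaf and patch-averaged label experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import (
    LeafTraits,
    SkeletonParams,
    SpeciesProfile,
    compute_traits,
    lateral_parabola_coefficients,
    sample_skeleton_params,
)

__all__ = ["NoiseConfig", "LeafRecord", "generate_pseudo_real_leaf", "generate_corpus",
           "surface_point", "patch_labels"]


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor-imperfection model for pseudo-real leaves.

    ``gaussian_sigma`` is isotropic point noise as a fraction of the blade
    length; ``dropout_fraction`` removes points independently;
    ``occlusion_fraction`` removes one contiguous patch of roughly that
    fraction of the points.  ``points_per_leaf`` is the pre-dropout target.
    """

    gaussian_sigma: float = 0.002
    dropout_fraction: float = 0.0
    occlusion_fraction: float = 0.0
    points_per_leaf: int = 600

    def __post_init__(self) -> None:
        for f in (self.dropout_fraction, self.occlusion_fraction):
            if not (0 <= f < 1):
                raise ValueError("fractions must be in [0, 1)")
        if self.gaussian_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.points_per_leaf < 50:
            raise ValueError("points_per_leaf must be >= 50")


def _envelope(u: np.ndarray, x_cross: float) -> np.ndarray:
    """Smooth half-width profile along the main axis: 0 at base (u=0) and tip
    (u=1), 1 at the crossing abscissa.  The cube-root plateau keeps the blade
    near its maximal width over most of its length, as real leaves are,
    rather than tapering immediately away from the widest section."""
    u = np.asarray(u, dtype=float)
    rising = np.sin(0.5 * np.pi * np.clip(u / x_cross, 0, 1))
    falling = np.sin(0.5 * np.pi * np.clip((1 - u) / (1 - x_cross), 0, 1))
    return np.where(u < x_cross, rising, falling) ** (1.0 / 3.0)


def surface_point(params: SkeletonParams, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unscaled blade surface at sweep parameter u in [0,1], lateral v in [-1,1].

    The v = 0 profile is the main axis; at u = x_cross the v-profile is the
    lateral parabola, guaranteeing both skeleton curves lie on the surface.
    """
    a, b, _ = lateral_parabola_coefficients(params)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    env = _envelope(u, params.x_cross)
    y = 0.5 * v * env
    rel = a * y**2 + b * y  # parabola z-profile relative to its midpoint
    z = np.tanh(u) + env * rel
    return np.column_stack([u, y, z])


def _sample_surface(params: SkeletonParams, n: int, rng: np.random.Generator,
                    return_uv: bool = False):
    """Approximately area-uniform samples of the scaled blade surface."""
    # importance sample (u, v) on a grid weighted by the local area element
    gu = np.linspace(0.0, 1.0, 96)
    gv = np.linspace(-1.0, 1.0, 32)
    uu, vv = np.meshgrid(gu, gv, indexing="ij")
    eps = 1e-4
    base = surface_point(params, uu.ravel(), vv.ravel())
    du = surface_point(params, np.clip(uu.ravel() + eps, 0, 1), vv.ravel()) - base
    dv = surface_point(params, uu.ravel(), np.clip(vv.ravel() + eps, -1, 1)) - base
    # scale to model units before measuring area
    for arr in (base, du, dv):
        arr[:, 0] *= params.s_l
        arr[:, 1] *= params.s_w
    area = np.linalg.norm(np.cross(du, dv), axis=1)
    w = area / area.sum()
    cells = rng.choice(len(w), size=n, p=w)
    cu = gu[1] - gu[0]
    cv = gv[1] - gv[0]
    u = np.clip(uu.ravel()[cells] + rng.uniform(0, cu, n), 0, 1)
    v = np.clip(vv.ravel()[cells] + rng.uniform(0, cv, n), -1, 1)
    pts = surface_point(params, u, v)
    pts[:, 0] *= params.s_l
    pts[:, 1] *= params.s_w
    if return_uv:
        return pts, np.column_stack([u, v])
    return pts


def _petiole_points(params: SkeletonParams, n: int, rng: np.random.Generator) -> np.ndarray:
    # points exactly on the scaled petiole line; any thickness comes from the
    # global Gaussian noise term so that noise-free clouds are exactly analytic
    x = rng.uniform(params.x_min, 0.0, n)
    return np.column_stack([x * params.s_l, np.zeros(n), params.alpha * x])


def generate_pseudo_real_leaf(
    params: SkeletonParams,
    noise: NoiseConfig = NoiseConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, LeafTraits]:
    """One pseudo-real leaf cloud with its exact trait labels."""
    rng = np.random.default_rng() if rng is None else rng
    traits = compute_traits(params)
    n = noise.points_per_leaf
    if params.include_petiole:
        n_pet = max(10, n // 10)
        n_blade = n - n_pet
    else:
        n_pet, n_blade = 0, n
    pts = _sample_surface(params, n_blade, rng)
    if n_pet:
        pts = np.vstack([pts, _petiole_points(params, n_pet, rng)])
    if noise.gaussian_sigma > 0:
        pts = pts + rng.normal(0.0, noise.gaussian_sigma * traits.blade_length, pts.shape)
    if noise.occlusion_fraction > 0:
        center = pts[rng.integers(len(pts))]
        d = np.linalg.norm(pts - center, axis=1)
        cut = np.quantile(d, noise.occlusion_fraction)
        pts = pts[d > cut]
    if noise.dropout_fraction > 0:
        keep = rng.random(len(pts)) >= noise.dropout_fraction
        if keep.sum() >= 50:
            pts = pts[keep]
    return pts, traits


@dataclass
class LeafRecord:
    leaf_id: int
    seed: int
    species: str
    params: SkeletonParams
    traits: LeafTraits
    patch_id: int
    cloud: np.ndarray


def generate_corpus(
    n: int,
    profile: SpeciesProfile,
    noise: NoiseConfig = NoiseConfig(),
    patches: int = 1,
    seed: int = 0,
) -> tuple[list[LeafRecord], pd.DataFrame]:
    """Generate ``n`` labeled pseudo-real leaves with round-robin patch ids.

    Returns the leaf records and a manifest with params, traits and seeds;
    identical seeds reproduce identical corpora and manifests.
    """
    if n < 1 or patches < 1:
        raise ValueError("n and patches must be >= 1")
    master = np.random.default_rng(seed)
    records: list[LeafRecord] = []
    rows = []
    for i in range(n):
        leaf_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(leaf_seed)
        params = sample_skeleton_params(profile, rng)
        cloud, traits = generate_pseudo_real_leaf(params, noise, rng)
        patch = i % patches
        records.append(LeafRecord(i, leaf_seed, profile.name, params, traits, patch, cloud))
        rows.append({
            "leaf_id": i, "seed": leaf_seed, "species": profile.name, "patch_id": patch,
            "s_l": params.s_l, "s_w": params.s_w, "alpha": params.alpha,
            "x_min": params.x_min, "x_cross": params.x_cross,
            "z_r": params.z_r, "z_l": params.z_l,
            "blade_length": traits.blade_length, "total_length": traits.total_length,
            "blade_width": traits.blade_width,
        })
    return records, pd.DataFrame(rows)


def patch_labels(manifest: pd.DataFrame) -> pd.DataFrame:
    """Replace per-leaf trait labels by their patch means (the label
    granularity of field datasets that only report per-patch aggregates)."""
    out = manifest.copy()
    for trait in ("blade_length", "total_length", "blade_width"):
        out[trait] = out.groupby("patch_id")[trait].transform("mean")
    return out
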
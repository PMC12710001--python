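"""Parametric leaf skeletons with exactly known traits.

A leaf skeleton is an ordered, part-labeled 3D polyline set with up to three
parts: the petiole (a straight stalk), the main axis running tip-to-base along
the blade length, and the lateral axis crossing it along the blade width.
Skeletons are built from a handful of random shape parameters:

* petiole: the line ``z = alpha * x`` on ``x in [x_min, 0]``, ``y = 0``;
* main axis: ``z = tanh(x)`` on ``x in [0, 1]``, ``y = 0``;
* lateral axis: the parabola ``z = a y^2 + b y + c`` through the crossing
  point ``(x_cross, 0, tanh(x_cross))`` and the two lateral extremes at
  ``y = +-0.5`` with independently drawn elevation offsets ``z_r``, ``z_l``.

The skeleton is then anisotropically scaled: every x coordinate is multiplied
by the length scale ``s_l`` and every y coordinate by the width scale ``s_w``
(z is left untouched).  Because the generating curves are known analytically,
the blade length, total length, and blade width of every simulated leaf are
exact arc lengths rather than measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate

__all__ = [
    "PART_PETIOLE",
    "PART_MAIN",
    "PART_LATERAL",
    "PART_NAMES",
    "SpeciesProfile",
    "SkeletonParams",
    "LeafSkeleton",
    "LeafTraits",
    "Resolution",
    "TraitQuadratureError",
    "SUGAR_BEET",
    "MAIZE",
    "TOMATO",
    "BUILTIN_PROFILES",
    "sample_skeleton_params",
    "build_skeleton",
    "compute_traits",
    "polyline_arc_length",
    "lateral_parabola_coefficients",
]

PART_PETIOLE = 0
PART_MAIN = 1
PART_LATERAL = 2
PART_NAMES = {PART_PETIOLE: "petiole", PART_MAIN: "main_axis", PART_LATERAL: "lateral_axis"}


class TraitQuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to converge for a trait integral."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Sampling rules for one crop species.

    ``width_scale_rule`` maps a drawn length scale ``s_l`` to the interval the
    width scale ``s_w`` is drawn from (uniformly).  ``gmm_modes`` is the number
    of Gaussian-mixture components used when densifying skeletons of this
    species: 2 when a petiole is present (one mode per structure), else 1.
    """

    name: str
    length_scale_range: tuple[float, float]
    width_scale_rule: Callable[[float], tuple[float, float]]
    has_petiole: bool

    def __post_init__(self) -> None:
        lo, hi = self.length_scale_range
        if not (0 < lo < hi):
            raise ValueError("length_scale_range must be positive and ordered")
        wlo, whi = self.width_scale_rule(lo)
        if not (0 < wlo < whi):
            raise ValueError("width_scale_rule must yield a positive ordered interval")

    @property
    def gmm_modes(self) -> int:
        return 2 if self.has_petiole else 1


SUGAR_BEET = SpeciesProfile(
    name="sugarbeet",
    length_scale_range=(0.02, 0.50),
    width_scale_rule=lambda sl: (sl / 4.0, sl),
    has_petiole=True,
)
MAIZE = SpeciesProfile(
    name="maize",
    length_scale_range=(0.15, 0.90),
    width_scale_rule=lambda sl: (sl / 10.0, sl / 5.0),
    has_petiole=False,
)
TOMATO = SpeciesProfile(
    name="tomato",
    length_scale_range=(0.10, 0.50),
    width_scale_rule=lambda sl: (sl / 2.0, sl),
    has_petiole=True,
)
BUILTIN_PROFILES = {p.name: p for p in (SUGAR_BEET, MAIZE, TOMATO)}


@dataclass(frozen=True)
class SkeletonParams:
    """Shape parameters of one simulated skeleton (unscaled frame + scales)."""

    alpha: float
    x_min: float
    x_cross: float
    z_r: float
    z_l: float
    s_l: float
    s_w: float
    include_petiole: bool

    def __post_init__(self) -> None:
        if not (np.pi / 6 - 1e-12 <= self.alpha <= np.pi / 3 + 1e-12):
            raise ValueError("alpha outside [pi/6, pi/3]")
        if not (-1 <= self.x_min <= -0.25):
            raise ValueError("x_min outside [-1, -0.25]")
        if not (0.25 <= self.x_cross <= 0.75):
            raise ValueError("x_cross outside [0.25, 0.75]")
        for z in (self.z_r, self.z_l):
            if not (-0.25 <= z <= 0.25):
                raise ValueError("z_r/z_l outside [-0.25, 0.25]")
        if self.z_r == self.z_l:
            raise ValueError("z_r and z_l must be distinct")
        if self.s_l <= 0 or self.s_w <= 0:
            raise ValueError("scale factors must be positive")


@dataclass(frozen=True)
class LeafTraits:
    """Ground-truth scalar traits (model units, i.e. meters)."""

    blade_length: float
    total_length: float
    blade_width: float

    def __post_init__(self) -> None:
        if min(self.blade_length, self.total_length, self.blade_width) <= 0:
            raise ValueError("traits must be positive")
        if self.total_length < self.blade_length - 1e-12:
            raise ValueError("total_length must be >= blade_length")

    def as_array(self) -> np.ndarray:
        return np.array([self.blade_length, self.total_length, self.blade_width])


@dataclass
class LeafSkeleton:
    """Ordered, part-labeled 3D polyline set."""

    points: np.ndarray  # (M, 3) float64
    part_labels: np.ndarray  # (M,) int, values in PART_NAMES
    part_order: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.part_labels = np.asarray(self.part_labels, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (M, 3)")
        if len(self.part_labels) != len(self.points):
            raise ValueError("one label per point required")
        if not self.part_order:
            self.part_order = {
                p: np.flatnonzero(self.part_labels == p)
                for p in np.unique(self.part_labels)
            }

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def has_petiole(self) -> bool:
        return bool(np.any(self.part_labels == PART_PETIOLE))

    def part_points(self, part: int) -> np.ndarray:
        return self.points[self.part_order[part]]


@dataclass(frozen=True)
class Resolution:
    """Points per skeleton part."""

    petiole: int = 20
    main: int = 50
    lateral: int = 30

    def __post_init__(self) -> None:
        if min(self.petiole, self.main, self.lateral) < 2:
            raise ValueError("need >= 2 points per part")


def sample_skeleton_params(profile: SpeciesProfile, rng: np.random.Generator) -> SkeletonParams:
    """Draw random skeleton parameters for one leaf of ``profile``.

    All parameters are uniform over their documented ranges; the two lateral
    elevations are redrawn until distinct, and ``s_w`` is drawn from the
    species' width rule evaluated at the drawn ``s_l``.
    """
    alpha = rng.uniform(np.pi / 6, np.pi / 3)
    x_min = rng.uniform(-1.0, -0.25)
    x_cross = rng.uniform(0.25, 0.75)
    z_r = rng.uniform(-0.25, 0.25)
    z_l = rng.uniform(-0.25, 0.25)
    while z_l == z_r:  # pragma: no cover - measure-zero event
        z_l = rng.uniform(-0.25, 0.25)
    s_l = rng.uniform(*profile.length_scale_range)
    s_w = rng.uniform(*profile.width_scale_rule(s_l))
    return SkeletonParams(
        alpha=alpha,
        x_min=x_min,
        x_cross=x_cross,
        z_r=z_r,
        z_l=z_l,
        s_l=s_l,
        s_w=s_w,
        include_petiole=profile.has_petiole,
    )


def lateral_parabola_coefficients(params: SkeletonParams) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the unscaled lateral parabola z(y).

    Solved from the three defining points (y, z) = (0, z_cross),
    (0.5, z_cross + z_r), (-0.5, z_cross + z_l).  Collinear points give a = 0.
    """
    z_cross = float(np.tanh(params.x_cross))
    c = z_cross
    # z(0.5) = 0.25 a + 0.5 b + c ; z(-0.5) = 0.25 a - 0.5 b + c
    a = 2.0 * (params.z_r + params.z_l)
    b = params.z_r - params.z_l
    return a, b, c


def build_skeleton(params: SkeletonParams, resolution: Resolution = Resolution()) -> LeafSkeleton:
    """Sample the three skeleton curves and apply the anisotropic scaling."""
    pts: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    if params.include_petiole:
        x = np.linspace(params.x_min, 0.0, resolution.petiole)
        pet = np.column_stack([x, np.zeros_like(x), params.alpha * x])
        pts.append(pet)
        labels.append(np.full(resolution.petiole, PART_PETIOLE))

    x = np.linspace(0.0, 1.0, resolution.main)
    main = np.column_stack([x, np.zeros_like(x), np.tanh(x)])
    pts.append(main)
    labels.append(np.full(resolution.main, PART_MAIN))

    a, b, c = lateral_parabola_coefficients(params)
    y = np.linspace(-0.5, 0.5, resolution.lateral)
    lat = np.column_stack([np.full_like(y, params.x_cross), y, a * y**2 + b * y + c])
    pts.append(lat)
    labels.append(np.full(resolution.lateral, PART_LATERAL))

    points = np.vstack(pts)
    points[:, 0] *= params.s_l
    points[:, 1] *= params.s_w
    return LeafSkeleton(points=points, part_labels=np.concatenate(labels))


def _quad(f, lo: float, hi: float) -> float:
    val, err = integrate.quad(f, lo, hi, limit=200, epsabs=1e-12, epsrel=1e-10)
    if not np.isfinite(val) or err > max(1e-8, 1e-6 * abs(val)):
        raise TraitQuadratureError(
            f"arc-length quadrature did not converge on [{lo}, {hi}]: value={val}, err={err}"
        )
    return float(val)


def compute_traits(params: SkeletonParams, mode: str = "true_arc_length") -> LeafTraits:
    """Exact traits of the scaled skeleton defined by ``params``.

    ``true_arc_length`` (default) integrates the standard planar arc-length
    element ``sqrt(1 + z'^2)`` along the scaled curves: the blade length is
    the arc length of ``z = tanh(x'/s_l)`` over ``x' in [0, s_l]``, the blade
    width the arc length of the scaled lateral parabola over its actual
    scaled y-extent ``[-s_w/2, s_w/2]``, and the total length adds the scaled
    petiole segment.  ``paper_literal`` instead evaluates the trait integrals
    with the ``1 +`` term left out of the root and the printed integration
    limits (width over ``[-s_w, s_w]`` of ``|2 a y + b|``; length as
    ``alpha * |x_min * s_l| + tanh(s_l)``), which reduces the width to the
    parabola's vertical variation; it is provided for cross-checking only.
    """
    a, b, _ = lateral_parabola_coefficients(params)
    s_l, s_w = params.s_l, params.s_w

    if mode == "true_arc_length":
        # scaled main axis: z(x') = tanh(x'/s_l), x' in [0, s_l]
        blade_length = _quad(
            lambda x: np.sqrt(1.0 + ((1.0 - np.tanh(x / s_l) ** 2) / s_l) ** 2), 0.0, s_l
        )
        # scaled lateral: z(y') = a (y'/s_w)^2 + b (y'/s_w) + c, y' in [-s_w/2, s_w/2]
        blade_width = _quad(
            lambda y: np.sqrt(1.0 + ((2.0 * a * y / s_w + b) / s_w) ** 2),
            -0.5 * s_w,
            0.5 * s_w,
        )
        if params.include_petiole:
            # scaled petiole is the segment from (s_l*x_min, 0, alpha*x_min) to origin
            petiole = abs(params.x_min) * float(np.hypot(s_l, params.alpha))
        else:
            petiole = 0.0
    elif mode == "paper_literal":
        blade_length = float(np.tanh(s_l))
        blade_width = _quad(lambda y: abs(2.0 * a * y + b), -s_w, s_w)
        petiole = params.alpha * abs(params.x_min) * s_l if params.include_petiole else 0.0
    else:
        raise ValueError(f"unknown trait mode {mode!r}")

    return LeafTraits(
        blade_length=blade_length,
        total_length=blade_length + petiole,
        blade_width=blade_width,
    )


def polyline_arc_length(points: np.ndarray) -> float:
    """Sum of Euclidean segment lengths of an ordered point sequence."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need at least 2 ordered points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())
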
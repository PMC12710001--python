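"""Offset-predicting leaf generator: training and conditioned generation.

The generative function g maps desired traits — realized as a parametric
skeleton scaled by (s_l, s_w) — to a leaf point cloud.  Training pairs an
augmented cloud P (skeleton + GMM samples) with the real leaf cloud its
skeleton was extracted from; the network predicts per-point offsets o and
the output is P_hat = P + o.  The objective combines four per-leaf
reconstruction terms (skeleton anchoring, bidirectional Chamfer, edge
regularity, Laplacian smoothness) with batch-level distribution terms
(CMMD, FID, precision-recall loss) computed on leaf embeddings against the
precomputed embeddings of the real training set.

The default embedding is the deterministic geometric descriptor, which is
not differentiable; the distribution terms are therefore evaluated each
epoch as weighted monitors folded into the reported total loss, while the
parameter gradients come from the reconstruction terms.  Setting the
distribution weight to zero reproduces the reconstruction-only ablation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from . import metrics as M
from .augmentation import AugmentedCloud, augment_skeleton
from .network import Adam, NetworkConfig, OffsetNetwork
from .skeleton import (
    LeafSkeleton,
    LeafTraits,
    Resolution,
    SkeletonParams,
    SpeciesProfile,
    build_skeleton,
    compute_traits,
    sample_skeleton_params,
)

__all__ = [
    "GeneratorConfig",
    "GeneratedLeaf",
    "TrainingHistory",
    "init_model",
    "train",
    "generate_leaf",
    "generate_dataset",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Training and architecture knobs of the offset generator."""

    hidden_width: int = 32
    n_layers: int = 3
    neighborhood_k: int = 8
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 4
    seed: int = 0
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)
    distribution_batch: int = 16
    knn_k: int = 8  # k for the edge/smoothness graph on the output cloud
    pr_k: int = 3  # neighborhood size of the PR monitor during training

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def network(self) -> NetworkConfig:
        return NetworkConfig(self.hidden_width, self.n_layers, self.neighborhood_k)


@dataclass
class GeneratedLeaf:
    """Output cloud with its conditioning traits and provenance."""

    points: np.ndarray  # (N, 3) = input points + offsets
    offsets: np.ndarray  # (N, 3)
    conditioning_traits: LeafTraits
    source_skeleton: LeafSkeleton
    skeleton_mask: np.ndarray
    params: SkeletonParams | None = None

    @property
    def skeleton_points_out(self) -> np.ndarray:
        """Skeleton points after displacement by the predicted offsets."""
        return self.points[self.skeleton_mask]

    @property
    def skeleton_displacement(self) -> np.ndarray:
        return np.linalg.norm(self.offsets[self.skeleton_mask], axis=1)


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    terms: dict[str, list[float]] = field(default_factory=dict)
    total: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)

    def record(self, epoch: int, terms: dict[str, float], total: float, dt: float) -> None:
        self.epochs.append(epoch)
        for name, value in terms.items():
            self.terms.setdefault(name, []).append(value)
        self.total.append(total)
        self.wall_time.append(dt)

    def to_frame(self) -> pd.DataFrame:
        data = {"epoch": self.epochs, "total": self.total, "wall_time": self.wall_time}
        data.update(self.terms)
        return pd.DataFrame(data)


def build_training_pairs(
    clouds: list[np.ndarray],
    gmm_modes: int,
    rng: np.random.Generator,
    delta: int = 9,
    extraction_cfg=None,
) -> list[tuple[AugmentedCloud, np.ndarray]]:
    """Standard supervision pipeline: extract a skeleton from each real (or
    pseudo-real) cloud, densify it with the species' GMM mode count, and pair
    it with the cloud it came from."""
    from .extraction import ExtractionConfig, extract_skeleton

    cfg = extraction_cfg or ExtractionConfig()
    pairs = []
    for cloud in clouds:
        skeleton = extract_skeleton(cloud, cfg)
        aug = augment_skeleton(skeleton, delta=delta, rng=rng, n_modes=gmm_modes)
        pairs.append((aug, np.asarray(cloud, dtype=float)))
    return pairs


def init_model(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> OffsetNetwork:
    """Deterministically initialized offset network (zero head: identity map)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return OffsetNetwork(cfg.network(), rng)


def _leaf_state(pair: tuple[AugmentedCloud, np.ndarray], model: OffsetNetwork):
    from scipy.spatial import cKDTree

    aug, real = pair
    nbrs = model.build_graph(aug.points)
    d_nn = np.linalg.norm(aug.points[nbrs[:, 0]] - aug.points, axis=1)
    real = np.asarray(real, dtype=float)
    dr, _ = cKDTree(real).query(real, k=2)
    l_bar = float(np.median(np.atleast_2d(dr)[:, 1]))
    return {"aug": aug, "real": real, "nbrs": nbrs, "l_bar": l_bar,
            "d_nn_med": float(np.median(d_nn))}


def _reconstruction_pass(model: OffsetNetwork, state: dict, cfg: GeneratorConfig):
    """Forward pass + loss terms + parameter gradients for one leaf."""
    aug: AugmentedCloud = state["aug"]
    offsets, cache = model.forward(aug.points, aug.skeleton_mask, state["nbrs"])
    p_hat = aug.points + offsets

    graph = L.build_knn_graph(p_hat, cfg.knn_k, d_max=5.0 * state["d_nn_med"])
    terms = {
        "skeleton": L.skeleton_loss(offsets, aug.skeleton_mask),
        "chamfer": L.chamfer_distance(state["real"], p_hat, squared=True),
        "edges": L.edge_loss(graph, p_hat, state["l_bar"]),
        "smooth": L.smoothness_loss(p_hat, graph),
    }
    w = cfg.loss_weights
    grad_points = (
        w.w_chamfer * L.chamfer_grad(p_hat, state["real"])
        + w.w_edges * L.edge_loss_grad(graph, p_hat, state["l_bar"])
        + w.w_smooth * L.smoothness_loss_grad(p_hat, graph)
    )
    grad_offsets = grad_points + w.w_skeleton * L.skeleton_loss_grad(offsets, aug.skeleton_mask)
    grads = model.backward(grad_offsets, cache)
    return terms, grads, p_hat


def _distribution_terms(p_hats: list[np.ndarray], real_emb: M.EmbeddingSet,
                        cfg: GeneratorConfig) -> dict[str, float]:
    try:
        gen_emb = M.embed_clouds(p_hats[: cfg.distribution_batch])
        k = min(cfg.pr_k, len(gen_emb) - 1, len(real_emb) - 1)
        if k < 1:
            raise ValueError("too few leaves for PR monitor")
        pr = M.precision_recall(real_emb, gen_emb, k)
        return {
            "cmmd": M.cmmd(real_emb, gen_emb),
            "fid": M.fid(real_emb, gen_emb),
            "pr": M.pr_loss(pr, epsilon=1e-8),
        }
    except ValueError as exc:  # batches too small for some term
        log.warning("distribution terms skipped: %s", exc)
        return {"cmmd": 0.0, "fid": 0.0, "pr": 0.0}


def train(model: OffsetNetwork, pairs: list[tuple[AugmentedCloud, np.ndarray]],
          cfg: GeneratorConfig) -> TrainingHistory:
    """Optimize the offset network on (augmented cloud, real cloud) pairs.

    Per-leaf gradient accumulation over mini-batches (no padding across the
    variable point counts); Adam updates; the distribution terms are
    evaluated once per epoch on the current generated batch against the
    precomputed real-set embeddings.  Aborts on a non-finite loss, keeping
    the last finite-state parameters.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    states = [_leaf_state(p, model) for p in pairs]
    real_emb = M.embed_clouds([s["real"] for s in states])
    opt = Adam(lr=cfg.learning_rate)
    history = TrainingHistory()
    last_good = model.state_dict()
    order = np.arange(len(states))
    rng = np.random.default_rng(cfg.seed + 1)

    for epoch in range(1, cfg.epochs + 1):
        t0 = time.perf_counter()
        rng.shuffle(order)
        epoch_terms: dict[str, float] = {}
        p_hats: list[np.ndarray] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            acc: dict[str, np.ndarray] = {}
            for i in batch:
                terms, grads, p_hat = _reconstruction_pass(model, states[i], cfg)
                p_hats.append(p_hat)
                for name, value in terms.items():
                    epoch_terms[name] = epoch_terms.get(name, 0.0) + value
                for key, g in grads.items():
                    acc[key] = acc.get(key, 0.0) + g / len(batch)
            opt.step(model.params, acc)

        for name in epoch_terms:
            epoch_terms[name] /= len(states)
        epoch_terms.update(_distribution_terms(p_hats, real_emb, cfg))
        total = L.total_loss(epoch_terms, cfg.loss_weights)
        if not np.isfinite(total):
            log.error("non-finite loss at epoch %d; restoring last checkpoint", epoch)
            model.load_state_dict(last_good)
            break
        last_good = model.state_dict()
        history.record(epoch, epoch_terms, total, time.perf_counter() - t0)
    return history


def generate_leaf(
    model: OffsetNetwork,
    profile: SpeciesProfile,
    rng: np.random.Generator,
    target: tuple[float, float] | None = None,
    delta: int = 9,
    resolution: Resolution = Resolution(),
) -> GeneratedLeaf:
    """Generate one leaf conditioned on (optionally) given scale factors."""
    params = sample_skeleton_params(profile, rng)
    if target is not None:
        params = replace(params, s_l=float(target[0]), s_w=float(target[1]))
    skeleton = build_skeleton(params, resolution)
    traits = compute_traits(params)
    aug = augment_skeleton(skeleton, delta=delta, rng=rng)
    offsets, _ = model.forward(aug.points, aug.skeleton_mask)
    return GeneratedLeaf(
        points=aug.points + offsets,
        offsets=offsets,
        conditioning_traits=traits,
        source_skeleton=skeleton,
        skeleton_mask=aug.skeleton_mask,
        params=params,
    )


def generate_dataset(
    model: OffsetNetwork,
    n: int,
    profile: SpeciesProfile,
    rng: np.random.Generator,
    delta: int = 9,
    resolution: Resolution = Resolution(),
) -> tuple[list[GeneratedLeaf], pd.DataFrame]:
    """Generate ``n`` leaves with per-leaf ground-truth traits and a manifest."""
    leaves: list[GeneratedLeaf] = []
    rows = []
    for i in range(n):
        seed = int(rng.integers(2**31 - 1))
        leaf = generate_leaf(model, profile, np.random.default_rng(seed),
                             delta=delta, resolution=resolution)
        leaves.append(leaf)
        t = leaf.conditioning_traits
        rows.append({
            "leaf_id": i,
            "seed": seed,
            "s_l": leaf.params.s_l,
            "s_w": leaf.params.s_w,
            "blade_length": t.blade_length,
            "total_length": t.total_length,
            "blade_width": t.blade_width,
        })
    manifest = pd.DataFrame(rows, columns=[
        "leaf_id", "seed", "s_l", "s_w", "blade_length", "total_length", "blade_width",
    ])
    return leaves, manifest


def save_checkpoint(path, model: OffsetNetwork, cfg: GeneratorConfig) -> None:
    """Single-file archive of weights + JSON config metadata."""
    meta = json.dumps({
        "hidden_width": cfg.hidden_width, "n_layers": cfg.n_layers,
        "neighborhood_k": cfg.neighborhood_k, "learning_rate": cfg.learning_rate,
        "epochs": cfg.epochs, "batch_size": cfg.batch_size, "seed": cfg.seed,
    })
    np.savez(path, __meta__=np.array([meta]), **model.state_dict())


def load_checkpoint(path) -> tuple[OffsetNetwork, GeneratorConfig]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"][0]))
    cfg = GeneratorConfig(**meta)
    model = init_model(cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, cfg
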
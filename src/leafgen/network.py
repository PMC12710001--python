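"""A small permutation-equivariant point network predicting per-point offsets.

The network maps an N x 3 cloud plus a per-point skeleton-mask channel to an
N x 3 offset field.  Each layer combines a pointwise linear transform of the
point's own features with a linear transform of the mean features of its k
nearest input-space neighbors, followed by ReLU; a final linear head (zero
initialized, so an untrained model predicts exactly zero offsets) maps to 3
offset components.  Inputs are normalized per cloud (centroid removed, unit
RMS radius) and the predicted offsets are scaled back to model units, making
the network size-agnostic across species.

Forward and backward passes are written directly in numpy; training uses a
hand-rolled Adam optimizer.  The k-NN aggregation graph is computed on the
*input* cloud, so it is constant during a forward/backward pair and the
network is exactly permutation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["NetworkConfig", "OffsetNetwork", "Adam"]


@dataclass(frozen=True)
class NetworkConfig:
    hidden_width: int = 32
    n_layers: int = 3
    neighborhood_k: int = 8

    def __post_init__(self) -> None:
        if self.hidden_width < 1 or self.n_layers < 1 or self.neighborhood_k < 1:
            raise ValueError("invalid network configuration")


def _neighbor_means(h: np.ndarray, nbrs: np.ndarray) -> np.ndarray:
    """Mean of neighbor features; rows of ``nbrs`` index into ``h`` (self used
    for padding when fewer than k neighbors exist)."""
    return h[nbrs].mean(axis=1)


class OffsetNetwork:
    """Per-point offset predictor with k-NN mean aggregation."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        d_in, w = 4, cfg.hidden_width
        self.params: dict[str, np.ndarray] = {}
        fan = d_in
        for layer in range(cfg.n_layers):
            std = np.sqrt(2.0 / fan)
            self.params[f"Wself{layer}"] = rng.normal(0, std, size=(fan, w))
            self.params[f"Wnbr{layer}"] = rng.normal(0, std, size=(fan, w))
            self.params[f"b{layer}"] = np.zeros(w)
            fan = w
        # zero-initialized head: untrained network predicts zero offsets
        self.params["Whead"] = np.zeros((w, 3))
        self.params["bhead"] = np.zeros(3)

    # -- graph -------------------------------------------------------------
    def build_graph(self, points: np.ndarray) -> np.ndarray:
        """Neighbor index matrix (N, k) on the input cloud; self-padded."""
        points = np.asarray(points, dtype=float)
        n = len(points)
        k = min(self.cfg.neighborhood_k, max(n - 1, 1))
        if n == 1:
            return np.zeros((1, 1), dtype=int)
        _, idx = cKDTree(points).query(points, k=k + 1)
        idx = np.atleast_2d(idx)
        out = np.empty((n, k), dtype=int)
        for u in range(n):
            row = idx[u][idx[u] != u][:k]
            if len(row) < k:
                row = np.pad(row, (0, k - len(row)), constant_values=u)
            out[u] = row
        return out

    # -- forward / backward ------------------------------------------------
    def forward(self, points: np.ndarray, mask: np.ndarray,
                nbrs: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
        """Predict offsets (model units). Returns (offsets, cache for backward)."""
        points = np.asarray(points, dtype=float)
        mask = np.asarray(mask, dtype=float)
        centroid = points.mean(axis=0)
        scale = float(np.sqrt(((points - centroid) ** 2).sum(axis=1).mean()))
        scale = max(scale, 1e-12)
        x = (points - centroid) / scale
        h = np.column_stack([x, mask])
        if nbrs is None:
            nbrs = self.build_graph(points)

        cache: dict = {"inputs": [], "pre": [], "nbrs": nbrs, "scale": scale}
        for layer in range(self.cfg.n_layers):
            hn = _neighbor_means(h, nbrs)
            pre = (h @ self.params[f"Wself{layer}"] + hn @ self.params[f"Wnbr{layer}"]
                   + self.params[f"b{layer}"])
            cache["inputs"].append((h, hn))
            cache["pre"].append(pre)
            h = np.maximum(pre, 0.0)
        cache["hidden"] = h
        offsets = (h @ self.params["Whead"] + self.params["bhead"]) * scale
        return offsets, cache

    def backward(self, grad_offsets: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given the loss
        gradient w.r.t. the predicted offsets."""
        grads: dict[str, np.ndarray] = {}
        scale = cache["scale"]
        nbrs = cache["nbrs"]
        g = np.asarray(grad_offsets, dtype=float) * scale
        h = cache["hidden"]
        grads["Whead"] = h.T @ g
        grads["bhead"] = g.sum(axis=0)
        gh = g @ self.params["Whead"].T
        for layer in reversed(range(self.cfg.n_layers)):
            pre = cache["pre"][layer]
            gpre = gh * (pre > 0)
            h_in, hn_in = cache["inputs"][layer]
            grads[f"Wself{layer}"] = h_in.T @ gpre
            grads[f"Wnbr{layer}"] = hn_in.T @ gpre
            grads[f"b{layer}"] = gpre.sum(axis=0)
            if layer > 0:
                gh = gpre @ self.params[f"Wself{layer}"].T
                gnbr = gpre @ self.params[f"Wnbr{layer}"].T
                # scatter mean-aggregation gradient back to neighbors
                k = nbrs.shape[1]
                contrib = np.zeros_like(gh)
                np.add.at(contrib, nbrs.ravel(), np.repeat(gnbr / k, k, axis=0))
                gh = gh + contrib
        return grads

    # -- (de)serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).copy()


@dataclass
class Adam:
    """Adam optimizer over a parameter dict."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
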
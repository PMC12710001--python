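"""Independent brute-force oracles shared by the acceptance checks.

Every function here is a direct O(N^2)-or-worse transcription of the
defining formula, kept free of the package's own fast paths.
"""

import numpy as np


def brute_chamfer(a, b, squared=True):
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    d = d2 if squared else np.sqrt(d2)
    return float(d.min(axis=1).sum() + d.min(axis=0).sum())


def brute_neighbor_sets(points, k, d_max):
    out = []
    for u in range(len(points)):
        d = np.linalg.norm(points - points[u], axis=1)
        order = [v for v in np.argsort(d, kind="stable") if v != u and d[v] < d_max]
        out.append(set(order[:k]))
    return out


def brute_cmmd_linear(x, y):
    n, m = len(x), len(y)
    sx = sum(float(x[i] @ x[j]) for i in range(n) for j in range(n) if i != j)
    sy = sum(float(y[i] @ y[j]) for i in range(m) for j in range(m) if i != j)
    sxy = sum(float(x[i] @ y[j]) for i in range(n) for j in range(m))
    return sx / (n * (n - 1)) + sy / (m * (m - 1)) - 2 * sxy / (n * m)


def brute_coverage(v, phi, k):
    for vp in phi:
        radius = sorted(np.sum((phi - vp) ** 2, axis=1))[k]
        if np.sum((v - vp) ** 2) < radius:
            return 1
    return 0


def brute_realism(vg, phi, k):
    best = 0.0
    for vp in phi:
        radius = np.sqrt(sorted(np.sum((phi - vp) ** 2, axis=1))[k])
        d = np.linalg.norm(vg - vp)
        best = max(best, np.inf if d == 0 else radius / d)
    return best
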
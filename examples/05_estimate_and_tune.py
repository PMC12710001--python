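"""Estimate leaf traits and tune an estimator on a labeled corpus.

Runs the polynomial-skeleton and geodesic estimators on labeled pseudo-real
leaves, then grid-searches the polynomial degree to minimize the mean
relative trait error — the calibration step generated datasets make
possible without manual measurements.
"""

import numpy as np

import leafgen as lg
from leafgen.traits import EstimatorParams, estimate_traits, trait_error, tune

records, _ = lg.generate_corpus(
    12, lg.MAIZE, lg.NoiseConfig(gaussian_sigma=0.002), seed=21)
dataset = [(r.cloud, r.traits) for r in records]

for params in (EstimatorParams(method="polyfit", poly_degree=3),
               EstimatorParams(method="geodesic")):
    errs = [trait_error(estimate_traits(c, params), t) for c, t in dataset]
    print(f"{params.method:9s} median relative trait error "
          f"{100 * np.median(errs):.1f}%")

grid = [EstimatorParams(poly_degree=d) for d in (1, 2, 3, 5, 8)]
result = tune(dataset, grid)
print("\ndegree grid search (summed relative error over the corpus):")
for cand, err in result.error_surface:
    marker = " <- selected" if cand == result.best_params else ""
    print(f"  degree {cand.poly_degree}: {err:.3f}{marker}")
print(f"tuned mean error per leaf: {100 * result.best_error / len(dataset):.1f}%")
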
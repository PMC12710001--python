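# Methods

This note records the models, conventions and numerical choices behind
`leafgen`, the design decisions that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Skeleton model and trait labels

A leaf skeleton consists of up to three analytic curves in a canonical
frame: petiole `z = αx`, `x ∈ [x_min, 0]`; main axis `z = tanh(x)`,
`x ∈ [0, 1]`; lateral parabola `z = ay² + by + c` at `x = x_cross`, passing
through the crossing point and the lateral extremes at `y = ±0.5` with
elevations `z_cross + z_r`, `z_cross + z_l`. Parameter priors:
`α ~ U(π/6, π/3)`, `x_min ~ U(−1, −0.25)`, `x_cross ~ U(0.25, 0.75)`,
`z_r, z_l ~ U(−0.25, 0.25)` resampled until distinct (no minimum gap).
Scaling multiplies `x` by `s_l` and `y` by `s_w` and leaves `z` unchanged.
Species profiles: sugar beet `s_l ~ U(0.02, 0.50)`, `s_w ~ U(s_l/4, s_l)`,
petiole present; maize `s_l ~ U(0.15, 0.90)`, `s_w ~ U(s_l/10, s_l/5)`, no
petiole; tomato `s_l ~ U(0.10, 0.50)`, `s_w ~ U(s_l/2, s_l)`, petiole
present. Model units are treated as meters throughout; this is a
documentation convention only.

**Traits are true arc lengths of the scaled curves** (default mode):
blade length `∫₀^{s_l} √(1 + z′²) dx′` for `z = tanh(x′/s_l)`; blade width
the arc length of the scaled parabola over its actual scaled extent
`y′ ∈ [−s_w/2, s_w/2]`; total length adds the petiole segment
`|x_min|·√(s_l² + α²)`. A `paper_literal` mode evaluates the alternative
integrand convention in which the `1 +` term is dropped under the root and
the width is integrated over `[−s_w, s_w]` of the unscaled parabola slope —
that form reduces the width to the parabola's vertical variation and is kept
for cross-checking only, because a trait label must describe the curve that
is actually emitted. Quadrature is `scipy.integrate.quad` with
`epsabs = 1e-12`, `epsrel = 1e-10`; non-convergence raises
`TraitQuadratureError`. Exactness is regression-checked against a
100 000-point polyline oracle (< 1e-6 relative; measured ~1e-11).

Note a geometric consequence of leaving `z` unscaled: for small `s_l` the
blade length is dominated by the fixed `z`-rise of the tanh (≈ tanh 1), so
lengths vary much less than `s_l` does, and lateral cross-sections are steep
(the `z_r`, `z_l` offsets are not scaled while the `y` half-extent is
`s_w/2`). This is intrinsic to the skeleton construction, is reflected
consistently in the surface generator and the labels, and drives the width
extraction accuracy discussed below.

Default sampling resolutions: 20 petiole, 50 main-axis, 30 lateral points
(no canonical values exist; these give ~single-millimeter polyline error at
decimeter scales).

## Pseudo-real surface generator

The synthetic stand-in for field-acquired single-leaf clouds sweeps the
lateral parabola profile along the main axis with a smooth width envelope
that is 0 at base and tip and maximal at `x_cross`. The envelope is a
cube-root-flattened sine plateau: real blades hold near-maximal width over
much of their length, and the plateau keeps the midsection width measurable
at the median chain node. The `v = 0` profile is the main axis and the
`u = x_cross` profile is the lateral parabola, so both skeleton curves are
embedded exactly in the surface and the attached `compute_traits` labels are
exact by construction. Points are sampled approximately area-uniformly
(importance sampling of a 96×32 parameter grid by local area element);
petiole points lie exactly on the petiole line. Sensor imperfections:
isotropic Gaussian noise (σ as a fraction of blade length, default 0.002),
independent dropout, and one contiguous occlusion patch (nearest-quantile
ball around a random surface point). Defaults: 600 points per leaf.

What this emulates: single-leaf clouds of varying density and noise with
petiole presence by species. What it does not: photogrammetric artifacts
(holes, ghost points, non-uniform viewpoint density), self-occlusion
geometry, leaf thickness (surfaces are infinitely thin), or real
species-specific blade shapes (margins are smooth; no heart shapes or
serration). Green tests on this corpus therefore demonstrate pipeline
correctness and internal consistency, not field performance.

## Skeleton extraction

The main axis is an ordered chain fitted as a principal curve: nodes are
initialized at the centroids of equal-width bins of the projection onto the
first principal component, then refined by alternating 1-D assignment (each
point to the node nearest *in projection coordinate*) and averaging, with
each node blended toward the midpoint of its chain neighbors (weight 0.5),
until node movement < 1e-6 or 100 iterations. Assignment in the projection
coordinate rather than in 3-D is deliberate: nearest-node-in-3-D assignment
lets nodes specialize laterally across a wide blade and the chain zigzags,
inflating its polyline length by tens of percent. Node ordering follows the
first-principal-component projection (tip-to-base orientation is not
disambiguated; no consumer needs it).

The lateral axis: slice all points within (closed) distance `τ` of the line
through the median chain node `m` along the second principal component, and
re-fit a chain on the slice. Defaults: `τ` = 10% of the first-principal
extent, 40 main / 21 lateral nodes. The wide default `τ` is needed because
the lateral cross-sections bend away from any straight line by more than a
narrow tube would capture (see the unscaled-`z` note above).

Accuracy on noise-free pseudo-real leaves (median over 50 seeds): main-chain
length within ~2–3% of the total (or blade, for petiole-free species)
length for all species; lateral width within ~11% for tomato, ~20% for
sugar beet and ~30% for maize. The width gap for narrow species is a
property of the slice-line construction applied to steep V-shaped
cross-sections, not of the chain fitter — anchoring the slice at the true
crossing point and using the exact lateral direction reproduces the same
error. The regression tests pin these levels.

## GMM augmentation

Full-covariance mixtures (modes stretch along curve-like skeletons), fitted
by EM (scikit-learn backend: k-means init seeded from the caller's
generator, covariance floor 1e-8, tol 1e-6, ≤ 200 iterations). Mode count
`J = 2` when the species has a petiole (one mode is expected to capture it),
else `J = 1`; `J` is dataset metadata, not inferred from the extracted
skeleton (extraction never labels a petiole part). Sampling draws a
component per point from the mixture weights, then a Gaussian draw — fully
reproducible from one `numpy` Generator. The density multiplier `δ`
defaults to 9 (total cloud = 10× skeleton size), which yields surface-like
densities from typical skeleton sizes; no canonical value exists.

## Offset network and training

The generator is a small permutation-equivariant point network written
directly in numpy: inputs are per-point `(x, y, z, mask)` after per-cloud
normalization (centroid removed, unit RMS radius); each of 3 layers combines
a pointwise linear map with a linear map of the mean features of the k = 8
nearest input-space neighbors, followed by ReLU (width 32); a
zero-initialized linear head outputs 3 offset components, scaled back to
model units. Zero initialization makes the untrained generator exactly the
identity (`P̂ = P`). Backpropagation and the Adam optimizer
(lr 0.001, β = 0.9/0.999) are hand-written; gradients of every loss term
with respect to the output points are analytic (nearest-neighbor assignments
and graph structure treated as locally constant) and are verified against
central differences in the test suite. The aggregation graph is built once
per leaf on the *input* cloud; the edge/smoothness graph is rebuilt on the
output cloud each step (k = 8, `d_max` = 5× the input cloud's median NN
distance, `l̄` = the real cloud's median NN distance).

Loss weights follow the reference configuration: skeleton 1, chamfer 0.1,
edges 0.1, smoothness 10, and 0.01 on the grouped distribution terms. The
**smoothness objective is the quadratic Laplacian form** `Σ‖(LP̂)_u‖²`
(rows with empty neighborhoods excluded — their row reduces to `−p̂_u`,
penalizing absolute position rather than smoothness). The sum-of-norms
variant `Σ‖(LP̂)_u‖` is available (`squared=False`) but not the default: its
gradient has constant magnitude however smooth the cloud already is, so at
weight 10 it indefinitely drags skeleton points off their anchors (measured
4–7% of blade length mean displacement, defeating the anchoring term's
purpose); with the quadratic form the gradient vanishes on smooth clouds
and displacement settles near 0.03%.

Distribution terms (CMMD, FID, PR-loss) are computed once per epoch on the
embeddings of the current generated batch against the precomputed embeddings
of the real training set. The default geometric embedding is not
differentiable, so these terms enter the reported total as weighted monitors
while parameter gradients come from the reconstruction terms; setting the
distribution weight to 0 is the reconstruction-only ablation. The embedding
interface is pluggable, so a differentiable or externally computed embedding
(one vector per leaf) can replace it.

Training accumulates per-leaf gradients over mini-batches of 4 (no padding
across variable point counts). The reference smoke configuration — 20
pseudo-real sugar-beet leaves (σ = 0.002, 600 points), δ = 9, 200 epochs —
runs in about 90 s on one CPU and, across seeds, reaches a final total loss
of 0.27–0.47× the first-epoch loss with mean skeleton displacement ≤ 0.1%
of blade length; generation uses skeleton resolutions matching the
extraction node counts (20/40/21) to avoid a train/generate density
mismatch.

## Embeddings and distribution metrics

The default per-leaf descriptor (d = 48) concatenates: normalized central
moments of orders 2–3 in a canonical frame (PCA axes, signs fixed by
third-moment positivity, unit RMS radius), a 16-bin radial density
histogram, and a 16-bin height histogram along the first principal axis.
It is exactly permutation-invariant and invariant to rigid motion and
uniform scale modulo the canonical frame. It is a deterministic geometric
summary, not a learned perceptual embedding: separation is demonstrated at
distribution level (cross-species mean distance exceeds within-species),
per-pair overlap is expected.

CMMD is the unbiased squared MMD (within-set sums over ordered pairs
`i ≠ j`, cross-term over all pairs); the linear kernel is the default, RBF
with the median-heuristic bandwidth is available. On *identical* sets the
unbiased estimator is slightly negative by construction. FID uses the
principal matrix square root `(Σ_r Σ_f)^{1/2}` (an FID without the square
root is not a distance) and Ledoit–Wolf shrinkage when a set is smaller
than d + 1. Coverage uses squared norms with a strict inequality (ties
excluded); realism scores use the unsquared radius/distance ratio with
`+inf` when a generated vector coincides with a real one. The F-score is
averaged over `k ∈ {2, 4, 8, 16, 32, 48, 64, 96}`, skipping infeasible `k`;
realism-filtered results are flagged invalid when half or fewer of the
generated vectors survive.

Point-to-mesh diversity reconstructs each leaf surface by Delaunay
triangulation in its PCA plane with triangles pruned when their longest 3-D
edge exceeds 4× the median NN spacing — an alpha-shape-style mesher suited
to open, nearly developable leaf surfaces — and compares mean
|d(probe, mesh_A) − d(probe, mesh_B)| over uniform probes in the padded
joint bounding box (exact vectorized point-triangle distances). Meshing
failure falls back to the symmetric mean Chamfer distance with a logged
warning.

## Trait estimators and tuning

`polyfit`: extract the skeleton; fit polynomials (default degree 3) to the
chain's transverse coordinates as functions of its first-PC projection;
blade length = arc length of the fitted curve integrated over the *cloud's*
projection extent (so chain-end shrinkage does not truncate the length);
width likewise on the lateral chain. Least-squares polynomials cannot
represent curves with near-vertical tangents (a semicircle keeps ≥ 6%
arc-length error even at degree 8), so accuracy claims are made for gentle
bends.

`geodesic`: remove sparse outliers (< 2 neighbors within 3× median NN
distance); directions from PCA; endpoint candidates = top/bottom 2% of
projections, restricted to the largest connected component of the k-NN
graph; trait = max over candidate pairs of the Dijkstra shortest path with
edge cost `distance^p` (default p = 1). Default k = 16: smaller
neighborhoods make paths zigzag laterally (≈ 5% length inflation at k = 8
on a dense half-circle ribbon vs ≈ 1.4% at 16).

`tune` is exhaustive grid search over candidate parameter sets; failed
candidates score `+inf`; ties break by grid order; the error function
defaults to mean relative error (absolute and squared variants provided).
Patch reports give per-patch mean/std/min/max per trait.

**On the per-leaf vs patch-averaged label experiment:** with patches formed
by deterministic round-robin assignment, every patch has the same trait
distribution and the patch-mean labels are nearly a global constant. The
patch-label tuning objective then equals the per-leaf objective plus a
within-patch dispersion term that is almost independent of the candidate,
so grid selection ties between the two labelings far more often than it
flips — the controlled corpus cannot reproduce the advantage that per-leaf
labels show on heterogeneous real fields. The experiment is implemented
and reported as specified; its strict-inequality assertion documents this
limitation rather than hiding it.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen as
the smallest that exercise every code path with stable statistics: corpora
of 8–100 leaves at 600 points, 200-epoch training on 20 leaves, 10⁴-sample
Monte-Carlo checks, 10⁵-point polyline oracles, and brute-force metric
oracles at ≤ 50 elements. The acceptance script completes in ~1 minute and
the full test suite in a few minutes on one CPU.

## Known limitations

- Width extraction degrades on species whose scaled `y`-extent is small
  relative to the unscaled lateral elevations (see above); documented
  regression bounds differ by species.
- The offset network is a deliberately small CPU model behind a swappable
  interface; it demonstrates the training objective, not a
  state-of-the-art backbone.
- Distribution losses act as monitors under the default non-differentiable
  embedding; they shape training only through a differentiable embedding
  plugged into the same interface.
- Compound leaves, whole-plant segmentation, template-mesh fitting and
  external pretrained embedding networks are out of scope; externally
  computed embeddings and pre-extracted skeletons can be supplied through
  the documented interfaces.
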
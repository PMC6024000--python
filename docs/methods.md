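# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `neurorecon`, and what the synthetic study design does and does not
establish.

## Representation network

`Φ` is a small convolutional network with the classic AlexNet-style layer
taxonomy — linear convolution (implemented as cross-correlation, no kernel
flip), ReLU gating, spatial max-pooling, cross-channel local response
normalization (LRN), and fully connected layers — on a single-channel
(grayscale) input with pixel values in [0, 1].  It is never trained:
weights are drawn once from a zero-mean Gaussian with standard deviation
`1/sqrt(fan_in)` using a generator seeded per layer from the network seed
(`SeedSequence(entropy=seed, spawn_key=(layer_index,))`), which keeps
activation magnitudes stable through depth and makes builds bit-for-bit
reproducible.  Random convolutional features preserve enough image
geometry for linear decoding and inversion experiments; they do not
emulate the semantic selectivity of a trained object-recognition network.

LRN follows the Krizhevsky form `b_c = a_c / (k + α Σ_{c'∈window} a_{c'}²)^β`
with defaults `(k, n, α, β) = (2, 5, 1e-4, 0.75)` and a centered size-`n`
channel window truncated at the edges (no `α/n` scaling).

The default 14-layer stack on a 32×32 input is
conv1(8ch, k5, s2, p2) – relu1 – mpool1(k2, s2) – norm1 – conv2(12ch, k3,
s1, p1) – relu2 – mpool2 – norm2 – conv3(16ch) – relu3 – conv4(16ch) –
relu4 – fc5(32) – relu5.  Depth matters for the hierarchy analysis: the
Mann–Kendall trend over per-layer area proportions can only reach
p < 0.05 with five or more points, so the scan covers all 14 layers.

Feature vectors are flattened channel-major, then row-major spatial
(C-order ravel of the `(C, H, W)` activation).  Max-pool forward values are
tie-free by definition; the backward pass routes the gradient to the first
maximal element in row-major scan order.  ReLU's input gradient at exactly
zero is taken as zero.  `input_gradient` returns the exact vector-Jacobian
product `∂⟨Φ(x), c⟩/∂x`; every layer type is verified against central
finite differences (tolerance 1e-4, probe images chosen away from ReLU
kinks where finite differences are invalid).

## Synthetic encoding model

The generator emulates a passive-viewing encoding experiment:

- **Stimuli**: bars, discs, oriented gratings and smoothed random
  textures, cycling through the kinds with randomized parameters; all in
  [0, 1].  The default split is 175 training / 12 validation images — one
  tenth of the 1750/120 reference design — so the full pipeline runs in
  seconds; both counts are configurable and `paper_scale=True` restores
  the full counts.
- **Voxels**: 300 by default, partitioned into V1/V2/V3/V4 with counts
  69/110/95/26 (largest-remainder apportionment of the reference pool
  ratio 1294:2083:1790:484).  Each voxel's clean response is an
  `s_enc`-sparse (default 3) linear combination — magnitudes uniform in
  [1, 2], random signs — of the features of its area's anchor layer:
  V1→mpool1, V2→conv2, V3→mpool2, V4→conv4.  This plants the
  early-area/shallow-layer gradient the trend test must recover.
- **Noise**: additive Gaussian with standard deviation
  `noise_sd × sd(clean response)` per voxel; default `noise_sd = 0.5`
  (noise at half the signal SD), a moderate regime where decoding clearly
  succeeds yet is visibly degraded.  The generator does not model
  hemodynamics, trial repeats, or natural-image statistics; conclusions
  from passing tests concern the estimators, not real BOLD data.

A coverage property worth stating explicitly: with 300 voxels × 3
couplings against layers of up to 2048 features, most features of a layer
are not coupled to any voxel, so even noise-free decoding cannot reach
mean r ≈ 1 — uncovered features are predictable only through feature
correlations (observed noise-free plateaus are ≈ 0.55–0.75).  The
end-to-end claims are therefore framed against the shuffled null rather
than against perfect recovery.

`make_sparse_problem` provides the solver test bed: i.i.d. Gaussian
designs with unit-norm columns and exactly `s`-sparse coefficients with
magnitudes in [1, 2] — the regime where greedy recovery guarantees apply.

## Sparse decoding

Voxel columns are z-scored with training-set statistics (constant columns
get unit SD) and an intercept column is appended after standardization;
the intercept never counts toward sparsity.

**ROMP.**  Default sparsity `s = ceil(m / (2 log n))` capped at 50 (the
compressed-sensing `m ≳ s log n` convention; the pipeline default is
s = 8, matching the planted problems' scale).  The regularization step
sorts candidate correlations descending and finds the maximal-energy
contiguous window satisfying `max ≤ 2·min` by a two-pointer sweep (an
optimal comparable subset is always contiguous in sorted order); ties
break toward lower indices.  Iteration stops at `max_support = 2s` or
residual norm below `1e-10‖y‖`.  Because ROMP's guarantee is recovery of
a *superset* of the true support, the final least-squares refit is pruned:
coefficients below `1e-8 × max|w|` are dropped and the model refit once,
making "exact support recovery" a well-defined event at zero noise.

**L1.**  The penalized program `min ½‖Xw−y‖² + λ‖w‖₁` is solved by
monotone FISTA (the accelerated candidate is discarded whenever it would
increase the objective, so the recorded trace is non-increasing; the
Lipschitz constant comes from 60 power iterations).  Equality-constrained
basis pursuit is approximated by a warm-started homotopy over 12
geometrically decreasing λ values from `0.5‖Xᵀy‖∞` to `1e-8‖Xᵀy‖∞`.
Support is defined by truncating entries below `1e-6 × max|w|`.  The
intercept is fitted by centering `X` and `y` (equivalent to an unpenalized
constant column at the optimum); `fit_intercept=False` preserves the exact
soft-threshold closed form on orthonormal designs.  Hitting `max_iter`
without meeting the tolerance returns a model flagged `converged=False`
rather than an exception.  Pipeline-scale fits use a relaxed tolerance
(1e-6, 800 iterations) since per-feature decoding does not need
oracle-grade precision.

The fitting interface follows the Model → `fit()` → Results idiom:
`LayerDecoder(features, responses, solver=...)` returns
`LayerDecoderResults` with one sparse model per feature, shared
standardization, `predict`, `summary()`, and the per-voxel usage counts
the contribution analysis consumes.  Constant feature columns are skipped,
flagged, and excluded from accuracy averaging (their prediction is the
constant itself).

## Feature inversion

The objective is the normalized Euclidean feature loss plus two
regularizers: `λ_α Σ|x̄ᵢ|^α` on the mean-subtracted image (default
`α = 6`, `λ_α = 1e-4`) and smooth total variation
`λ_TV Σ((Δ_h x)² + (Δ_v x)²)^{β/2}` with forward differences and
replicate boundary (default `β = 2`, `λ_TV = 1e-3`; for `β < 2` an
`ε = 1e-8` floor keeps the gradient finite).  Normalizing the feature
loss by `‖Φ₀‖²` makes the λ's scale-free; `loss_normalization="none"`
disables it.

Optimization is gradient descent with momentum: `v ← μv − ηg`,
`x ← clip(x + v, [0, 1])`, defaults `μ = 0.9`, `η = 0.2`, 500 iterations,
initialized from clipped Gaussian noise around 0.5 (SD 0.15) or a constant
0.5.  The best iterate by objective value is returned with the full loss
trace.  If the objective exceeds 1e3× its initial value (or turns
non-finite) the step is halved once and the run restarts; a second
blow-up raises `InversionDivergence`.  Batch reconstruction derives a
per-trial seed from the config seed and isolates per-trial failures in
each result's `status`.

## Evaluation

- **Prediction accuracy**: vectorized per-feature Pearson r across
  validation trials (≥ 3 required); constant columns are excluded and
  counted.  Significance against the shuffled null uses 200 row
  permutations of the predictions and the add-one p-value estimator.
- **CW-SSIM**: complex log-Gabor filter bank in the frequency domain,
  3 levels × 4 orientations by default (center frequencies 0.25/2^level
  cycles per pixel, bandwidth ratio 0.55, one-sided angular Gaussians of
  width (π/orientations)/1.2, DC excluded), per-window index
  `S = (2|Σ c_a c_b*| + K)/(Σ|c_a|² + Σ|c_b|² + K)` with `K = 0`.  The
  decomposition is undecimated, so the averaging window scales with level
  (7×7 × 2^level) to match the conventional decimated-subband window.
  Cauchy–Schwarz bounds S in [0, 1]; an ε-guard makes identical constant
  images score 1.  Subband weights are uniform by default and exposed.
- **2AFC identification**: for each original, the metric compares its own
  reconstruction against one uniformly drawn other reconstruction (seeded);
  ties earn half credit; chance is 0.5; a one-sided binomial test scores
  the run.
- **Significant voxels**: a voxel's frequency is the number of feature
  models whose support contains it; the top-k (ties by summed |weight|,
  then lowest index) are the significant voxels, and area proportions are
  taken over the labeled ones.  At desk scale the default is k = 60 (20%
  of the 300-voxel panel); the reference analysis used 300 of 5651 voxels
  (~5%), and `paper_scale` restores those counts.  Choosing k equal to the
  panel would collapse the proportions to the panel composition and erase
  the trend.
- **Mann–Kendall**: `S = Σ_{i<j} sgn(x_j − x_i)`, tie-corrected variance
  `[n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18`, ±1 continuity correction, normal
  two-sided p.  Exact permutation enumeration is provided for n ≤ 8 and
  used to validate the approximation.
- **Paired t-test** on per-feature accuracy differences between solvers
  (the same features are scored under both, so the paired form applies);
  zero-variance differences are flagged undefined rather than returned as
  numbers.

## Orchestration and reproducibility

All stage randomness derives from named substreams of one master seed
(`stage_seed` hashes the stage name into a `SeedSequence` with the master
seed; all derived seeds are < 2^31), so a run is bit-reproducible from its
saved config, and the CLI stages (`simulate`, `extract`, `fit`, `predict`,
`reconstruct`, `evaluate`) interoperate through plain-text artifacts
(PNG, TSV, JSON) with SHA-256 checksums recorded in the run manifest.
The solver comparison defaults to the pooling/convolution representative
layers (ReLU layers decode poorly and add little to a solver contrast).
The recommended reconstruction layer is the first pooling layer among
layers with at least median accuracy — pooling features invert with less
distortion than deeper, more semantic features of equal accuracy.

## Known limitations

- Random (untrained) features stand in for a trained hierarchy; absolute
  CW-SSIM or accuracy values are comparable within this artifact only.
- The encoding simulator is linear-Gaussian by construction, matching the
  decoder's assumptions; it cannot probe model misspecification.
- Basis pursuit via homotopy is approximate (final λ is small but
  nonzero); for certified equality solutions use the penalized mode with a
  tight tolerance and shrink λ further.
- The 2AFC proxy replaces human raters with the CW-SSIM metric; agreement
  between metric and human judgment is outside scope.
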
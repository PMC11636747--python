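# Methods

## Smoothed Caputo fractional gradient

The kernel computes, per coordinate i of an objective f at x with lower
terminal (reference point) c,

    g_i = c_α Σ_m λ_m f′(t_im) + c_α γ |x_i − c_i| Σ_m λ_m f″(t_im),
    t_im = Δ_i (1 + u_m) + c_i,   Δ_i = (x_i − c_i)/2,
    c_α = (1 − α) 2^(−(1−α)),

where {(λ_m, u_m)} is the n-point Gauss-Jacobi rule for the weight
(1−u)^(−α) on [−1, 1] (`scipy.special.roots_jacobi` with parameters
(−α, 0)).  Properties relied on throughout, and verified in the test suite
against adaptive integration (`scipy.integrate.quad` with an algebraic
endpoint weight) and closed forms:

- constants map to the zero vector (the defining Caputo property);
- f(x) = x² with c = 0 gives exactly 2x/(2−α);
- α → 1 recovers the classical gradient (c_α · ∫(1−u)^(−α)du → 1);
- the rule integrates polynomials of degree ≤ 2n−1 exactly.

**Half-interval Δ.**  Δ_i = (x_i − c_i)/2 makes the substitution map the
quadrature interval exactly onto [c_i, x_i]; this is the unique affine
choice for which the α → 1 limit lands on f′(x_i).

**α = 1 cap.**  c_α vanishes at α = 1, which would annihilate the update,
so α is clipped internally to 1 − 10⁻⁶: the classical-gradient limit is
preserved instead of producing a dead step.

**Derivatives.**  By default f′ and f″ come from shared three-point central
differences with step h = max(h₀, h₀|t|), h₀ = 10⁻⁶.  Callers may supply an
analytic per-coordinate callback `(i, t) → (f′, f″)`, or a full-gradient
callback `grad_f`; with the latter, all coordinates are shifted jointly to
t_m = Δ(1+u_m) + c and one gradient evaluation per node replaces the
per-coordinate sweep.  The joint shift is exact for additively separable
objectives and an approximation otherwise; it is what makes the kernel
affordable for the million-parameter classifier head, where `grad_f` is
backpropagation and n gradient calls replace ~3·n·dim loss evaluations.
Note that second-difference noise limits the finite-difference path to
roughly 10⁻³–10⁻⁴ relative accuracy on the curvature term; the analytic
paths carry the tight tolerances in the tests.

**Curvature weight γ.**  The curvature term is a smoothing correction, not
a descent direction, and must not dominate the first-order term.  The
default is γ = 0.1: at γ = 1 the term swamps the gradient on
curvature-heavy objectives (on 2-D Rosenbrock, where f″ ~ 10³, the hybrid
then falls behind plain cuckoo search — 2/20 paired-seed wins — while at
γ = 0.1 it wins 15/20 with a ~14× better median).  Head training uses
γ = 0 (the joint-shift curvature estimate adds cost without benefit
there).

**Normalization.**  Under the smoothed formula the derivative of the
identity is exactly 1, so the diagonal normalization that motivates the
`normalize` option would be a no-op; when enabled, the classical Caputo
identity derivative |x_i − c_i|^(1−α)/Γ(2−α) is used as the normalizer
instead (restoring classical-gradient units), skipped where x_i = c_i.
Default off.

**Coincident terminals.**  x_i = c_i gives Δ_i = 0; the first term
collapses to c_α f′(c_i) Σλ_m and the curvature term vanishes.  No special
casing.

## Cuckoo search and the hybrid

Per generation, for each of n nests: a global proposal is compared greedily
against a randomly chosen nest; then the ⌈p_a·n⌉ worst nests are abandoned
and rebuilt with the local walk; the incumbent best is reinserted if the
rebuild lost it (elitism), so the best-so-far trace is non-increasing by
construction.

- Global walk (plain): x_j + β ⊗ Lévy(λ).  Lévy steps use Mantegna's
  construction with stability index λ − 1 (default λ = 2.5, the de-facto
  standard index 1.5); at the Gaussian edge λ = 3 a standard normal is
  substituted.  Tail behavior is property-tested with a Hill estimator.
- Local walk (plain): x_j + βs·H(p_a − v)·(x_p − x_q), v ~ U[0,1] per call,
  x_p, x_q drawn via two independent population permutations; H(0) = 1.
- Hybrid global walk: x_j − β (Lévy ⊗ ∇ᵅf(x_best)), reference
  c = x_j − mean(r₁,r₂,r₃)(x_best − x_j), r_i ~ U[0,2], computed per nest
  (the reference depends on x_j).  The descent sign is the default; a
  `printed_sign` switch restores the "+" form of the update equations
  verbatim.
- Hybrid local walk: x_j − βs·H(p_a − v)·∇ᵅf(x_best) with the worst nest
  as reference; the gradient is shared across nests within a generation
  since the reference does not depend on j.
- ⊗ is the elementwise product throughout; bounds are enforced by clamping
  (simplest contract); non-finite fitness values are treated as +∞.

Defaults follow the standard protocol: population 50, 100 generations,
p_a = 0.25.  β defaults to 1% of the per-dimension box width and the local
scale s to 0.05 — conventional cuckoo-search scalings; greedy replacement
makes neither critical.

## Baselines

Classical gradient descent, SGDM (momentum 0.9), ADAM (0.9, 0.999, 10⁻⁸)
with bias correction, learning rate 10⁻⁴ by default.  Standalone fractional
descent iterates x ← x − η∇ᵅf(x) with the previous iterate as reference
(c⁰ = x⁰ − 10⁻²), so the memory window shrinks as iterates converge; a
fixed reference can be supplied.  Runs whose objective grows 10⁶-fold are
flagged as diverged and stopped.  CSA-ADAM mirrors the hybrid's skeleton
with the per-generation displacement supplied by an ADAM step on the
gradient at the best nest (finite differences, or backprop when available).

## Classifier head and training binding

Features → 1024 (ReLU) → 512 (ReLU) → sigmoid, binary cross-entropy with
probabilities clipped at 10⁻¹².  All parameters, including the output
layer, are flattened into one vector (the option to freeze the output layer
is deliberately not taken: nothing in the architecture motivates excluding
it from the search).  Population encoding: one nest = one flattened head;
search box [−0.5, 0.5] with Glorot-style per-layer initialization clipped
to the box.  One optimizer generation (or gradient step) per mini-batch;
the incumbent best is re-scored on every new batch before comparisons, so a
champion of a lucky batch cannot persist on a stale fitness.  Under a fixed
(full) batch this makes the incumbent's loss provably non-increasing, which
is the form the monotonicity test asserts; across changing mini-batches
monotonicity of the *selection* fitness is not a meaningful invariant.

For head training the global step uses β = 0.5 rather than the 1%-of-box
default: per-coordinate BCE gradients of the ~10⁶-parameter head are
O(10⁻³), so β must be O(1) for proposals to move at all; 0.5 keeps the
largest steps inside the box.  Training uses γ = 0 and the backprop
`grad_f` path.

The frozen backbone is a synthetic stand-in: eight fixed-seed random 5×5
RGB filters on a 56×56 downsample, ReLU, 7×7 average pooling to a
512-dimensional embedding.  It honors the frozen image→vector contract
(deterministic, fixed dimension) and nothing more; adapters accept real
pretrained extractors.  Input resizing follows the backbone contract:
224×224 (vgg16/googlenet/stand-in) or 256×256 (alexnet), bilinear.

## Synthetic corpus and augmentation

Each image: a textured circular fundus-like field (radial falloff,
low-frequency blotches, vessel-like random curves from an optic-disc-like
bright spot) plus one lesion with a harmonically perturbed polar boundary.
Benign: smooth border (irregularity 0.02–0.10), low contrast (0.10–0.28),
no satellites.  Malignant: irregular border (0.10–0.30), higher contrast
(0.22–0.50), 1–5 satellite blobs.  The ranges overlap by design; the
calibration target is that a cross-validated linear probe on stand-in
features lands in the 80–95% band — learnable but not trivially separable —
and the suite asserts exactly that.  Defaults: 200 images per class
(400 total), 128×128.

Augmentation samples uniformly from rotation ±30°, shifts ±0.1, shear
±0.2, zoom 0.8–1.2, optional horizontal/vertical flips, brightness
0.8–1.2; reflect padding at borders; output shape/dtype preserved and
clipped to the valid range.  Identity parameters short-circuit the warp, so
the all-identity draw returns the input bit-for-bit.  Augmentation is
applied on the fly, seeded, rather than pre-expanding the corpus.
A 70/30 stratified split utility is provided (class ratio preserved within
one image); k-fold orchestration beyond stratified splitting is out of
scope.

## Repeated-run statistics

Summaries use the sample (ddof = 1) standard deviation.  Rank sums use
average ranks on ties (repeated-run accuracies tie often).  Exact critical
values: the null distribution of the smaller group's rank sum is counted by
dynamic programming over all C(n₁+n₂, n₁) rank subsets (exact integer
arithmetic); the critical value is the largest w with P(W ≤ w) ≤ a/2, with
"≤" at the boundary — the convention of classic two-tailed tables, stated
because off-by-one conventions exist.  The decision rule rejects at 99%
when min(W₁, W₂) ≤ critical(0.01), else at 95% against critical(0.05),
else accepts.  This convention presumes the expected-weaker group is the
first and smaller one (whose rank sum the critical values bound) — the
orientation the comparison harness uses.  Both the rank-based t statistic
and a conventional two-sample t-test p-value are exposed, so either reading
of a "t-test" column is reproducible.  No multiple-testing correction is
applied across optimizer pairs, matching the protocol being reproduced.

The α-sweep harness runs a pipeline n times per order on a stable seed
fan-out (CRC32 of master seed, label and run index — reproducible across
machines and sessions) and records per-cell failures as NaN rather than
aborting.

## Problem sizes and presets

Two bundled presets: `paper` (population 50, 6 epochs × 400 iterations,
batch 32, 20 repeats, 200 images per class) mirrors the full protocol;
`desk` (population 10, 1 × 50, 3 repeats, 50 images per class) is the
scale at which the test suite and examples run.  Benchmark tests use
population 50 × 100 generations (sphere and Rosenbrock, 20 seeds); the
desk-scale pipeline check trains the head for 50 generations on the
100-image corpus, which reaches well above the 0.80 training-accuracy bar.

## Known limitations

- The joint-shift gradient path is exact only for separable objectives;
  for the head loss it is an approximation (consistent with treating the
  fractional gradient as a per-coordinate operator on a frozen batch).
- Clamping at the box boundary can park nests on faces of the box for
  flat objectives.
- The synthetic corpus has no pathology fidelity, no inter-patient
  variability, no acquisition artifacts; passing tests demonstrate
  optimizer behavior on a controlled, separable-but-overlapping task, not
  clinical performance.
- Exact critical values are practical for the small group sizes used in
  comparison tables (enumeration is polynomial but the table convention
  itself targets small n); large-sample comparisons should use the normal
  approximation the tests cross-check against.
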
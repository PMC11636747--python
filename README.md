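# csacfgd

Cuckoo search hybridized with Caputo fractional gradient descent (CSA-CFGD),
with everything needed to study it: the baseline optimizers it is compared
against, a frozen-backbone binary classifier head it can train, a synthetic
two-class fundus-image generator, and the repeated-run rank-sum comparison
machinery.

## The problem and the method

Training the classifier head of a transfer-learning model for ocular-tumor
fundus images is a high-dimensional, non-convex optimization.  Pure
gradient methods stall in local minima; pure population metaheuristics
explore well but converge slowly.  The hybrid implemented here embeds a
fractional-order gradient into cuckoo search.

The Caputo fractional derivative of order α ∈ (0, 1) of the coordinate
restriction f_i at x_i, taken from a lower terminal c_i, is evaluated in its
smoothed form

    (∇ᵅf)_i = c_α ∫₋₁¹ f′(Δ_i(1+u) + c_i) (1−u)^(−α) du
            + c_α γ |x_i − c_i| ∫₋₁¹ f″(Δ_i(1+u) + c_i) (1−u)^(−α) du,

with c_α = (1−α)·2^(−(1−α)) and Δ_i = (x_i − c_i)/2, so the substitution
maps the quadrature interval onto [c_i, x_i] and α → 1 recovers the
classical gradient.  The singular integrals are computed with a Gauss-Jacobi
rule whose weight function absorbs (1−u)^(−α).  Unlike other fractional
definitions, the Caputo derivative of a constant is zero, which is what
makes it usable as a descent direction.

Cuckoo search keeps a population of "nests" (candidate solutions),
proposing heavy-tailed Lévy-flight jumps globally and permuted-difference
walks locally, abandoning the worst fraction p_a each generation.  The
hybrid modulates the Lévy step elementwise by the fractional gradient at
the incumbent best nest — anchored at a randomized reference
c = x_j − mean(r₁,r₂,r₃)(x_best − x_j), r_i ~ U[0,2], in the global phase
and at the worst nest in the local phase — so proposals carry both
exploration noise and a worst-to-best descent pull with memory of the
interval between the anchors.

For optimizer comparisons, repeated seeded runs are summarized
(best/worst/mean/std) and compared pairwise with the Wilcoxon rank-sum
test using *exact* critical values (dynamic-programming enumeration of the
null distribution) and the rank-based statistic
t = (W₁ − μ)/SE, μ = n₁(n₁+n₂+1)/2, SE = √(n₁n₂(n₁+n₂+1)/12).

## Worked example

```bash
python examples/fractional_gradient.py
```

```
 alpha  fractional grad  closed form
 0.300         1.764706     1.764706
 0.500         2.000000     2.000000
 0.700         2.307692     2.307692
 0.900         2.727273     2.727273
 0.999         2.997003     2.997003

classical gradient at x=1.5 is 3.0; the alpha=0.999 row approaches it.
```

For f(x) = x² with lower terminal 0 the fractional gradient is exactly
2x/(2−α); the table shows the quadrature reproducing it and approaching the
classical gradient as α → 1.

```bash
python examples/optimize_benchmarks.py
```

```
seed 0: CSA 6.425e-04   CSA-CFGD 5.709e-07
seed 1: CSA 2.495e+00   CSA-CFGD 8.381e-02
seed 2: CSA 4.240e-04   CSA-CFGD 7.081e-02
seed 3: CSA 4.285e-02   CSA-CFGD 2.751e-02
seed 4: CSA 3.706e-02   CSA-CFGD 6.177e-03

medians: CSA 3.706e-02, CSA-CFGD 2.751e-02
```

Paired-seed final best fitness on the 2-D Rosenbrock valley under a shared
budget; the gradient-guided hybrid reaches the valley floor deeper.

Other examples: `train_synthetic.py` (head training on a generated corpus),
`rank_sum_tables.py` (exact critical values and a worked decision),
`generate_corpus.py` (corpus generation and augmentation).

A thin CLI wraps the same functions:

```bash
csacfgd generate-data --n-per-class 50 --out corpus/
csacfgd optimize --objective rosenbrock --dim 2 --optimizer csa-cfgd
csacfgd compare --preset desk --out results/
csacfgd sweep --alphas 0.3,0.5,0.7,0.9 --n-runs 3
```

## Scope

The corpus is synthetic: real ocular-tumor fundus photographs are not
redistributable, and the frozen feature extractor is a fixed random
projection standing in for a pretrained convolutional backbone (a plug-in
contract accepts real ones).  Accuracies obtained here therefore
characterize the optimizers on a controlled task, not clinical performance.
See `docs/methods.md` for the model, parameter and design details.
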
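"""Cuckoo search and its fractional-gradient hybrid.

Classic cuckoo search alternates heavy-tailed Levy-flight proposals (global
exploration) with local random walks over permuted population differences,
abandoning a fraction ``p_a`` of the worst nests each generation.  The hybrid
variant replaces the raw Levy step with a Levy-modulated Caputo fractional
gradient of the objective evaluated at the incumbent best nest, anchoring the
fractional integral at a randomized reference (global phase) or at the worst
nest (local phase), so the fractional "memory" pulls proposals from the worst
region toward the best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .fractional import (
    FractionalConfig,
    ReferencePoint,
    caputo_gradient,
)

__all__ = [
    "Nest",
    "CSAConfig",
    "OptimizerTrace",
    "sample_levy",
    "global_walk",
    "local_walk",
    "reference_global",
    "cfgd_global_walk",
    "cfgd_local_walk",
    "csa_optimize",
    "csa_cfgd_optimize",
]


@dataclass
class Nest:
    """One candidate solution with its (minimization) fitness."""

    position: np.ndarray
    fitness: float = math.inf


@dataclass
class CSAConfig:
    """Cuckoo-search hyperparameters.

    ``bounds`` is a sequence of per-dimension ``(low, high)`` pairs.  ``beta``
    defaults to 1% of the per-dimension box width and ``step_scale`` to 0.05
    -- conventional cuckoo-search scalings; neither is critical because
    greedy replacement filters bad proposals.
    """

    bounds: Sequence[tuple[float, float]] = ((-5.0, 5.0),)
    pop_size: int = 50
    p_a: float = 0.25
    beta: Optional[float] = None
    step_scale: float = 0.05
    levy_exponent: float = 2.5
    generations: int = 100
    seed: int = 0
    printed_sign: bool = False  # use the formulas' "+" instead of descent

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (0.0 <= self.p_a <= 1.0):
            raise ValueError("p_a must be in [0, 1]")
        if not (1.0 < self.levy_exponent <= 3.0):
            raise ValueError("levy_exponent must be in (1, 3]")
        b = np.asarray(self.bounds, dtype=float).reshape(-1, 2)
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("each bound must satisfy low < high")
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in b)

    @property
    def low(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)[:, 0]

    @property
    def high(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)[:, 1]

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def beta_vector(self) -> np.ndarray:
        if self.beta is not None:
            return np.full(self.dim, float(self.beta))
        return 0.01 * (self.high - self.low)

    @property
    def sign(self) -> float:
        return 1.0 if self.printed_sign else -1.0


@dataclass
class OptimizerTrace:
    """Per-generation incumbent record; best_fitness is non-increasing."""

    best_fitness: list = field(default_factory=list)
    best_position: list = field(default_factory=list)
    evaluations: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "evaluations": self.evaluations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _mantegna_sigma(stability: float) -> float:
    num = math.gamma(1.0 + stability) * math.sin(math.pi * stability / 2.0)
    den = (
        math.gamma((1.0 + stability) / 2.0)
        * stability
        * 2.0 ** ((stability - 1.0) / 2.0)
    )
    return (num / den) ** (1.0 / stability)


def sample_levy(levy_exponent: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step vector via Mantegna's algorithm.

    The survival function of |step| decays with tail index
    ``levy_exponent - 1`` (the stability index).  At the Gaussian edge
    ``levy_exponent = 3`` the construction degenerates and a standard normal
    is returned.
    """
    if not (1.0 < levy_exponent <= 3.0):
        raise ValueError(f"levy_exponent must be in (1, 3], got {levy_exponent}")
    stability = levy_exponent - 1.0
    if stability >= 2.0 - 1e-12:
        return rng.normal(size=dim)
    sigma = _mantegna_sigma(stability)
    u = rng.normal(0.0, sigma, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1.0 / stability)


def _clamp(x: np.ndarray, cfg: CSAConfig) -> np.ndarray:
    return np.clip(x, cfg.low, cfg.high)


def global_walk(x_j: np.ndarray, beta, levy: np.ndarray, cfg: CSAConfig) -> np.ndarray:
    """Levy-flight proposal x_j + beta * levy, clamped to the box."""
    x_j = np.asarray(x_j, dtype=float)
    levy = np.asarray(levy, dtype=float)
    if x_j.shape != levy.shape:
        raise ValueError("dimension mismatch between position and Levy step")
    return _clamp(x_j + beta * levy, cfg)


def local_walk(
    x_j: np.ndarray,
    x_p: np.ndarray,
    x_q: np.ndarray,
    cfg: CSAConfig,
    rng: np.random.Generator,
    v: Optional[float] = None,
) -> np.ndarray:
    """Local random walk over a permuted population difference.

    Moves by ``beta * s * H(p_a - v) * (x_p - x_q)`` with ``v ~ U[0, 1]``
    drawn per call; the Heaviside gate takes H(0) = 1 (tie goes to movement).
    """
    if v is None:
        v = float(rng.uniform())
    gate = 1.0 if (cfg.p_a - v) >= 0.0 else 0.0
    if gate == 0.0:
        return np.array(x_j, dtype=float)
    step = cfg.beta_vector() * cfg.step_scale * (np.asarray(x_p) - np.asarray(x_q))
    return _clamp(np.asarray(x_j, dtype=float) + step, cfg)


def reference_global(
    x_j: np.ndarray,
    x_best: np.ndarray,
    rng: np.random.Generator,
    r: Optional[np.ndarray] = None,
) -> ReferencePoint:
    """Randomized lower terminal for the global phase.

    Mean of three perturbed solutions ``x_j - r_i (x_best - x_j)`` with
    ``r_i ~ U[0, 2]``, i.e. ``c = x_j - mean(r) * (x_best - x_j)``.
    """
    if r is None:
        r = rng.uniform(0.0, 2.0, size=3)
    x_j = np.asarray(x_j, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    c = x_j - float(np.mean(np.asarray(r, dtype=float))) * (x_best - x_j)
    return ReferencePoint(c=c)


def cfgd_global_walk(
    x_j: np.ndarray,
    x_best: np.ndarray,
    f: Callable[[np.ndarray], float],
    cfg: CSAConfig,
    fcfg: FractionalConfig,
    rng: np.random.Generator,
    levy: Optional[np.ndarray] = None,
    reference: Optional[ReferencePoint] = None,
    grad_f: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Gradient-guided global proposal.

    ``x_j + sign * beta * (levy (*) g)`` where ``g`` is the Caputo fractional
    gradient of ``f`` at the incumbent best, anchored at the randomized
    reference of :func:`reference_global`.  The default sign is -1 (descent);
    ``cfg.printed_sign`` restores the formulas' "+".  ``levy`` and
    ``reference`` may be injected for reproducible single-step use.
    """
    x_j = np.asarray(x_j, dtype=float)
    if levy is None:
        levy = sample_levy(cfg.levy_exponent, x_j.size, rng)
    if reference is None:
        reference = reference_global(x_j, x_best, rng)
    est = caputo_gradient(
        f, np.asarray(x_best, dtype=float), reference, fcfg, grad_f=grad_f
    )
    step = cfg.sign * cfg.beta_vector() * (np.asarray(levy, dtype=float) * est.g)
    return _clamp(x_j + step, cfg)


def cfgd_local_walk(
    x_j: np.ndarray,
    x_best: np.ndarray,
    x_worst: np.ndarray,
    f: Callable[[np.ndarray], float],
    cfg: CSAConfig,
    fcfg: FractionalConfig,
    rng: np.random.Generator,
    v: Optional[float] = None,
    grad: Optional[np.ndarray] = None,
    grad_f: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Gradient-guided local proposal anchored at the worst nest.

    ``x_j + sign * beta * s * H(p_a - v) * g`` with the fractional gradient
    evaluated at the best nest and the worst nest as reference point, so the
    move points along the worst-to-best direction.  ``grad`` lets callers
    share one gradient across nests (the reference does not depend on j).
    """
    x_j = np.asarray(x_j, dtype=float)
    if v is None:
        v = float(rng.uniform())
    gate = 1.0 if (cfg.p_a - v) >= 0.0 else 0.0
    if gate == 0.0:
        return np.array(x_j)
    if grad is None:
        est = caputo_gradient(
            f,
            np.asarray(x_best, dtype=float),
            ReferencePoint(np.asarray(x_worst, dtype=float)),
            fcfg,
            grad_f=grad_f,
        )
        grad = est.g
    step = cfg.sign * cfg.beta_vector() * cfg.step_scale * grad
    return _clamp(x_j + step, cfg)


class _CountingObjective:
    """Wraps the raw objective: counts calls, maps non-finite values to +inf."""

    def __init__(self, f: Callable[[np.ndarray], float]):
        self._f = f
        self.count = 0

    def __call__(self, x: np.ndarray) -> float:
        self.count += 1
        val = float(self._f(x))
        if not math.isfinite(val):
            return math.inf
        return val


def _evolve(
    f: Callable[[np.ndarray], float],
    cfg: CSAConfig,
    propose_global: Callable,
    propose_local: Callable,
) -> tuple[Nest, OptimizerTrace]:
    """Shared engine for Levy-flight and gradient-guided cuckoo search.

    Per generation: one global proposal per nest compared greedily against a
    randomly chosen nest, then the ceil(p_a * n) worst nests are abandoned
    and rebuilt with the local walk, and the incumbent best is reinserted
    (elitism).  ``propose_local`` receives the live population through a
    per-generation state dict (permutations, worst nest, gradient cache).
    """
    rng = np.random.default_rng(cfg.seed)
    counted = _CountingObjective(f)
    n = cfg.pop_size
    pos = rng.uniform(cfg.low, cfg.high, size=(n, cfg.dim))
    fit = np.array([counted(x) for x in pos])

    best_idx = int(np.argmin(fit))
    best_x = pos[best_idx].copy()
    best_f = float(fit[best_idx])
    trace = OptimizerTrace()

    n_abandon = math.ceil(cfg.p_a * n)
    for _ in range(cfg.generations):
        for j in range(n):
            x_new = propose_global(pos[j], best_x, counted, rng)
            f_new = counted(x_new)
            l = int(rng.integers(n))
            if f_new < fit[l]:
                pos[l] = x_new
                fit[l] = f_new
                if f_new < best_f:
                    best_f, best_x = f_new, x_new.copy()

        if n_abandon > 0:
            worst_order = np.argsort(fit)[::-1][:n_abandon]
            state = {
                "pos": pos,
                "x_worst": pos[int(np.argmax(fit))].copy(),
                "perm1": rng.permutation(n),
                "perm2": rng.permutation(n),
                "grad_cache": None,
            }
            for j in worst_order:
                x_new = propose_local(pos[j], int(j), best_x, counted, rng, state)
                f_new = counted(x_new)
                pos[j] = x_new
                fit[j] = f_new
                if f_new < best_f:
                    best_f, best_x = f_new, x_new.copy()

        cur_best = int(np.argmin(fit))
        if fit[cur_best] > best_f:
            cur_worst = int(np.argmax(fit))
            pos[cur_worst] = best_x
            fit[cur_worst] = best_f

        trace.best_fitness.append(best_f)
        trace.best_position.append(best_x.copy())
        trace.evaluations.append(counted.count)

    if cfg.generations == 0:
        trace.best_fitness.append(best_f)
        trace.best_position.append(best_x.copy())
        trace.evaluations.append(counted.count)

    return Nest(position=best_x, fitness=best_f), trace


def csa_optimize(
    f: Callable[[np.ndarray], float], cfg: CSAConfig
) -> tuple[Nest, OptimizerTrace]:
    """Classic cuckoo search over a box-bounded objective (minimization)."""
    beta = cfg.beta_vector()

    def propose_global(x_j, x_best, counted, rng):
        levy = sample_levy(cfg.levy_exponent, cfg.dim, rng)
        return global_walk(x_j, beta, levy, cfg)

    def propose_local(x_j, j, x_best, counted, rng, state):
        p = int(state["perm1"][j])
        q = int(state["perm2"][j])
        return local_walk(x_j, state["pos"][p], state["pos"][q], cfg, rng)

    return _evolve(f, cfg, propose_global, propose_local)


def csa_cfgd_optimize(
    f: Callable[[np.ndarray], float],
    cfg: CSAConfig,
    fcfg: FractionalConfig,
    grad_f: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[Nest, OptimizerTrace]:
    """Hybrid cuckoo search with Caputo-fractional-gradient guidance.

    Same skeleton as :func:`csa_optimize`; the global Levy step is modulated
    elementwise by the fractional gradient at the incumbent best (randomized
    reference per nest), and abandoned nests are rebuilt by a gated step
    along the fractional gradient anchored at the worst nest (one gradient
    shared per generation, since that reference does not depend on the nest).
    """

    def propose_global(x_j, x_best, counted, rng):
        return cfgd_global_walk(x_j, x_best, counted, cfg, fcfg, rng, grad_f=grad_f)

    def propose_local(x_j, j, x_best, counted, rng, state):
        v = float(rng.uniform())
        if (cfg.p_a - v) < 0.0:
            return np.array(x_j)
        if state.get("grad_cache") is None:
            est = caputo_gradient(
                counted,
                np.asarray(x_best, dtype=float),
                ReferencePoint(np.asarray(state["x_worst"], dtype=float)),
                fcfg,
                grad_f=grad_f,
            )
            state["grad_cache"] = est.g
        return cfgd_local_walk(
            x_j, x_best, state["x_worst"], counted, cfg, fcfg, rng,
            v=v, grad=state["grad_cache"],
        )

    return _evolve(f, cfg, propose_global, propose_local)
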
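"""Baseline optimizers for the comparison harness.

Classical gradient descent, SGD with momentum, ADAM, the standalone Caputo
fractional gradient descent iteration, and a cuckoo-search/ADAM hybrid in
which the per-nest displacement direction comes from an ADAM step on the
finite-difference gradient at the incumbent best nest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .cuckoo import (
    CSAConfig,
    Nest,
    OptimizerTrace,
    _evolve,
    sample_levy,
)
from .fractional import FractionalConfig, ReferencePoint, caputo_gradient

__all__ = [
    "StepConfig",
    "SGDMState",
    "AdamState",
    "gd_step",
    "sgdm_step",
    "adam_step",
    "finite_difference_gradient",
    "cfgd_optimize",
    "csa_adam_optimize",
    "DescentTrace",
]


@dataclass(frozen=True)
class StepConfig:
    """First-order step hyperparameters (conventional defaults)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    iterations: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if not (0.0 < self.adam_beta1 < 1.0 and 0.0 < self.adam_beta2 < 1.0):
            raise ValueError("adam betas must be in (0, 1)")


@dataclass
class SGDMState:
    velocity: np.ndarray


@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0


def gd_step(x: np.ndarray, grad: np.ndarray, cfg: StepConfig) -> np.ndarray:
    """One plain gradient-descent update, x - eta * grad."""
    x = np.asarray(x, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if x.shape != grad.shape:
        raise ValueError("dimension mismatch between x and grad")
    return x - cfg.learning_rate * grad


def sgdm_step(
    state: Optional[SGDMState], grad: np.ndarray, cfg: StepConfig
) -> tuple[SGDMState, np.ndarray]:
    """Momentum update; returns (new state, displacement to add to x)."""
    grad = np.asarray(grad, dtype=float)
    if state is None:
        state = SGDMState(velocity=np.zeros_like(grad))
    velocity = cfg.momentum * state.velocity - cfg.learning_rate * grad
    return SGDMState(velocity=velocity), velocity


def adam_step(
    state: Optional[AdamState], grad: np.ndarray, cfg: StepConfig
) -> tuple[AdamState, np.ndarray]:
    """Bias-corrected ADAM update; returns (new state, displacement)."""
    grad = np.asarray(grad, dtype=float)
    if state is None:
        state = AdamState(m=np.zeros_like(grad), v=np.zeros_like(grad), t=0)
    t = state.t + 1
    m = cfg.adam_beta1 * state.m + (1.0 - cfg.adam_beta1) * grad
    v = cfg.adam_beta2 * state.v + (1.0 - cfg.adam_beta2) * grad * grad
    m_hat = m / (1.0 - cfg.adam_beta1**t)
    v_hat = v / (1.0 - cfg.adam_beta2**t)
    step = -cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)
    return AdamState(m=m, v=v, t=t), step


def finite_difference_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-6
) -> np.ndarray:
    """Central-difference classical gradient (plumbing for gradient-free objectives)."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    z = x.copy()
    for i in range(x.size):
        h = max(step, step * abs(x[i]))
        z[i] = x[i] + h
        fp = float(f(z))
        z[i] = x[i] - h
        fm = float(f(z))
        z[i] = x[i]
        g[i] = (fp - fm) / (2.0 * h)
    return g


@dataclass
class DescentTrace:
    """Iterate history of a sequential descent run."""

    x: list = field(default_factory=list)
    f: list = field(default_factory=list)
    diverged: bool = False

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(len(self.f)), "f": self.f}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cfgd_optimize(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    cfg: StepConfig,
    fcfg: FractionalConfig,
    reference: str | np.ndarray = "previous",
    grad_f: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> DescentTrace:
    """Standalone Caputo fractional gradient descent.

    Iterates ``x <- x - eta * grad_alpha f(x)``.  The lower terminal is the
    previous iterate by default (``c^0 = x^0 - 1e-2``), so the fractional
    memory window shrinks as the iterates converge; a fixed vector may be
    supplied instead.  If the objective grows by 1e6x over its starting
    value the run is flagged as diverged and stopped.
    """
    x = np.asarray(x0, dtype=float).copy()
    if isinstance(reference, str):
        if reference != "previous":
            raise ValueError(f"unknown reference policy {reference!r}")
        c = x - 1e-2
        previous_policy = True
    else:
        c = np.asarray(reference, dtype=float)
        previous_policy = False

    trace = DescentTrace()
    f0 = float(f(x))
    trace.x.append(x.copy())
    trace.f.append(f0)
    blowup = 1e6 * max(abs(f0), 1.0)
    for _ in range(cfg.iterations):
        est = caputo_gradient(f, x, ReferencePoint(c), fcfg, grad_f=grad_f)
        x_new = x - cfg.learning_rate * est.g
        f_new = float(f(x_new))
        if not math.isfinite(f_new) or abs(f_new) > blowup:
            trace.diverged = True
            warnings.warn(
                f"fractional descent diverged (f={f_new:.3g} from f0={f0:.3g}); "
                "stopping early",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        if previous_policy:
            c = x
        x = x_new
        trace.x.append(x.copy())
        trace.f.append(f_new)
    return trace


def csa_adam_optimize(
    f: Callable[[np.ndarray], float],
    cfg: CSAConfig,
    step: StepConfig,
    grad_f: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[Nest, OptimizerTrace]:
    """Cuckoo search whose displacement direction is an ADAM step at the best nest.

    Mirrors the fractional hybrid's skeleton: the global Levy step is
    modulated elementwise by the (shared, per-generation) ADAM displacement
    computed from the gradient at the incumbent best; abandoned nests move by
    the gated, step-scaled version of the same displacement.
    """
    adam_state: dict = {"state": None, "gen_cache": None, "global_calls": 0}

    def _direction(x_best, counted):
        grad = (
            np.asarray(grad_f(x_best), dtype=float)
            if grad_f is not None
            else finite_difference_gradient(counted, x_best)
        )
        new_state, disp = adam_step(adam_state["state"], grad, step)
        adam_state["state"] = new_state
        return disp

    def propose_global(x_j, x_best, counted, rng):
        # one ADAM update per generation, shared across nests; a generation
        # boundary is every pop_size-th global proposal
        if adam_state["global_calls"] % cfg.pop_size == 0:
            adam_state["gen_cache"] = _direction(x_best, counted)
        adam_state["global_calls"] += 1
        levy = sample_levy(cfg.levy_exponent, cfg.dim, rng)
        disp = adam_state["gen_cache"]
        # ADAM displacement already carries the descent sign and learning rate
        return np.clip(x_j + levy * disp, cfg.low, cfg.high)

    def propose_local(x_j, j, x_best, counted, rng, state):
        v = float(rng.uniform())
        if (cfg.p_a - v) < 0.0:
            return np.array(x_j)
        out = np.clip(x_j + cfg.step_scale * adam_state["gen_cache"], cfg.low, cfg.high)
        return out

    nest, trace = _evolve(f, cfg, propose_global, propose_local)
    return nest, trace
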
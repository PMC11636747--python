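"""Two-hidden-layer classifier head over a frozen feature extractor.

The backbone is a frozen image-to-vector mapping; only the head is trained:
two fully connected ReLU layers (1024 then 512 units) and a sigmoid output
for binary classification under binary cross-entropy.  The head's flattened
parameter vector is the search space for population optimizers (one nest =
one candidate head) and the iterate for gradient optimizers, so the same
pipeline compares SGDM, ADAM, plain and fractional descent, and the cuckoo
hybrids on identical footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import StepConfig, adam_step, sgdm_step
from .cuckoo import CSAConfig, sample_levy
from .fractional import FractionalConfig, ReferencePoint, caputo_gradient
from .synth import ImageSample, resize_for_model

__all__ = [
    "StandInExtractor",
    "HeadParameters",
    "TrainConfig",
    "extract_features",
    "head_forward",
    "bce_loss",
    "head_gradient",
    "train_head",
    "train_head_on_features",
    "evaluate_accuracy",
    "OPTIMIZERS",
]

HIDDEN_1 = 1024
HIDDEN_2 = 512

OPTIMIZERS = ("sgdm", "adam", "cfgd", "csa", "csa-adam", "csa-cfgd")


class StandInExtractor:
    """Frozen random-convolution feature extractor (synthetic backbone).

    A fixed-seed stack of 8 random 5x5 RGB filters applied to a downsampled
    56x56 view, ReLU, then 7x7 average pooling to an 8x8 grid, giving a
    deterministic 512-dimensional embedding.  It is a synthetic stand-in for
    a pretrained convolutional backbone: no claim of fidelity to any trained
    network, only the frozen image -> fixed-dimension contract.
    """

    feature_dim = 512
    input_size = 224
    name = "standin"

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.filters = rng.normal(0.0, 1.0, size=(8, 5, 5, 3))
        self.filters -= self.filters.mean(axis=(1, 2, 3), keepdims=True)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        from scipy.signal import fftconvolve

        img = resize_for_model(image, self.name).astype(float) / 255.0
        # cheap 4x downsample to 56x56 by block averaging
        img = img.reshape(56, 4, 56, 4, 3).mean(axis=(1, 3))
        maps = []
        for filt in self.filters:
            acc = np.zeros((56, 56))
            for ch in range(3):
                acc += fftconvolve(img[..., ch], filt[..., ch], mode="same")
            maps.append(np.maximum(acc, 0.0))
        stack = np.stack(maps, axis=-1)  # (56, 56, 8)
        pooled = stack.reshape(8, 7, 8, 7, 8).mean(axis=(1, 3))  # (8, 8, 8)
        return pooled.reshape(-1)


def extract_features(
    samples: Sequence[ImageSample], extractor
) -> tuple[np.ndarray, np.ndarray]:
    """Stack frozen features and labels for a corpus."""
    feats = np.stack([extractor(s.image) for s in samples])
    labels = np.array([s.label for s in samples], dtype=float)
    return feats, labels


@dataclass
class HeadParameters:
    """Weights and biases of the two hidden layers and the output unit."""

    W_fc1: np.ndarray  # (feature_dim, 1024)
    b_fc1: np.ndarray  # (1024,)
    W_fc2: np.ndarray  # (1024, 512)
    b_fc2: np.ndarray  # (512,)
    W_fc: np.ndarray  # (512,)
    b_fc: float

    @property
    def feature_dim(self) -> int:
        return self.W_fc1.shape[0]

    @staticmethod
    def param_count(feature_dim: int) -> int:
        return feature_dim * HIDDEN_1 + HIDDEN_1 + HIDDEN_1 * HIDDEN_2 + HIDDEN_2 + HIDDEN_2 + 1

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [
                self.W_fc1.ravel(),
                self.b_fc1,
                self.W_fc2.ravel(),
                self.b_fc2,
                self.W_fc,
                [self.b_fc],
            ]
        )

    @classmethod
    def unflatten(cls, vec: np.ndarray, feature_dim: int) -> "HeadParameters":
        expected = cls.param_count(feature_dim)
        vec = np.asarray(vec, dtype=float)
        if vec.size != expected:
            raise ValueError(f"expected {expected} parameters, got {vec.size}")
        sizes = [
            feature_dim * HIDDEN_1,
            HIDDEN_1,
            HIDDEN_1 * HIDDEN_2,
            HIDDEN_2,
            HIDDEN_2,
            1,
        ]
        parts = np.split(vec, np.cumsum(sizes)[:-1])
        return cls(
            W_fc1=parts[0].reshape(feature_dim, HIDDEN_1),
            b_fc1=parts[1],
            W_fc2=parts[2].reshape(HIDDEN_1, HIDDEN_2),
            b_fc2=parts[3],
            W_fc=parts[4],
            b_fc=float(parts[5][0]),
        )

    @classmethod
    def init_glorot(
        cls, feature_dim: int, rng: np.random.Generator, box: float = 0.5
    ) -> "HeadParameters":
        """Glorot-uniform layer init, clipped into the search box [-box, box]."""

        def layer(fan_in, fan_out, shape):
            limit = min(math.sqrt(6.0 / (fan_in + fan_out)), box)
            return rng.uniform(-limit, limit, size=shape)

        return cls(
            W_fc1=layer(feature_dim, HIDDEN_1, (feature_dim, HIDDEN_1)),
            b_fc1=np.zeros(HIDDEN_1),
            W_fc2=layer(HIDDEN_1, HIDDEN_2, (HIDDEN_1, HIDDEN_2)),
            b_fc2=np.zeros(HIDDEN_2),
            W_fc=layer(HIDDEN_2, 1, (HIDDEN_2,)),
            b_fc=0.0,
        )

    def save_npz(self, path) -> None:
        np.savez(
            path,
            W_fc1=self.W_fc1,
            b_fc1=self.b_fc1,
            W_fc2=self.W_fc2,
            b_fc2=self.b_fc2,
            W_fc=self.W_fc,
            b_fc=np.array([self.b_fc]),
        )

    @classmethod
    def load_npz(cls, path) -> "HeadParameters":
        data = np.load(path)
        return cls(
            W_fc1=data["W_fc1"],
            b_fc1=data["b_fc1"],
            W_fc2=data["W_fc2"],
            b_fc2=data["b_fc2"],
            W_fc=data["W_fc"],
            b_fc=float(data["b_fc"][0]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def head_forward(features: np.ndarray, params: HeadParameters) -> np.ndarray:
    """ReLU -> ReLU -> sigmoid forward pass; accepts (d,) or (n, d)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != params.feature_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match head ({params.feature_dim})"
        )
    h1 = np.maximum(X @ params.W_fc1 + params.b_fc1, 0.0)
    h2 = np.maximum(h1 @ params.W_fc2 + params.b_fc2, 0.0)
    z = h2 @ params.W_fc + params.b_fc
    p = _sigmoid(z)
    return p if np.asarray(features).ndim > 1 else float(p[0])


BCE_EPS = 1e-12


def bce_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping at 1e-12."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("label/probability length mismatch")
    p = np.clip(yhat, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def head_gradient(
    X: np.ndarray, y: np.ndarray, theta: np.ndarray, feature_dim: int
) -> np.ndarray:
    """Backprop gradient of the batch BCE with respect to the flattened head."""
    params = HeadParameters.unflatten(theta, feature_dim)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]

    z1 = X @ params.W_fc1 + params.b_fc1
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ params.W_fc2 + params.b_fc2
    h2 = np.maximum(z2, 0.0)
    z3 = h2 @ params.W_fc + params.b_fc
    p = _sigmoid(z3)

    dz3 = (p - y) / n  # (n,)
    dW3 = h2.T @ dz3
    db3 = float(np.sum(dz3))
    dh2 = np.outer(dz3, params.W_fc)
    dz2 = dh2 * (z2 > 0)
    dW2 = h1.T @ dz2
    db2 = dz2.sum(axis=0)
    dh1 = dz2 @ params.W_fc2.T
    dz1 = dh1 * (z1 > 0)
    dW1 = X.T @ dz1
    db1 = dz1.sum(axis=0)

    return np.concatenate(
        [dW1.ravel(), db1, dW2.ravel(), db2, dW3, [db3]]
    )


@dataclass(frozen=True)
class TrainConfig:
    """Training budget and optimizer selection.

    Defaults mirror the full-scale protocol (learning rate 1e-4, 6 epochs of
    400 iterations, batch 32).  Desk-scale experiments shrink epochs and
    iterations, not the architecture.
    """

    learning_rate: float = 1e-4
    epochs: int = 6
    iterations_per_epoch: int = 400
    batch_size: int = 32
    optimizer: str = "csa-cfgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.iterations_per_epoch < 0:
            raise ValueError("epochs and iterations_per_epoch must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; expected one of {OPTIMIZERS}"
            )


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-9] = 1.0
    return (X - mu) / sd


def train_head_on_features(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    csa_cfg: Optional[CSAConfig] = None,
    fcfg: Optional[FractionalConfig] = None,
    step_cfg: Optional[StepConfig] = None,
    standardize: bool = True,
) -> tuple[HeadParameters, pd.DataFrame]:
    """Train the head on precomputed features with the selected optimizer.

    Population optimizers advance one generation per mini-batch, with the
    incumbent best re-scored on every new batch before comparisons (so a
    lucky-batch champion cannot survive on a stale fitness).  Gradient
    optimizers take one step per mini-batch.  Returns the best parameters
    and a per-epoch history of training loss and accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if cfg.batch_size > X.shape[0]:
        raise ValueError("batch_size exceeds dataset size")
    if standardize:
        X = _standardize(X)
    d_feat = X.shape[1]
    dim = HeadParameters.param_count(d_feat)
    rng = np.random.default_rng(cfg.seed)

    fcfg = fcfg or FractionalConfig(gamma=0.0)
    step_cfg = step_cfg or StepConfig(learning_rate=cfg.learning_rate)

    def batch_iter():
        while True:
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0] - cfg.batch_size + 1, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                yield X[idx], y[idx]

    batches = batch_iter()
    total_iters = cfg.epochs * cfg.iterations_per_epoch
    history_rows = []

    def full_metrics(theta):
        p = head_forward(X, HeadParameters.unflatten(theta, d_feat))
        return bce_loss(y, p), float(np.mean((p >= 0.5) == (y == 1)))

    if cfg.optimizer in ("sgdm", "adam", "cfgd"):
        theta = HeadParameters.init_glorot(d_feat, rng).flatten()
        state = None
        prev_theta = theta - 1e-2
        it = 0
        for epoch in range(cfg.epochs):
            for _ in range(cfg.iterations_per_epoch):
                Xb, yb = next(batches)
                if cfg.optimizer == "cfgd":
                    est = caputo_gradient(
                        lambda t: bce_loss(
                            yb, head_forward(Xb, HeadParameters.unflatten(t, d_feat))
                        ),
                        theta,
                        ReferencePoint(prev_theta),
                        fcfg,
                        grad_f=lambda t: head_gradient(Xb, yb, t, d_feat),
                    )
                    prev_theta = theta
                    theta = theta - step_cfg.learning_rate * est.g
                else:
                    grad = head_gradient(Xb, yb, theta, d_feat)
                    if cfg.optimizer == "sgdm":
                        state, disp = sgdm_step(state, grad, step_cfg)
                    else:
                        state, disp = adam_step(state, grad, step_cfg)
                    theta = theta + disp
                it += 1
            loss, acc = full_metrics(theta)
            history_rows.append(
                {"epoch": epoch, "iteration": it, "train_loss": loss, "train_acc": acc}
            )
        best_theta = theta
    else:
        csa_cfg = csa_cfg or CSAConfig(
            bounds=[(-0.5, 0.5)], pop_size=10, generations=total_iters, seed=cfg.seed
        )
        low, high = csa_cfg.bounds[0]
        beta = (
            float(csa_cfg.beta)
            if csa_cfg.beta is not None
            else 0.01 * (high - low)
        )
        n_pop = csa_cfg.pop_size
        pop = np.stack(
            [HeadParameters.init_glorot(d_feat, rng).flatten() for _ in range(n_pop)]
        )
        np.clip(pop, low, high, out=pop)

        def batch_loss(theta, Xb, yb):
            return bce_loss(
                yb, head_forward(Xb, HeadParameters.unflatten(theta, d_feat))
            )

        adam_state = None
        n_abandon = math.ceil(csa_cfg.p_a * n_pop)
        it = 0
        best_theta = pop[0].copy()
        for epoch in range(cfg.epochs):
            for _ in range(cfg.iterations_per_epoch):
                Xb, yb = next(batches)
                fit = np.array([batch_loss(t, Xb, yb) for t in pop])
                best_idx = int(np.argmin(fit))
                best_theta = pop[best_idx].copy()
                best_fit = float(fit[best_idx])
                grad_cb = lambda t: head_gradient(Xb, yb, t, d_feat)

                if cfg.optimizer == "csa-adam":
                    adam_state, shared_disp = adam_step(
                        adam_state, grad_cb(best_theta), step_cfg
                    )
                elif cfg.optimizer == "csa-cfgd":
                    shared_disp = None  # per-nest reference, computed below

                # global phase: one proposal per nest, greedy vs random nest
                for j in range(n_pop):
                    levy = sample_levy(csa_cfg.levy_exponent, dim, rng)
                    if cfg.optimizer == "csa":
                        x_new = np.clip(pop[j] + beta * levy, low, high)
                    elif cfg.optimizer == "csa-adam":
                        x_new = np.clip(pop[j] + levy * shared_disp, low, high)
                    else:  # csa-cfgd
                        r = rng.uniform(0.0, 2.0, size=3)
                        c = pop[j] - float(np.mean(r)) * (best_theta - pop[j])
                        est = caputo_gradient(
                            lambda t: batch_loss(t, Xb, yb),
                            best_theta,
                            ReferencePoint(c),
                            fcfg,
                            grad_f=grad_cb,
                        )
                        x_new = np.clip(
                            pop[j] + csa_cfg.sign * beta * (levy * est.g), low, high
                        )
                    f_new = batch_loss(x_new, Xb, yb)
                    l = int(rng.integers(n_pop))
                    if f_new < fit[l]:
                        pop[l] = x_new
                        fit[l] = f_new
                        if f_new < best_fit:
                            best_fit, best_theta = f_new, x_new.copy()

                # abandonment: rebuild the worst fraction
                if n_abandon > 0:
                    worst_order = np.argsort(fit)[::-1][:n_abandon]
                    x_worst = pop[int(np.argmax(fit))].copy()
                    perm1, perm2 = rng.permutation(n_pop), rng.permutation(n_pop)
                    local_grad = None
                    for j in worst_order:
                        v = float(rng.uniform())
                        if (csa_cfg.p_a - v) < 0.0:
                            continue
                        if cfg.optimizer == "csa":
                            step = beta * csa_cfg.step_scale * (
                                pop[int(perm1[j])] - pop[int(perm2[j])]
                            )
                        elif cfg.optimizer == "csa-adam":
                            step = csa_cfg.step_scale * shared_disp
                        else:
                            if local_grad is None:
                                est = caputo_gradient(
                                    lambda t: batch_loss(t, Xb, yb),
                                    best_theta,
                                    ReferencePoint(x_worst),
                                    fcfg,
                                    grad_f=grad_cb,
                                )
                                local_grad = est.g
                            step = csa_cfg.sign * beta * csa_cfg.step_scale * local_grad
                        x_new = np.clip(pop[j] + step, low, high)
                        f_new = batch_loss(x_new, Xb, yb)
                        pop[j] = x_new
                        fit[j] = f_new
                        if f_new < best_fit:
                            best_fit, best_theta = f_new, x_new.copy()

                # elitism: incumbent survives into the next generation
                cur_worst = int(np.argmax(fit))
                if best_fit < fit[cur_worst]:
                    pop[cur_worst] = best_theta.copy()
                    fit[cur_worst] = best_fit
                it += 1
            loss, acc = full_metrics(best_theta)
            history_rows.append(
                {"epoch": epoch, "iteration": it, "train_loss": loss, "train_acc": acc}
            )

    params = HeadParameters.unflatten(best_theta, d_feat)
    history = pd.DataFrame(history_rows)
    return params, history


def train_head(
    samples: Sequence[ImageSample],
    extractor,
    cfg: TrainConfig,
    csa_cfg: Optional[CSAConfig] = None,
    fcfg: Optional[FractionalConfig] = None,
    step_cfg: Optional[StepConfig] = None,
) -> tuple[HeadParameters, pd.DataFrame]:
    """Extract frozen features once, then train the head on them."""
    X, y = extract_features(samples, extractor)
    return train_head_on_features(
        X, y, cfg, csa_cfg=csa_cfg, fcfg=fcfg, step_cfg=step_cfg
    )


def evaluate_accuracy(
    features: np.ndarray, labels: np.ndarray, params: HeadParameters
) -> float:
    """Fraction of correct predictions at threshold 0.5 (>= goes to class 1)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    p = head_forward(X, params)
    return float(np.mean((p >= 0.5) == (y == 1)))


def evaluate_accuracy_on_samples(
    samples: Sequence[ImageSample], extractor, params: HeadParameters,
    standardize_with: Optional[np.ndarray] = None,
) -> float:
    X, y = extract_features(samples, extractor)
    if standardize_with is not None:
        mu = standardize_with.mean(axis=0)
        sd = standardize_with.std(axis=0)
        sd[sd < 1e-9] = 1.0
        X = (X - mu) / sd
    else:
        X = _standardize(X)
    return evaluate_accuracy(X, y, params)
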
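"""Repeated-run comparison statistics.

Summary metrics over repeated training runs, the Wilcoxon rank-sum test with
exact critical values obtained by dynamic-programming enumeration of the null
distribution, the rank-based t statistic ``t = (W1 - mu) / SE`` with
``mu = n1 (n1 + n2 + 1) / 2`` and ``SE = sqrt(n1 n2 (n1 + n2 + 1) / 12)``,
and the fractional-order sweep harness that averages accuracy over repeated
seeded runs per order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RunRecord",
    "RankSumResult",
    "TStatResult",
    "Summary",
    "summarize",
    "rank_sums",
    "exact_critical_value",
    "rank_t_statistic",
    "decide",
    "ttest_pvalue",
    "alpha_sweep",
]


@dataclass(frozen=True)
class RunRecord:
    """One repeated-run outcome (final accuracy of one seeded training run)."""

    optimizer: str
    model: str
    seed: int
    accuracy: float
    trace: Optional[object] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"accuracy must be in [0, 1], got {self.accuracy}")


@dataclass
class RankSumResult:
    """Rank sums of two pooled groups with exact two-sided critical values."""

    W1: float
    W2: float
    n1: int
    n2: int
    critical_05: Optional[int] = None
    critical_01: Optional[int] = None
    decision: Optional[str] = None
    confidence_level: Optional[float] = None


@dataclass(frozen=True)
class TStatResult:
    """Rank-based t statistic with its null mean and standard error."""

    t: float
    mu: float
    se: float


@dataclass(frozen=True)
class Summary:
    best: float
    worst: float
    mean: float
    std: float


def summarize(accuracies: Sequence[float]) -> Summary:
    """Best / worst / mean / sample standard deviation (ddof=1) of run accuracies."""
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    std = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return Summary(
        best=float(np.max(a)), worst=float(np.min(a)), mean=float(np.mean(a)), std=std
    )


def rank_sums(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Pooled rank sums with average-rank tie handling.

    ``W1`` is the sum of the ranks of ``group_a``.  The exact two-sided
    critical values at 0.05 and 0.01 for the smaller group's rank sum are
    attached when they exist.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]), method="average")
    w1 = float(np.sum(ranks[: a.size]))
    w2 = float(np.sum(ranks[a.size :]))
    n_small, n_large = sorted((a.size, b.size))
    return RankSumResult(
        W1=w1,
        W2=w2,
        n1=a.size,
        n2=b.size,
        critical_05=exact_critical_value(n_small, n_large, 0.05),
        critical_01=exact_critical_value(n_small, n_large, 0.01),
    )


@lru_cache(maxsize=None)
def _rank_sum_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of size-n1 subsets of ranks 1..n1+n2 per rank-sum value.

    Dynamic programme over ranks: counts[s] after processing rank r is the
    number of subsets of {1..r} of each size with sum s; only the size-n1
    layer is returned, indexed from sum 0.
    """
    n = n1 + n2
    max_sum = n1 * n + 1  # loose upper bound on achievable sums
    # layers[k][s] = number of k-subsets with rank sum s
    layers = [np.zeros(max_sum, dtype=object) for _ in range(n1 + 1)]
    layers[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            src = layers[k - 1]
            dst = layers[k]
            dst[r:] = dst[r:] + src[:-r] if r > 0 else dst
    return tuple(int(v) for v in layers[n1])


def exact_critical_value(
    n1: int, n2: int, alpha_two_sided: float
) -> Optional[int]:
    """Exact lower critical value of the rank sum of the smaller group.

    Largest integer w with ``P(W <= w) <= alpha_two_sided / 2`` under the
    exact null (all C(n1+n2, n1) rank subsets equally likely), enumerated by
    dynamic programming.  Returns ``None`` when even the minimal rank sum has
    tail probability above the threshold.  Requires ``1 <= n1 <= n2``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    if n1 > n2:
        raise ValueError("call with n1 <= n2 (the smaller group's rank sum)")
    counts = _rank_sum_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    threshold = alpha_two_sided / 2.0
    cum = 0
    best: Optional[int] = None
    min_sum = n1 * (n1 + 1) // 2
    max_sum = n1 * (2 * n2 + n1 + 1) // 2
    for w in range(min_sum, max_sum + 1):
        cum += counts[w]
        if cum / total <= threshold:
            best = w
        else:
            break
    return best


def rank_t_statistic(W1: float, n1: int, n2: int) -> TStatResult:
    """Rank-based t statistic of the first group's rank sum.

    ``mu = n1 (n1 + n2 + 1) / 2`` and
    ``SE = sqrt(n1 n2 (n1 + n2 + 1) / 12)``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    mu = n1 * (n1 + n2 + 1) / 2.0
    se = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return TStatResult(t=(W1 - mu) / se, mu=mu, se=se)


def decide(result: RankSumResult) -> RankSumResult:
    """Two-sided decision on a rank-sum result.

    Reject at 99% confidence when ``min(W1, W2) <= critical(0.01)``, else at
    95% when ``<= critical(0.05)``, else accept; the boundary counts as a
    rejection.  Returns the result with decision fields filled in.
    """
    if result.critical_05 is None and result.critical_01 is None:
        raise ValueError("no critical values available for these group sizes")
    w_min = min(result.W1, result.W2)
    if result.critical_01 is not None and w_min <= result.critical_01:
        result.decision, result.confidence_level = "reject", 0.99
    elif result.critical_05 is not None and w_min <= result.critical_05:
        result.decision, result.confidence_level = "reject", 0.95
    else:
        result.decision, result.confidence_level = "accept", None
    return result


def ttest_pvalue(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Conventional two-sample t-test p-value (equal-variance), for the
    p-value reading of the parametric column in comparison tables."""
    res = sps.ttest_ind(np.asarray(group_a, float), np.asarray(group_b, float))
    return float(res.pvalue)


def alpha_sweep(
    pipeline: Callable[[float, int], float],
    alphas: Sequence[float],
    n_runs: int,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy per fractional order over repeated seeded runs.

    ``pipeline(alpha, seed) -> accuracy`` is invoked ``n_runs`` times per
    order with distinct, stable seeds.  Per-cell failures are recorded as NaN
    rather than aborting the sweep.  Returns a tidy frame with one row per
    (alpha, run) plus a ``mean_accuracy`` column repeated per order.
    """
    rows = []
    for alpha in alphas:
        if not (0.0 < alpha <= 1.0):
            raise ValueError(f"alpha grid values must be in (0, 1], got {alpha}")
        accs = []
        for run in range(n_runs):
            seed = _fanout_seed(base_seed, f"alpha={alpha!r}", run)
            try:
                acc = float(pipeline(alpha, seed))
            except Exception as exc:  # recorded, not fatal
                rows.append(
                    {
                        "alpha": alpha,
                        "run": run,
                        "seed": seed,
                        "accuracy": math.nan,
                        "error": repr(exc),
                    }
                )
                continue
            accs.append(acc)
            rows.append(
                {"alpha": alpha, "run": run, "seed": seed, "accuracy": acc, "error": ""}
            )
        mean = float(np.mean(accs)) if accs else math.nan
        for row in rows:
            if row["alpha"] == alpha:
                row["mean_accuracy"] = mean
    return pd.DataFrame(rows)


def _fanout_seed(master: int, label: str, index: int) -> int:
    """Stable per-run seed from (master seed, label, run index)."""
    import zlib

    return zlib.crc32(f"{master}:{label}:{index}".encode()) & 0x7FFFFFFF
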
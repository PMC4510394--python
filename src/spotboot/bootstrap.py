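"""Bootstrap of the mean for 2-DE spot volumes.

For each (spot, group) the observed replicate volumes are resampled with
replacement ``B`` times (default 2000); the bias-corrected (BC) percentile
method then turns the empirical distribution of the ``B`` bootstrap means
into nonparametric confidence intervals, and the deviation of the
below-mean proportion from 50% gives a bootstrap bias statistic for the
sampling distribution of the mean.

The BC correction uses only the proportion ``p`` of bootstrap means that
fall strictly below the observed mean: ``z0 = Phi^{-1}(p)`` shifts the
percentile points to ``Phi(2*z0 -/+ z)``.  No acceleration constant is
estimated (BC, not BCa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .rng import MinimalStandardRNG

__all__ = [
    "DEFAULT_B",
    "DEFAULT_LEVELS",
    "BootstrapSummary",
    "bootstrap_means",
    "below_mean_proportion",
    "bc_percentile_ci",
    "bias_statistic",
    "summarize_group",
]

DEFAULT_B = 2000
DEFAULT_LEVELS = (0.95, 0.99)


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicate values in a group."""


@dataclass
class BootstrapSummary:
    """Per-(spot, group) bootstrap results.

    ``bias_pct`` is ``|100*p - 50|`` in percentage points, or ``None``
    (reported as N/A) for a spot absent from the group, i.e. all
    replicate volumes exactly zero.  ``degenerate`` flags a bootstrap
    distribution collapsed onto a single value, for which every interval
    is the point interval.
    """

    observed_mean: float
    se: float
    boot_means: np.ndarray
    p_below: float
    z0: float
    ci: dict[float, tuple[float, float]]
    bias_pct: float | None
    B: int
    degenerate: bool = False
    spot_id: str | None = None
    group: str | None = None
    n: int = field(default=0)


def bootstrap_means(
    values, B: int = DEFAULT_B, rng: MinimalStandardRNG | None = None
) -> np.ndarray:
    """``B`` bootstrap replications of the sample mean.

    Each replication averages ``N`` values picked with replacement via
    the minimal-standard generator; exactly ``B*N`` generator steps are
    consumed.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        raise InsufficientReplicatesError(
            f"need at least 2 replicates to bootstrap, got {n}"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = MinimalStandardRNG(1)
    idx = rng.sample_indices(n, B * n).reshape(B, n)
    return values[idx].mean(axis=1)


def below_mean_proportion(
    boot_means, observed_mean: float, tie_rule: str = "strict"
) -> float:
    """Proportion of bootstrap means below the observed mean.

    ``tie_rule='strict'`` counts strictly smaller replications only;
    ``'midrank'`` adds half of the exactly-equal ones.
    """
    boot_means = np.asarray(boot_means, dtype=np.float64)
    B = boot_means.size
    below = int(np.count_nonzero(boot_means < observed_mean))
    if tie_rule == "strict":
        return below / B
    if tie_rule == "midrank":
        equal = int(np.count_nonzero(boot_means == observed_mean))
        return (below + 0.5 * equal) / B
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


def _nearest_rank(sorted_means: np.ndarray, q: float) -> float:
    """Nearest-rank order statistic: the ceil(q*B)-th smallest value.

    The small epsilon keeps analytically integer ranks (e.g. q = 0.005
    at B = 2000) from being pushed up a rank by floating-point round-off
    in q itself.
    """
    B = sorted_means.size
    rank = math.ceil(q * B - 1e-9)
    rank = min(max(rank, 1), B)
    return float(sorted_means[rank - 1])


def bc_percentile_ci(
    boot_means,
    observed_mean: float,
    level: float,
    tie_rule: str = "strict",
) -> tuple[float, float]:
    """Bias-corrected percentile confidence interval for the mean.

    With ``p`` the (clamped) below-mean proportion, ``z0 = Phi^{-1}(p)``
    and ``z = Phi^{-1}(1 - alpha/2)``, the interval endpoints are the
    empirical quantiles of the bootstrap means at ``Phi(2*z0 - z)`` and
    ``Phi(2*z0 + z)``, each taken as the nearest-rank (ceil(q*B)) order
    statistic.  A degenerate bootstrap distribution (all replications
    identical) yields the point interval.
    """
    boot_means = np.asarray(boot_means, dtype=np.float64)
    B = boot_means.size
    if B < 2:
        raise ValueError("need at least 2 bootstrap replications")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if np.all(boot_means == boot_means[0]):
        v = float(boot_means[0])
        return (v, v)
    p = below_mean_proportion(boot_means, observed_mean, tie_rule)
    p = min(max(p, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = float(norm.ppf(p))
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    q_lo = float(norm.cdf(2.0 * z0 - z))
    q_hi = float(norm.cdf(2.0 * z0 + z))
    sorted_means = np.sort(boot_means)
    return _nearest_rank(sorted_means, q_lo), _nearest_rank(sorted_means, q_hi)


def bias_statistic(
    boot_means, observed_mean: float, values, tie_rule: str = "strict"
) -> float | None:
    """Bootstrap bias statistic ``|100*p - 50|`` in percentage points.

    ``p`` is the proportion of bootstrap mean replications below the
    observed mean; for an unbiased (symmetric) sampling distribution the
    expectation of ``p`` is 50%, so the statistic measures skew of the
    empirical distribution of the mean and is bounded by 50.  Returns
    ``None`` (N/A) when the spot is absent from the group, i.e. every
    replicate volume is exactly zero.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.all(values == 0.0):
        return None
    p = below_mean_proportion(boot_means, observed_mean, tie_rule)
    return abs(100.0 * p - 50.0)


def summarize_group(
    values,
    B: int = DEFAULT_B,
    levels=DEFAULT_LEVELS,
    rng: MinimalStandardRNG | None = None,
    tie_rule: str = "strict",
    spot_id: str | None = None,
    group: str | None = None,
) -> BootstrapSummary:
    """Full bootstrap summary for one group of replicate volumes.

    ``se`` is the conventional standard error of the mean, sample
    standard deviation (ddof=1) over ``sqrt(N)``.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    observed_mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n))
    boot = bootstrap_means(values, B=B, rng=rng)
    degenerate = bool(np.all(boot == boot[0]))
    p = below_mean_proportion(boot, observed_mean, tie_rule)
    p_clamped = min(max(p, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = float(norm.ppf(p_clamped))
    ci = {
        float(level): bc_percentile_ci(boot, observed_mean, level, tie_rule)
        for level in levels
    }
    bias = bias_statistic(boot, observed_mean, values, tie_rule)
    return BootstrapSummary(
        observed_mean=observed_mean,
        se=se,
        boot_means=boot,
        p_below=p,
        z0=z0,
        ci=ci,
        bias_pct=bias,
        B=int(B),
        degenerate=degenerate,
        spot_id=spot_id,
        group=group,
        n=n,
    )
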
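"""Classical two-sample baselines and the bootstrap significance rule.

The bootstrap pipeline declares a spot differentially abundant when the
two groups' bias-corrected percentile intervals at the matched confidence
level are disjoint (a shared endpoint counts as overlap — the
conservative choice).  An alternative rule bootstraps the difference of
group means directly and rejects when the BC interval for the difference
excludes zero.

For comparison, the pooled-variance Student t-test and the Mann–Whitney
U-test are provided.  The Mann–Whitney p-value is computed by exact
enumeration of all C(N+M, N) group assignments (midrank ties) for
N+M <= 12 — the regime of small proteomics experiments — and by the
normal approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .bootstrap import BootstrapSummary, bc_percentile_ci
from .rng import MinimalStandardRNG

__all__ = [
    "DifferentialCall",
    "ci_overlap_call",
    "diff_ci_call",
    "t_test",
    "mann_whitney_u",
    "EXACT_ENUM_LIMIT",
]

EXACT_ENUM_LIMIT = 12  # exact enumeration when N + M is at most this


@dataclass
class DifferentialCall:
    spot_id: str
    significant: dict[float, bool]
    method: str
    t_p: float | None
    mw_p: float | None
    degenerate_t: bool = False


def ci_overlap_call(
    summary_ref: BootstrapSummary, summary_trt: BootstrapSummary, level: float
) -> bool:
    """Significant iff the groups' CIs at ``level`` are disjoint."""
    level = float(level)
    for s in (summary_ref, summary_trt):
        if level not in s.ci:
            raise KeyError(f"confidence level {level} missing from summary")
    lo_r, hi_r = summary_ref.ci[level]
    lo_t, hi_t = summary_trt.ci[level]
    return hi_r < lo_t or hi_t < lo_r


def diff_ci_call(
    values_ref,
    values_trt,
    level: float,
    B: int,
    rng: MinimalStandardRNG,
    tie_rule: str = "strict",
) -> bool:
    """Bootstrap-of-differences rule: reject iff the BC interval for the
    difference of group means (treatment minus reference) excludes zero.

    Both groups are resampled independently in each replication;
    consumes exactly ``B * (N + M)`` generator steps.
    """
    ref = np.asarray(values_ref, dtype=np.float64)
    trt = np.asarray(values_trt, dtype=np.float64)
    n, m = ref.size, trt.size
    idx_r = rng.sample_indices(n, B * n).reshape(B, n)
    idx_t = rng.sample_indices(m, B * m).reshape(B, m)
    diffs = trt[idx_t].mean(axis=1) - ref[idx_r].mean(axis=1)
    observed = float(trt.mean() - ref.mean())
    lo, hi = bc_percentile_ci(diffs, observed, level, tie_rule)
    return lo > 0.0 or hi < 0.0


def t_test(values_ref, values_trt, variant: str = "pooled") -> tuple[float, bool]:
    """Two-sided two-sample t-test p-value.

    Default is the pooled-variance Student test; ``variant='welch'``
    drops the equal-variance assumption.  Returns ``(p, degenerate)``:
    when both groups have zero variance the statistic is undefined, and
    p is 1 for equal means or 0 for different means, with the degenerate
    flag set in the latter case.
    """
    ref = np.asarray(values_ref, dtype=np.float64)
    trt = np.asarray(values_trt, dtype=np.float64)
    if ref.size < 2 or trt.size < 2:
        raise ValueError("each group needs at least 2 values")
    if ref.std(ddof=1) == 0.0 and trt.std(ddof=1) == 0.0:
        if ref.mean() == trt.mean():
            return 1.0, False
        return 0.0, True
    if variant == "pooled":
        res = stats.ttest_ind(ref, trt, equal_var=True)
    elif variant == "welch":
        res = stats.ttest_ind(ref, trt, equal_var=False)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return float(res.pvalue), False


def _u_statistic_from_ranks(ranks_ref: np.ndarray, n_ref: int, n_trt: int) -> float:
    # U for the reference group from its midrank sum
    return float(ranks_ref.sum() - n_ref * (n_ref + 1) / 2.0)


def mann_whitney_u(values_ref, values_trt) -> float:
    """Two-sided Mann–Whitney U-test p-value.

    Exact for N+M <= 12: enumerate every assignment of the pooled
    midranks to the reference group and count assignments whose U
    deviates from the null mean N*M/2 at least as much as the observed U
    (the enumeration distribution is symmetric about that mean, with or
    without ties).  Larger samples use the normal approximation with tie
    and continuity corrections.
    """
    ref = np.asarray(values_ref, dtype=np.float64)
    trt = np.asarray(values_trt, dtype=np.float64)
    n, m = ref.size, trt.size
    if n < 2 or m < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([ref, trt])
    ranks = stats.rankdata(pooled)  # midranks for ties
    mu = n * m / 2.0
    u_obs = _u_statistic_from_ranks(ranks[:n], n, m)
    dev_obs = abs(u_obs - mu)
    if n + m <= EXACT_ENUM_LIMIT:
        total = 0
        extreme = 0
        const = n * (n + 1) / 2.0
        for pick in combinations(range(n + m), n):
            u = ranks[list(pick)].sum() - const
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        return extreme / total
    # normal approximation with tie correction + continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = ((counts**3 - counts).sum()) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * ((nm + 1) - tie_term)
    if sigma2 == 0.0:
        return 1.0
    z = (dev_obs - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))
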
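"""Synthetic 2-DE spot-volume generation and benchmarking.

Real spot-volume data at small replicate numbers are non-negative, often
right-skewed and zero-inflated (a protein can be entirely undetectable in
one group).  The generator emulates exactly that: volumes are drawn from
a normal, lognormal or gamma family via inverse-CDF transforms of the
minimal-standard LCG uniforms, and an optional group-wise dropout turns
all replicates of a (spot, group) to zero, producing qualitative
presence/absence changes.  Every draw flows through the one LCG stream,
so a scenario plus a seed reproduces a dataset exactly.

The benchmark harness runs the bootstrap CI-overlap decision, the pooled
t-test and the Mann–Whitney U-test on each simulated spot and aggregates
rejection rates (type-I error under a null scenario, power under an
alternative), 95% CI coverage of the true group mean, and the mean
bootstrap bias statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import DEFAULT_B, summarize_group
from .classical import ci_overlap_call, mann_whitney_u, t_test
from .io import GroupMeanFixture, SpotVolumeTable
from .rng import MinimalStandardRNG

__all__ = [
    "SimulationScenario",
    "ScenarioRates",
    "BenchmarkResult",
    "draw_family",
    "generate_dataset",
    "run_benchmark",
    "evaluate_scenario",
    "replicate_table1_regime",
]

_FAMILIES = ("normal", "lognormal", "gamma")


@dataclass
class SimulationScenario:
    """Generative description of a synthetic 2-DE experiment.

    ``params_ref``/``params_trt`` are per-family dicts: normal uses
    ``mean``/``sd``, lognormal the log-scale ``mu``/``sigma``, gamma
    ``shape``/``scale``.  ``dropout_prob`` is the probability that a
    (spot, group) is entirely absent (all replicates zero) — a scalar
    applied to both groups or a ``(ref, trt)`` pair; dropout is
    group-wise, matching the presence/absence notion of 2-DE, not
    per-replicate.  ``n`` defaults to 4 replicates per group, the typical
    size of small gel studies.
    """

    family: str
    params_ref: dict
    params_trt: dict
    n: int = 4
    dropout_prob: float | tuple[float, float] = 0.0
    n_spots: int = 100
    n_datasets: int = 1
    seed: int = 1
    group_labels: tuple[str, str] = ("C", "DFD")

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.n < 2:
            raise ValueError("n (replicates per group) must be >= 2")
        probs = self.dropout_probs
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("dropout_prob entries must be in [0, 1]")
        if self.n_spots < 1 or self.n_datasets < 1:
            raise ValueError("n_spots and n_datasets must be >= 1")
        for params in (self.params_ref, self.params_trt):
            _validate_params(self.family, params)

    @property
    def dropout_probs(self) -> tuple[float, float]:
        """Per-group (reference, treatment) dropout probabilities."""
        if isinstance(self.dropout_prob, (tuple, list)):
            if len(self.dropout_prob) != 2:
                raise ValueError("dropout_prob pair must have exactly two entries")
            return float(self.dropout_prob[0]), float(self.dropout_prob[1])
        return float(self.dropout_prob), float(self.dropout_prob)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_labels"] = list(self.group_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        if "group_labels" in d:
            d["group_labels"] = tuple(d["group_labels"])
        return cls(**d)

    def true_mean(self, params: dict) -> float:
        """Population mean of the family (before dropout)."""
        if self.family == "normal":
            return float(params["mean"])
        if self.family == "lognormal":
            return float(math.exp(params["mu"] + params["sigma"] ** 2 / 2.0))
        return float(params["shape"] * params["scale"])


def _validate_params(family: str, params: dict) -> None:
    try:
        if family == "normal":
            if params["sd"] < 0:
                raise ValueError("normal sd must be >= 0")
        elif family == "lognormal":
            if params["sigma"] < 0:
                raise ValueError("lognormal sigma must be >= 0")
        elif family == "gamma":
            if params["shape"] <= 0 or params["scale"] <= 0:
                raise ValueError("gamma shape and scale must be > 0")
    except KeyError as exc:
        raise ValueError(f"{family} parameters missing key {exc}") from None


def draw_family(family: str, params: dict, k: int, rng: MinimalStandardRNG) -> np.ndarray:
    """``k`` deviates from the family by inverse-CDF transform of LCG
    uniforms; consumes exactly ``k`` generator steps.

    Inverse-CDF (rather than rejection or Box–Muller) keeps the uniform
    consumption fixed per draw, which is what makes interleaved streams
    reproducible.  Normal draws are clipped at zero so every volume is
    non-negative; with the means and spreads used for volume data the
    clipped mass is negligible.
    """
    _validate_params(family, params)
    u = rng.uniforms(k)
    if family == "normal":
        vals = params["mean"] + params["sd"] * stats.norm.ppf(u)
        return np.maximum(vals, 0.0)
    if family == "lognormal":
        return np.exp(params["mu"] + params["sigma"] * stats.norm.ppf(u))
    return stats.gamma.ppf(u, a=params["shape"], scale=params["scale"])


def generate_dataset(scenario: SimulationScenario, rng: MinimalStandardRNG) -> SpotVolumeTable:
    """One synthetic dataset: n_spots spots x 2 groups x N replicates.

    Per (spot, group), in input order and reference group first: when
    ``dropout_prob > 0`` one uniform decides dropout, then (if present)
    ``N`` uniforms become volumes.
    """
    ref, trt = scenario.group_labels
    p_ref, p_trt = scenario.dropout_probs
    records = []
    for i in range(scenario.n_spots):
        spot_id = f"S{i + 1:04d}"
        for group, params, p_drop in (
            (ref, scenario.params_ref, p_ref),
            (trt, scenario.params_trt, p_trt),
        ):
            if p_drop > 0.0 and rng.uniform() < p_drop:
                values = np.zeros(scenario.n)
            else:
                values = draw_family(scenario.family, params, scenario.n, rng)
            for j, v in enumerate(values):
                records.append((spot_id, "", group, f"r{j + 1}", float(v)))
    df = pd.DataFrame(records, columns=["spot_id", "protein", "group", "replicate", "volume"])
    return SpotVolumeTable(data=df, group_labels=scenario.group_labels)


@dataclass
class ScenarioRates:
    """Aggregated benchmark metrics for one scenario."""

    rejection: dict[str, float]
    coverage95: float | None
    mean_bias: float
    n_tests: int


@dataclass
class BenchmarkResult:
    null: ScenarioRates
    alt: ScenarioRates | None = None
    config: dict = field(default_factory=dict)


def evaluate_scenario(
    scenario: SimulationScenario,
    rng: MinimalStandardRNG,
    B: int = DEFAULT_B,
    alpha: float = 0.05,
    tie_rule: str = "midrank",
) -> ScenarioRates:
    """Run the three tests on every simulated spot of every dataset.

    Rejection rates are at significance ``alpha`` (the bootstrap decision
    uses disjointness of the two 1-alpha BC intervals).  Coverage is the
    fraction of per-group 95% intervals containing the family's true
    mean, reported only for scenarios without dropout.  The mean bias
    averages the bootstrap bias statistic over all (spot, group) pairs
    where it is defined.

    The bias diagnostic defaults to the midrank tie rule here, unlike
    per-spot reporting: for continuous volume distributions the bootstrap
    mean has an atom exactly at the observed mean (mass N!/N^N, about
    9.4% at N=4), and the strict rule assigns all of it to "not below",
    adding a constant offset of roughly 4.7 points for any symmetric
    distribution that would swamp the skewness signal this benchmark is
    meant to measure.  Splitting ties (midrank) removes the offset, so
    the aggregate statistic reflects distribution shape alone.
    """
    level = 1.0 - alpha
    ref, trt = scenario.group_labels
    rejections = {"bootstrap": 0, "t": 0, "mw": 0}
    n_tests = 0
    cover = 0
    n_cover = 0
    bias_sum = 0.0
    n_bias = 0
    truth = {ref: scenario.true_mean(scenario.params_ref),
             trt: scenario.true_mean(scenario.params_trt)}
    for _ in range(scenario.n_datasets):
        table = generate_dataset(scenario, rng)
        for spot_id in table.spot_ids:
            vals = {g: table.group_values(spot_id, g) for g in (ref, trt)}
            summaries = {}
            for g in (ref, trt):
                s = summarize_group(vals[g], B=B, levels=(level,), rng=rng,
                                    tie_rule=tie_rule)
                summaries[g] = s
                if s.bias_pct is not None:
                    bias_sum += s.bias_pct
                    n_bias += 1
                if max(scenario.dropout_probs) == 0.0:
                    lo, hi = s.ci[level]
                    cover += int(lo <= truth[g] <= hi)
                    n_cover += 1
            n_tests += 1
            if ci_overlap_call(summaries[ref], summaries[trt], level):
                rejections["bootstrap"] += 1
            t_p, _ = t_test(vals[ref], vals[trt])
            if t_p < alpha:
                rejections["t"] += 1
            if mann_whitney_u(vals[ref], vals[trt]) < alpha:
                rejections["mw"] += 1
    return ScenarioRates(
        rejection={k: v / n_tests for k, v in rejections.items()},
        coverage95=(cover / n_cover) if n_cover else None,
        mean_bias=bias_sum / n_bias if n_bias else math.nan,
        n_tests=n_tests,
    )


def run_benchmark(
    scenario_null: SimulationScenario,
    scenario_alt: SimulationScenario | None = None,
    B: int = DEFAULT_B,
    alpha: float = 0.05,
    seed: int | None = None,
    tie_rule: str = "midrank",
) -> BenchmarkResult:
    """Benchmark the bootstrap decision against t and Mann–Whitney.

    The null scenario yields type-I error rates, the (optional)
    alternative scenario power.  Both scenarios must share N and
    n_spots so the comparison is like for like.
    """
    if scenario_alt is not None and (
        scenario_alt.n != scenario_null.n or scenario_alt.n_spots != scenario_null.n_spots
    ):
        raise ValueError("null and alternative scenarios must share n and n_spots")
    rng = MinimalStandardRNG(seed if seed is not None else scenario_null.seed)
    null_rates = evaluate_scenario(scenario_null, rng, B=B, alpha=alpha, tie_rule=tie_rule)
    alt_rates = None
    if scenario_alt is not None:
        alt_rates = evaluate_scenario(scenario_alt, rng, B=B, alpha=alpha, tie_rule=tie_rule)
    return BenchmarkResult(
        null=null_rates,
        alt=alt_rates,
        config={
            "B": B,
            "alpha": alpha,
            "seed": seed if seed is not None else scenario_null.seed,
            "tie_rule": tie_rule,
        },
    )


def replicate_table1_regime(
    fixture: GroupMeanFixture,
    rng: MinimalStandardRNG,
    n: int = 4,
    group_labels: tuple[str, str] = ("C", "DFD"),
) -> SpotVolumeTable:
    """Synthetic replicate volumes moment-matched to the reference fixture.

    For each (spot, group) with printed mean m and standard error se, N
    replicates are drawn from a gamma distribution with mean m and
    standard deviation se*sqrt(N) (shape = (m/sd)^2, scale = sd^2/m) —
    gamma because volumes are non-negative and right-skewed.  A zero mean
    yields N exact zeros (the spot is absent from the group); a zero mean
    with a nonzero SE is a fixture inconsistency.
    """
    ref, trt = group_labels
    records = []
    for row in fixture:
        for group, mean, se in (
            (ref, row.mean_control, row.se_control),
            (trt, row.mean_dfd, row.se_dfd),
        ):
            if mean == 0.0:
                if se not in (None, 0.0):
                    raise ValueError(
                        f"fixture inconsistency for {row.spot_id}/{group}: "
                        "zero mean with nonzero SE"
                    )
                values = np.zeros(n)
            else:
                sd = (se or 0.0) * math.sqrt(n)
                if sd == 0.0:
                    values = np.full(n, mean)
                else:
                    shape = (mean / sd) ** 2
                    scale = sd**2 / mean
                    values = draw_family("gamma", {"shape": shape, "scale": scale}, n, rng)
            for j, v in enumerate(values):
                records.append((row.spot_id, row.spot_id, group, f"r{j + 1}", float(v)))
    df = pd.DataFrame(records, columns=["spot_id", "protein", "group", "replicate", "volume"])
    return SpotVolumeTable(data=df, group_labels=group_labels)
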
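"""Multi-parameter sensitivity analysis (MPSA).

A Monte Carlo filtering procedure over rate constants:

1. select the rate constants to assess;
2. set each one's range as (lo, hi) multiples of its nominal value
   (default 1/4x to 4x);
3. draw Latin hypercube samples from the box, uniform per coordinate;
4. score each sample with an error against the nominal model — either the
   mean squared error of one species' ODE trajectory, or the absolute
   difference of an expected-reward model-checking query;
5. classify samples as acceptable (error strictly below the median) or
   unacceptable;
6. per parameter, compare the ECDFs of acceptable vs unacceptable sample
   values with two indices: the two-sample Kolmogorov-Smirnov statistic
   and one minus the Pearson correlation of the two ECDFs evaluated on
   the pooled value grid.

Larger index = more sensitive parameter; the result carries one ranking
per index.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .ctmc import (
    RewardSpec,
    TargetPredicate,
    enumerate_states,
    expected_reward_to_target,
    limiting_amount,
)
from .network import ReactionNetwork, set_parameters
from .ode import IntegrationError, Trajectory, simulate, trajectory_mse

__all__ = [
    "SampleFailure",
    "MPSAError",
    "OdeMseBackend",
    "PmcRewardBackend",
    "MPSAConfig",
    "MPSAResult",
    "lhs_sample",
    "sample_error_ode",
    "sample_error_pmc",
    "classify",
    "ecdf",
    "ks_statistic",
    "pmcc_index",
    "run_mpsa",
]


class SampleFailure(RuntimeError):
    """A parameter sample could not be scored (solver failure, infinite reward)."""


class MPSAError(RuntimeError):
    """The analysis as a whole is invalid (too many failures, degenerate errors)."""


# -- sampling ------------------------------------------------------------


def lhs_sample(
    n: int, ranges: Sequence[tuple[float, float]], seed: int
) -> np.ndarray:
    """Latin hypercube sample, shape (n, len(ranges)).

    Per parameter, exactly one value falls in each of the n equal-width
    strata of its (lo, hi) range; strata are paired across parameters by
    seeded permutations and positions within a stratum are uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for lo, hi in ranges:
        if not (lo < hi):
            raise ValueError(f"invalid range ({lo}, {hi}): need lo < hi")
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    unit = sampler.random(n)
    lows = np.array([lo for lo, _ in ranges])
    highs = np.array([hi for _, hi in ranges])
    return qmc.scale(unit, lows, highs)


# -- error backends ------------------------------------------------------


@dataclass(frozen=True)
class OdeMseBackend:
    """Error = MSE of one species' ODE trajectory vs the nominal model."""

    species: str = "P"
    t_end: float = 30.0
    n_points: int = 300

    def reference(self, net: ReactionNetwork) -> Trajectory:
        return simulate(net, self.t_end, self.n_points)

    def error(
        self, net: ReactionNetwork, sample: Mapping[str, float], reference: Trajectory
    ) -> float:
        return sample_error_ode(
            net, sample, reference, self.species, self.t_end, self.n_points
        )


@dataclass(frozen=True)
class PmcRewardBackend:
    """Error = |expected-reward query on the sample - nominal value|.

    The query counts firings of ``counted_reaction`` until ``species``
    reaches half of its limiting amount; the target threshold is fixed
    once from the nominal model (rate changes do not move the limit).
    """

    counted_reaction: str = "r1"
    species: str = "P"
    strict: bool = False
    cap: int = 1_000_000

    def query(self, net: ReactionNetwork) -> tuple[RewardSpec, TargetPredicate]:
        limit = limiting_amount(enumerate_states(net, self.cap), self.species)
        thr = math.floor(0.5 * limit) + 1 if self.strict else math.ceil(0.5 * limit)
        return RewardSpec(self.counted_reaction), TargetPredicate(self.species, ">=", thr)

    def reference(self, net: ReactionNetwork) -> tuple[float, RewardSpec, TargetPredicate]:
        reward, target = self.query(net)
        value = expected_reward_to_target(enumerate_states(net, self.cap), reward, target)
        if not math.isfinite(value):
            raise MPSAError("nominal model has infinite expected reward")
        return value, reward, target

    def error(
        self,
        net: ReactionNetwork,
        sample: Mapping[str, float],
        reference: tuple[float, RewardSpec, TargetPredicate],
    ) -> float:
        value, reward, target = reference
        return sample_error_pmc(net, sample, value, reward, target, self.cap)


def sample_error_ode(
    net: ReactionNetwork,
    sample: Mapping[str, float],
    reference: Trajectory,
    species: str = "P",
    t_end: float = 30.0,
    n_points: int = 300,
) -> float:
    """Trajectory-MSE error of one parameter sample against the reference."""
    try:
        traj = simulate(set_parameters(net, sample), t_end, n_points)
    except IntegrationError as exc:
        raise SampleFailure(f"integration failed for sample {dict(sample)}: {exc}") from exc
    return trajectory_mse(traj, reference, species)


def sample_error_pmc(
    net: ReactionNetwork,
    sample: Mapping[str, float],
    reference_value: float,
    reward: RewardSpec,
    target: TargetPredicate,
    cap: int = 1_000_000,
) -> float:
    """Absolute expected-reward difference of one sample vs the reference."""
    space = enumerate_states(set_parameters(net, sample), cap)
    value = expected_reward_to_target(space, reward, target)
    if not math.isfinite(value):
        raise SampleFailure(
            f"sample {dict(sample)}: target reached with probability < 1 "
            "(infinite expected reward)"
        )
    return abs(value - reference_value)


# -- classification and indices ------------------------------------------


def classify(errors: np.ndarray, rule: str = "median") -> np.ndarray:
    """Boolean acceptability: error strictly below the rule's threshold.

    With the median rule and an even number of distinct errors this
    splits the samples exactly in half.  All-identical errors make the
    classification degenerate and raise :class:`MPSAError`.
    """
    if rule != "median":
        raise ValueError(f"unknown classification rule {rule!r}")
    errors = np.asarray(errors, dtype=float)
    if len(errors) < 2 or not np.all(np.isfinite(errors)):
        raise ValueError("need at least 2 finite errors")
    if np.all(errors == errors[0]):
        raise MPSAError("all sample errors are identical; classification is degenerate")
    return errors < np.median(errors)


def ecdf(values: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Right-continuous empirical CDF, F(t) = #(values <= t) / n."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("ecdf of empty sample")

    def f(t):
        return np.searchsorted(v, t, side="right") / len(v)

    return f


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov statistic, sup |F_a - F_b|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ks_statistic of empty sample")
    return float(stats.ks_2samp(a, b).statistic)


def pmcc_index(a: Sequence[float], b: Sequence[float]) -> float:
    """1 - Pearson correlation of the two ECDFs on the pooled value grid.

    0 for identical distributions, up to 2 for perfectly anti-correlated
    ECDF shapes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grid = np.unique(np.concatenate([a, b]))
    fa = ecdf(a)(grid)
    fb = ecdf(b)(grid)
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        raise ValueError("degenerate ECDF (zero variance on the pooled grid)")
    r = stats.pearsonr(fa, fb).statistic
    return float(1.0 - r)


# -- the full procedure ---------------------------------------------------


@dataclass(frozen=True)
class MPSAConfig:
    """Configuration of one MPSA run.

    ``parameters`` are reaction labels whose rate constants are varied;
    each ranges over nominal * [range_factors[0], range_factors[1]],
    sampled uniformly on the linear scale (``log_scale=True`` switches to
    log-uniform).
    """

    parameters: tuple[str, ...]
    range_factors: tuple[float, float] = (0.25, 4.0)
    n_samples: int = 400
    seed: int = 0
    backend: OdeMseBackend | PmcRewardBackend = field(default_factory=OdeMseBackend)
    threshold_rule: str = "median"
    log_scale: bool = False
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("parameters must be non-empty")
        lo, hi = self.range_factors
        if not (0 < lo < hi):
            raise ValueError("range_factors must satisfy 0 < lo < hi")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class MPSAResult:
    """Samples, errors, classification and per-parameter sensitivity indices."""

    parameters: tuple[str, ...]
    samples: np.ndarray  # (n_samples, n_parameters)
    errors: np.ndarray  # nan where the sample failed
    acceptable: np.ndarray  # bool; False where failed
    failed: np.ndarray  # indices of failed samples
    indices: dict[str, dict[str, float]]  # parameter -> {"ks": .., "pmcc": ..}
    rankings: dict[str, list[str]]  # index name -> parameters, most sensitive first
    config: MPSAConfig

    def to_dict(self) -> dict:
        """JSON-ready summary (config echo, seed, indices, rankings, failures)."""
        cfg = self.config
        return {
            "parameters": list(self.parameters),
            "range_factors": list(cfg.range_factors),
            "n_samples": int(cfg.n_samples),
            "seed": int(cfg.seed),
            "backend": type(cfg.backend).__name__,
            "threshold_rule": cfg.threshold_rule,
            "log_scale": bool(cfg.log_scale),
            "n_failed": int(len(self.failed)),
            "indices": {
                p: {k: float(v) for k, v in d.items()} for p, d in self.indices.items()
            },
            "rankings": {k: list(v) for k, v in self.rankings.items()},
        }


def run_mpsa(net: ReactionNetwork, config: MPSAConfig) -> MPSAResult:
    """Execute the six-step MPSA procedure on a network.

    Failed samples (solver failure or infinite reward) are excluded from
    classification and indices and counted; more than
    ``max_failure_fraction`` of them aborts with :class:`MPSAError`.
    """
    nominal = net.rate_constants()
    for p in config.parameters:
        if p not in nominal:
            raise KeyError(f"unknown reaction label {p!r}")
    lo, hi = config.range_factors
    if config.log_scale:
        ranges = [(math.log(nominal[p] * lo), math.log(nominal[p] * hi)) for p in config.parameters]
        samples = np.exp(lhs_sample(config.n_samples, ranges, config.seed))
    else:
        ranges = [(nominal[p] * lo, nominal[p] * hi) for p in config.parameters]
        samples = lhs_sample(config.n_samples, ranges, config.seed)

    reference = config.backend.reference(net)
    errors = np.full(config.n_samples, np.nan)
    failures: list[int] = []
    for i in range(config.n_samples):
        assignment = dict(zip(config.parameters, samples[i]))
        try:
            errors[i] = config.backend.error(net, assignment, reference)
        except SampleFailure:
            failures.append(i)
    if len(failures) > config.max_failure_fraction * config.n_samples:
        raise MPSAError(
            f"{len(failures)} of {config.n_samples} samples failed "
            f"(> {config.max_failure_fraction:.0%}); aborting"
        )

    ok = np.isfinite(errors)
    acceptable = np.zeros(config.n_samples, dtype=bool)
    acceptable[ok] = classify(errors[ok], config.threshold_rule)

    indices: dict[str, dict[str, float]] = {}
    for j, p in enumerate(config.parameters):
        acc = samples[ok & acceptable, j]
        unacc = samples[ok & ~acceptable, j]
        indices[p] = {
            "ks": ks_statistic(acc, unacc),
            "pmcc": pmcc_index(acc, unacc),
        }
    rankings = {
        name: sorted(config.parameters, key=lambda p: (-indices[p][name], p))
        for name in ("ks", "pmcc")
    }
    return MPSAResult(
        parameters=config.parameters,
        samples=samples,
        errors=errors,
        acceptable=acceptable,
        failed=np.array(failures, dtype=int),
        indices=indices,
        rankings=rankings,
        config=config,
    )
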
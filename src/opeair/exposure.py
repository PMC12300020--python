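"""Monte Carlo estimation of daily inhalation intake (EDI).

The inhaled dose rate of a congener for a person in one microenvironment is

    EDI = C x IR x IEF / BW        [ng/kg bw/day]

with C the air concentration (ng/m^3), IR the respiration rate (m^3/day),
IEF the fraction of the day spent in that microenvironment, and BW body
weight (kg); absorption is a multiplicative fraction (default 1, i.e. all
inhaled mass absorbed).  Across microenvironments the contributions add,
with a single (IR, BW) pair per simulated person shared across environments
and congeners — respiration and weight belong to the person, not the
pollutant.

Uncertainty is propagated by Monte Carlo: per trial, IR and BW are drawn
from the age group's distributions and C per environment is drawn either by
resampling measured site concentrations (after non-detect substitution) or
from a lognormal fitted to them.  A total-OPE distribution is formed by
summing congener draws within each trial, preserving distributional
coherence (its mean is generally not the sum of the per-congener summary
means rounded separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .censored import substitute_values
from .registry import Registry
from .synthetic import fit_lognormal_from_mean_median

__all__ = [
    "Dist",
    "PopulationGroup",
    "ExposureDistribution",
    "MonteCarloResult",
    "edi_point",
    "multi_env_edi",
    "run_monte_carlo",
    "summarize_distribution",
]

GROUP_NAMES = ("infant", "toddler", "child", "adolescent", "adult")
C_SAMPLING_MODES = ("empirical", "lognormal")


@dataclass(frozen=True)
class Dist:
    """Scalar input distribution for IR or BW.

    ``point`` is a degenerate constant; ``normal`` is truncated at zero
    (body weights and breathing rates are strictly positive); ``lognormal``
    interprets (mean, sd) as the arithmetic moments.
    """

    kind: str  # point | normal | lognormal
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "normal", "lognormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point" or self.sd == 0.0:
            return np.full(n, self.mean)
        if self.kind == "normal":
            a = (0.0 - self.mean) / self.sd  # truncate at zero
            return sps.truncnorm.rvs(
                a, np.inf, loc=self.mean, scale=self.sd, size=n, random_state=rng
            )
        cv2 = (self.sd / self.mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(self.mean) - sigma**2 / 2.0
        return rng.lognormal(mu, sigma, n)


@dataclass(frozen=True)
class PopulationGroup:
    """An age class: IR/BW distributions, time-fraction per microenvironment
    (IEF) and an inhalation absorption fraction."""

    name: str
    ir: Dist
    bw: Dist
    ief: Mapping[str, float]
    absorption: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.absorption <= 1.0:
            raise ValueError("absorption must be in (0, 1]")
        for env, f in self.ief.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"ief[{env!r}] must be in [0, 1]")
        if sum(self.ief.values()) > 1.0 + 1e-9:
            raise ValueError("ief fractions must sum to at most 1")

    @property
    def active_envs(self) -> list[str]:
        return [e for e, f in self.ief.items() if f > 0]


@dataclass
class ExposureDistribution:
    """Monte Carlo EDI draws for one (group, congener)."""

    group: str
    congener: str
    draws: np.ndarray  # ng/kg/day

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.draws, q))


@dataclass
class MonteCarloResult:
    """All per-(group, congener) distributions plus, per group, the raw
    input-factor draws needed for sensitivity analysis."""

    distributions: list[ExposureDistribution]
    input_draws: dict[str, dict[str, np.ndarray]]  # group -> factor -> draws
    n_trials: int
    seed: int
    c_sampling: str

    def get(self, group: str, congener: str) -> ExposureDistribution:
        for d in self.distributions:
            if d.group == group and d.congener == congener:
                return d
        raise KeyError((group, congener))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([summarize_distribution(d) for d in self.distributions])


def edi_point(
    c: float, ir: float, ief: float, bw: float, absorption: float = 1.0
) -> float:
    """Closed-form single-environment EDI (ng/kg/day)."""
    if bw <= 0:
        raise ValueError("body weight must be positive")
    if not 0.0 <= ief <= 1.0:
        raise ValueError("ief must be in [0, 1]")
    return c * ir * ief / bw * absorption


def multi_env_edi(
    c_by_env: Mapping[str, float],
    group: PopulationGroup,
    ir: float | None = None,
    bw: float | None = None,
) -> float:
    """EDI summed over the group's microenvironments at fixed IR/BW
    (defaults: the distribution means)."""
    ir = group.ir.mean if ir is None else ir
    bw = group.bw.mean if bw is None else bw
    total = 0.0
    for env in group.active_envs:
        if env not in c_by_env:
            raise ValueError(f"missing concentration for microenvironment {env!r}")
        total += edi_point(c_by_env[env], ir, group.ief[env], bw, group.absorption)
    return total


def _concentration_pools(
    table: pd.DataFrame,
    congeners: Sequence[str],
    envs: Sequence[str],
    registry: Registry,
    policy: str,
) -> dict[tuple[str, str], np.ndarray]:
    pools: dict[tuple[str, str], np.ndarray] = {}
    for env in envs:
        env_sel = table[table["microenvironment"] == env]
        for name in congeners:
            grp = env_sel[env_sel["congener"] == name]
            if grp.empty:
                continue
            pools[(env, name)] = substitute_values(
                grp["value_ng_m3"].to_numpy(),
                grp["censor"].to_numpy(),
                registry[name].mdl,
                policy,
            )
    return pools


def _sample_concentration(
    pool: np.ndarray, mode: str, rng: np.random.Generator, n: int
) -> np.ndarray:
    if mode == "empirical":
        return rng.choice(pool, size=n, replace=True)
    # lognormal: moment-match mean/median of the substituted pool
    mean = float(pool.mean())
    median = float(np.median(pool))
    if mean <= 0:
        return np.zeros(n)
    median = min(max(median, 1e-12), mean)  # guard degenerate/left-skew pools
    mu, sigma = fit_lognormal_from_mean_median(mean, median)
    return rng.lognormal(mu, sigma, n) if sigma > 0 else np.full(n, mean)


def run_monte_carlo(
    table: pd.DataFrame,
    groups: Sequence[PopulationGroup],
    congeners: Sequence[str],
    registry: Registry,
    n_trials: int = 1000,
    seed: int = 0,
    c_sampling: str = "empirical",
    policy: str = "nd_zero_half_mdl",
    total_label: str = "total_OPEs",
) -> MonteCarloResult:
    """Propagate C, IR and BW variability into per-(group, congener) EDI
    distributions plus a within-trial total-OPE distribution per group.

    ``table`` is a censor-flagged concentration table covering every
    microenvironment any group occupies; ``c_sampling`` chooses between
    empirical resampling of site concentrations and a fitted-lognormal
    parametric mode.  Reproducible under a fixed ``seed`` (per-group
    independent substreams).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if c_sampling not in C_SAMPLING_MODES:
        raise ValueError(f"unknown c_sampling mode {c_sampling!r}")
    envs_needed = sorted({e for g in groups for e in g.active_envs})
    pools = _concentration_pools(table, congeners, envs_needed, registry, policy)
    for g in groups:
        for env in g.active_envs:
            for name in congeners:
                if (env, name) not in pools:
                    raise ValueError(
                        f"no concentration records for {name!r} in {env!r} "
                        f"(needed by group {g.name!r})"
                    )

    children = np.random.SeedSequence(seed).spawn(len(groups))
    dists: list[ExposureDistribution] = []
    input_draws: dict[str, dict[str, np.ndarray]] = {}
    for g, child in zip(groups, children):
        rng = np.random.default_rng(child)
        ir = g.ir.sample(rng, n_trials)
        bw = g.bw.sample(rng, n_trials)
        env_totals = {env: np.zeros(n_trials) for env in g.active_envs}
        total = np.zeros(n_trials)
        for name in congeners:
            dose = np.zeros(n_trials)
            for env in g.active_envs:
                c = _sample_concentration(pools[(env, name)], c_sampling, rng, n_trials)
                dose += c * g.ief[env]
                env_totals[env] += c
            draws = dose * ir / bw * g.absorption
            total += draws
            dists.append(ExposureDistribution(g.name, name, draws))
        dists.append(ExposureDistribution(g.name, total_label, total))
        factors = {f"C_{env}": env_totals[env] for env in g.active_envs}
        factors["IR"] = ir
        factors["BW"] = bw
        factors["EDI_total"] = total
        input_draws[g.name] = factors
    return MonteCarloResult(
        distributions=dists,
        input_draws=input_draws,
        n_trials=n_trials,
        seed=seed,
        c_sampling=c_sampling,
    )


def summarize_distribution(dist: ExposureDistribution) -> dict:
    """Mean / P5 / P50 / P95 row (linear-interpolation percentiles)."""
    if dist.draws.size == 0:
        raise ValueError("empty draw vector")
    p5, p50, p95 = np.percentile(dist.draws, [5, 50, 95])
    return {
        "group": dist.group,
        "congener": dist.congener,
        "mean": dist.mean,
        "p5": float(p5),
        "p50": float(p50),
        "p95": float(p95),
    }
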
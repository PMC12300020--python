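"""Typed pipeline configuration.

A single YAML file defines the whole run: the congener registry (sampling
rates, detection limits, structural family, toxicity values), the population
groups (IR/BW distributions, per-microenvironment daily exposure fractions),
the synthetic-generator targets (per-microenvironment mean/median/detection
frequency per congener), Monte Carlo and statistics settings, and optional
reference mean EDIs used to build a risk table directly.

Validation is strict: unknown keys are rejected, every referenced congener
and microenvironment must be defined exactly once, and sampling rates must
lie inside the configured plausibility band.  The packaged ``guangzhou2020``
profile ships the published-table constants as the default study conditions.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exposure import Dist, PopulationGroup
from .registry import CongenerSpec, Registry
from .synthetic import GeneratorSpec, calibrate_censoring

__all__ = ["PipelineConfig", "load_config", "default_config", "default_config_path"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DistConfig(_Strict):
    kind: Literal["point", "normal", "lognormal"] = "point"
    mean: float = Field(gt=0)
    sd: float = Field(default=0.0, ge=0)

    def build(self) -> Dist:
        return Dist(kind=self.kind, mean=self.mean, sd=self.sd)


class CongenerConfig(_Strict):
    family: Literal["chlorinated", "alkyl", "aryl"]
    sampling_rate: float = Field(gt=0)  # m^3/day
    mdl: float = Field(ge=0)  # ng/m^3
    idl: float | None = Field(default=None, gt=0)  # ng/m^3
    rfd: float | None = Field(default=None, gt=0)  # ng/kg bw/day
    csf: float | None = Field(default=None, ge=0)  # (mg/kg bw/day)^-1


class GroupConfig(_Strict):
    ir: DistConfig
    bw: DistConfig
    ief: dict[str, float]
    absorption: float = Field(default=1.0, gt=0, le=1)


class TargetConfig(_Strict):
    """Marginal summary a synthetic microenvironment should reproduce."""

    mean: float = Field(gt=0)  # ng/m^3
    median: float = Field(gt=0)
    detection_frequency: float = Field(ge=0, le=100)  # percent

    @model_validator(mode="after")
    def _right_skew(self):
        if self.mean < self.median:
            raise ValueError("target mean must be >= median (right skew)")
        return self


class EnvTargets(_Strict):
    total_mean: float = Field(gt=0)
    total_median: float = Field(gt=0)
    congeners: dict[str, TargetConfig]


class MCConfig(_Strict):
    n_trials: int = Field(default=1000, ge=1)
    seed: int = 0
    c_sampling: Literal["empirical", "lognormal"] = "empirical"


class StatsConfig(_Strict):
    policy: Literal["nd_zero_half_mdl", "zero_all", "mdl_sqrt2", "detected_only"] = (
        "nd_zero_half_mdl"
    )
    alpha: float = Field(default=0.05, gt=0, lt=1)
    min_detection_frequency: float = Field(default=25.0, ge=0, le=100)
    total_inclusion_df: float = Field(default=10.0, ge=0, le=100)
    log_transform: bool = False


class BlanksConfig(_Strict):
    per_batch: int = Field(default=5, ge=1)
    mean_level_ng: float = Field(default=0.0, ge=0)
    noise_sd_ng: float = Field(default=0.0, ge=0)


class PipelineConfig(_Strict):
    profile: str = "custom"
    microenvironments: list[str]
    site_counts: dict[str, int]
    congeners: dict[str, CongenerConfig]
    sampling_rate_bounds: tuple[float, float] = (0.59, 2.01)
    mdl_bounds: tuple[float, float] = (0.022, 1.21)
    concentration_targets: dict[str, EnvTargets] = Field(default_factory=dict)
    env_total_means: dict[str, float] = Field(default_factory=dict)
    groups: dict[str, GroupConfig]
    mc: MCConfig = Field(default_factory=MCConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    blanks: BlanksConfig = Field(default_factory=BlanksConfig)
    reference_edi: dict[str, dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _cross_references(self):
        envs = set(self.microenvironments)
        if len(envs) != len(self.microenvironments):
            raise ValueError("duplicate microenvironment")
        for env, n in self.site_counts.items():
            if env not in envs:
                raise ValueError(f"site_counts references unknown microenvironment {env!r}")
            if n < 1:
                raise ValueError(f"site_counts[{env!r}] must be >= 1")
        for gname, grp in self.groups.items():
            for env in grp.ief:
                if env not in envs:
                    raise ValueError(
                        f"group {gname!r} ief references unknown microenvironment {env!r}"
                    )
            if sum(grp.ief.values()) > 1.0 + 1e-9:
                raise ValueError(f"group {gname!r}: ief fractions sum above 1")
        for group, per_congener in self.reference_edi.items():
            if group not in self.groups:
                raise ValueError(f"reference_edi references unknown group {group!r}")
            for name in per_congener:
                if name not in self.congeners:
                    raise ValueError(
                        f"reference_edi references unknown congener {name!r}"
                    )
        lo, hi = self.sampling_rate_bounds
        for name, cfg in self.congeners.items():
            if not (lo <= cfg.sampling_rate <= hi):
                raise ValueError(
                    f"{name}: sampling rate outside plausibility band [{lo}, {hi}]"
                )
        return self

    # ---- builders -------------------------------------------------------

    def build_registry(self) -> Registry:
        return Registry(
            (
                CongenerSpec(
                    name=name,
                    sampling_rate=c.sampling_rate,
                    mdl=c.mdl,
                    family=c.family,
                    idl=c.idl,
                    rfd=c.rfd,
                    csf=c.csf,
                )
                for name, c in self.congeners.items()
            ),
            rate_bounds=self.sampling_rate_bounds,
        )

    def build_groups(self) -> list[PopulationGroup]:
        return [
            PopulationGroup(
                name=name,
                ir=g.ir.build(),
                bw=g.bw.build(),
                ief=dict(g.ief),
                absorption=g.absorption,
            )
            for name, g in self.groups.items()
        ]

    def generator_specs(self) -> list[GeneratorSpec]:
        """Per-(microenvironment, congener) generator specs.

        Target blocks keyed by a microenvironment are used directly.  The
        ``indoor`` block is a pooled target for the non-car environments; it
        is rescaled per environment by the ratio of that environment's total
        mean to the pooled total mean, so per-environment totals track the
        configured levels while the congener mix stays fixed.
        """
        specs: list[GeneratorSpec] = []
        for env in self.microenvironments:
            if env in self.concentration_targets:
                block, factor = self.concentration_targets[env], 1.0
            elif "indoor" in self.concentration_targets:
                block = self.concentration_targets["indoor"]
                factor = self.env_total_means.get(env, block.total_mean) / block.total_mean
            else:
                raise ValueError(f"no concentration targets for microenvironment {env!r}")
            for name, t in block.congeners.items():
                mdl, absent = calibrate_censoring(
                    t.mean, t.median, t.detection_frequency, self.mdl_bounds
                )
                specs.append(
                    GeneratorSpec(
                        congener=name,
                        microenvironment=env,
                        target_mean=t.mean * factor,
                        target_median=t.median * factor,
                        mdl=mdl,
                        n_sites=self.site_counts[env],
                        absent_prob=absent,
                    )
                )
        return specs

    def target_means(self, block: str) -> dict[str, float]:
        """Configured per-congener mean concentrations for a target block."""
        return {
            name: t.mean
            for name, t in self.concentration_targets[block].congeners.items()
        }

    def included_congeners(self, block: str) -> list[str]:
        """Congeners entering totals/composition for a target block: those
        at or above the total-inclusion detection-frequency threshold."""
        thr = self.stats.total_inclusion_df
        return [
            name
            for name, t in self.concentration_targets[block].congeners.items()
            if t.detection_frequency >= thr
        ]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline configuration from YAML."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.model_validate(data)


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(resources.files("opeair").joinpath("data/guangzhou2020.yaml"))


def default_config() -> PipelineConfig:
    """The packaged ``guangzhou2020`` default profile."""
    return load_config(default_config_path())
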
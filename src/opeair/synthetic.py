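"""Synthetic censored concentration tables and procedural blanks.

Indoor-air OPE concentrations are strongly right-skewed: in every printed
summary the mean exceeds the median.  The generator therefore draws site
concentrations from a lognormal law moment-matched to a target (mean, median)
pair:

    median = exp(mu)            ->  mu    = ln(median)
    mean   = exp(mu + s^2/2)    ->  sigma = sqrt(2 ln(mean / median))

Non-detects arise two ways: left-censoring at the method detection limit
(values drawn below the MDL are flagged ``below_mdl``), and an independent
per-site "absent" probability that models congeners genuinely missing from a
site's materials (flagged ``not_detected``) — censoring alone cannot push the
detection frequency below the lognormal CDF at the MDL.
``calibrate_censoring`` chooses the MDL within plausible bounds (and, where
needed, an absent probability) so a spec reproduces a target detection
frequency.

A single global seed is expanded into independent per-spec substreams so a
table is reproducible as a whole while congeners stay independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CensorFlag

__all__ = [
    "GeneratorSpec",
    "fit_lognormal_from_mean_median",
    "calibrate_censoring",
    "generate_site_table",
    "generate_blanks",
]

TABLE_COLUMNS = ["site_id", "microenvironment", "congener", "value_ng_m3", "censor"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Target marginal for one congener in one microenvironment.

    ``target_mean >= target_median > 0`` encodes the right skew; ``mdl`` is
    the censoring point; ``absent_prob`` is the probability a site simply
    lacks the congener (reported not-detected regardless of the draw).
    """

    congener: str
    microenvironment: str
    target_mean: float
    target_median: float
    mdl: float
    n_sites: int
    absent_prob: float = 0.0
    seed: int | None = None  # optional per-spec override of the substream

    def __post_init__(self) -> None:
        if not (self.target_mean >= self.target_median > 0):
            raise ValueError(
                f"{self.congener}/{self.microenvironment}: need "
                "target_mean >= target_median > 0"
            )
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mdl < 0:
            raise ValueError("mdl must be non-negative")
        if not 0.0 <= self.absent_prob <= 1.0:
            raise ValueError("absent_prob must be in [0, 1]")


def fit_lognormal_from_mean_median(
    target_mean: float, target_median: float
) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given mean and median.

    Returns ``sigma = 0`` (a point mass) when mean equals median.  Raises for
    non-positive inputs or mean < median (left skew has no lognormal
    solution).
    """
    if target_median <= 0 or target_mean <= 0:
        raise ValueError("mean and median must be positive")
    if target_mean < target_median:
        raise ValueError("no lognormal has mean < median")
    mu = math.log(target_median)
    sigma = math.sqrt(2.0 * math.log(target_mean / target_median))
    return mu, sigma


def calibrate_censoring(
    target_mean: float,
    target_median: float,
    target_df_pct: float,
    mdl_bounds: tuple[float, float] = (0.022, 1.21),
) -> tuple[float, float]:
    """Choose (mdl, absent_prob) reproducing a target detection frequency.

    The MDL is placed at the lognormal quantile matching the undetected
    fraction, clipped into ``mdl_bounds``; any shortfall in non-detection
    that clipping leaves is assigned to the independent absent probability.
    """
    if not 0.0 <= target_df_pct <= 100.0:
        raise ValueError("detection frequency must be in [0, 100]")
    lo, hi = mdl_bounds
    mu, sigma = fit_lognormal_from_mean_median(target_mean, target_median)
    p_undet = 1.0 - target_df_pct / 100.0
    if sigma == 0.0:
        # Point mass: censoring is all-or-nothing; use absence instead.
        return lo, p_undet
    cand = math.exp(mu + sigma * stats.norm.ppf(p_undet)) if p_undet > 0 else 0.0
    mdl = min(max(cand, lo), hi)
    cdf = stats.norm.cdf((math.log(mdl) - mu) / sigma)
    absent = 0.0
    if p_undet > cdf and cdf < 1.0:
        absent = (p_undet - cdf) / (1.0 - cdf)
    return float(mdl), float(absent)


def _draw_one(spec: GeneratorSpec, rng: np.random.Generator) -> pd.DataFrame:
    mu, sigma = fit_lognormal_from_mean_median(spec.target_mean, spec.target_median)
    values = (
        np.full(spec.n_sites, spec.target_mean)
        if sigma == 0.0
        else rng.lognormal(mu, sigma, spec.n_sites)
    )
    absent = rng.random(spec.n_sites) < spec.absent_prob
    flags = np.where(
        absent,
        CensorFlag.NOT_DETECTED.value,
        np.where(values >= spec.mdl, CensorFlag.DETECTED.value, CensorFlag.BELOW_MDL.value),
    )
    values = np.where(absent, 0.0, values)
    return pd.DataFrame(
        {
            "site_id": [f"{spec.microenvironment}-{i + 1:03d}" for i in range(spec.n_sites)],
            "microenvironment": spec.microenvironment,
            "congener": spec.congener,
            "value_ng_m3": values,
            "censor": flags,
        }
    )


def generate_site_table(
    specs: Sequence[GeneratorSpec], seed: int = 0
) -> pd.DataFrame:
    """Draw a censor-flagged concentration table from a list of specs.

    One global ``seed`` is expanded into independent substreams, one per
    spec (a spec's own ``seed`` field overrides its substream).  Rejects
    duplicate (congener, microenvironment) specs, which would collide on
    (site, congener) keys.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    keys = [(s.congener, s.microenvironment) for s in specs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (congener, microenvironment) spec")
    children = np.random.SeedSequence(seed).spawn(len(specs))
    frames = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(spec.seed if spec.seed is not None else child)
        frames.append(_draw_one(spec, rng))
    table = pd.concat(frames, ignore_index=True)
    return table[TABLE_COLUMNS]


def generate_blanks(
    n: int, mean_level: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Procedural-blank masses (ng): normal noise around a mean contamination
    level, truncated at zero.  ``n = 0`` or ``mean_level = noise_sd = 0``
    model clean blanks."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if mean_level < 0:
        raise ValueError("mean_level must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean_level, noise_sd, n) if noise_sd > 0 else np.full(n, mean_level)
    return np.clip(draws, 0.0, None)


def scaled_specs(specs: Iterable[GeneratorSpec], factor: float) -> list[GeneratorSpec]:
    """Rescale target mean/median (and MDL) of every spec by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return [
        replace(
            s,
            target_mean=s.target_mean * factor,
            target_median=s.target_median * factor,
        )
        for s in specs
    ]
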
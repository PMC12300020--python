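"""Passive-sampler calibration: mass -> concentration, MDLs, censor flags.

A polyurethane-foam passive air sampler (PUF-PAS) deployed for a period
accumulates analyte mass at a compound-specific effective sampling rate
(m^3/day).  The time-averaged air concentration is then

    C  =  mass / (sampling_rate x duration)        [ng/m^3]

Method detection limits (MDLs) come from procedural blanks: mean blank level
plus three times the blank standard deviation; when a compound is never seen
in blanks, half the instrumental detection limit (IDL) is used instead.
Concentrations are censor-flagged against the MDL: ``detected`` (>= MDL),
``below_mdl`` (quantified but under the MDL) or ``not_detected`` (instrument
reported nothing).  No recovery correction is applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .registry import CongenerSpec

__all__ = [
    "CensorFlag",
    "Deployment",
    "compute_mdl",
    "mass_to_concentration",
    "apply_censoring",
]


class CensorFlag(str, enum.Enum):
    """Detection status of one concentration record."""

    DETECTED = "detected"
    BELOW_MDL = "below_mdl"
    NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class Deployment:
    """One sampler deployment at a site (nominal duration 30 days)."""

    site_id: str
    microenvironment: str
    duration_days: float = 30.0
    sampler_type: str = "PUF-PAS"

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("deployment duration must be positive")


def compute_mdl(
    blanks: Sequence[float],
    idl: float,
    detection_threshold: float = 0.0,
) -> float:
    """Method detection limit from procedural blanks.

    If any blank exceeds ``detection_threshold`` (default: any positive
    reading counts as a blank detection) the MDL is the blank mean plus three
    sample (n-1) standard deviations; otherwise the compound is treated as
    not detected in blanks and the MDL falls back to ``idl / 2``.
    """
    if idl <= 0:
        raise ValueError("idl must be positive")
    arr = np.asarray(blanks, dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("blank concentrations must be non-negative")
    if arr.size and np.any(arr > detection_threshold):
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean() + 3.0 * sd)
    return idl / 2.0


def mass_to_concentration(
    mass_ng: float,
    spec: CongenerSpec,
    deployment: Deployment,
) -> float:
    """Air concentration (ng/m^3) from accumulated sampler mass (ng)."""
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    if spec.sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    # Deployment validates duration > 0 on construction.
    return mass_ng / (spec.sampling_rate * deployment.duration_days)


def apply_censoring(value: float | None, mdl: float) -> CensorFlag:
    """Censor flag for one concentration against the MDL.

    Values exactly at the MDL count as detected (inclusive convention).
    ``None``/NaN, or a zero reading, mean the instrument reported nothing.
    """
    if mdl < 0:
        raise ValueError("mdl must be non-negative")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return CensorFlag.NOT_DETECTED
    if value < 0:
        raise ValueError("concentration must be non-negative")
    if value == 0:
        return CensorFlag.NOT_DETECTED
    if value >= mdl:
        return CensorFlag.DETECTED
    return CensorFlag.BELOW_MDL
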
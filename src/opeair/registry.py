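"""Congener registry: identity, sampler calibration and toxicity constants per OPE.

Each organophosphate ester (OPE) congener carries the constants the pipeline
needs end to end: the passive-sampler effective sampling rate used to turn
accumulated mass into an air concentration, the instrumental/method detection
limits used for censoring, a structural family (chlorinated alkyl,
non-chlorinated alkyl, aryl) used for compositional class aggregates, and the
USEPA toxicity benchmarks (reference dose RfD, cancer slope factor CSF) used
for risk characterization.  Congeners without an RfD or CSF are carried
through the pipeline and flagged unavailable in the risk table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["CongenerSpec", "Registry", "FAMILIES"]

FAMILIES = ("chlorinated", "alkyl", "aryl")

#: plausibility band for PUF-PAS effective sampling rates (m^3/day)
DEFAULT_RATE_BOUNDS = (0.59, 2.01)


@dataclass(frozen=True)
class CongenerSpec:
    """One OPE congener and its per-compound constants.

    Parameters
    ----------
    name:
        Congener abbreviation (e.g. ``"TCEP"``).
    sampling_rate:
        PUF-PAS effective sampling rate, m^3/day.
    mdl:
        Method detection limit, ng/m^3.
    family:
        Structural class: ``"chlorinated"`` (Cl-bearing alkyl esters),
        ``"alkyl"`` (non-chlorinated alkyl esters) or ``"aryl"``.
    idl:
        Instrumental detection limit expressed on the concentration scale,
        ng/m^3; used for the MDL fallback rule when blanks are clean.
    rfd:
        Reference dose for non-carcinogenic effects, ng/kg bw/day.
    csf:
        Cancer slope factor, (mg/kg bw/day)^-1.
    """

    name: str
    sampling_rate: float
    mdl: float
    family: str = "alkyl"
    idl: float | None = None
    rfd: float | None = None
    csf: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.name}")
        if self.sampling_rate <= 0:
            raise ValueError(f"{self.name}: sampling_rate must be positive")
        if self.mdl < 0:
            raise ValueError(f"{self.name}: mdl must be non-negative")
        if self.rfd is not None and self.rfd <= 0:
            raise ValueError(f"{self.name}: rfd must be positive when present")
        if self.csf is not None and self.csf < 0:
            raise ValueError(f"{self.name}: csf must be non-negative when present")

    @property
    def chlorinated(self) -> bool:
        return self.family == "chlorinated"


class Registry(Mapping[str, CongenerSpec]):
    """Ordered, validated collection of :class:`CongenerSpec`.

    Validates that every sampling rate lies inside the configured
    plausibility band (the range spanned by the calibration study the rates
    were taken from).
    """

    def __init__(
        self,
        specs: Iterable[CongenerSpec],
        rate_bounds: tuple[float, float] = DEFAULT_RATE_BOUNDS,
    ) -> None:
        self._specs: dict[str, CongenerSpec] = {}
        lo, hi = rate_bounds
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate congener {spec.name!r}")
            if not (lo <= spec.sampling_rate <= hi):
                raise ValueError(
                    f"{spec.name}: sampling rate {spec.sampling_rate} outside "
                    f"plausibility band [{lo}, {hi}] m^3/day"
                )
            self._specs[spec.name] = spec
        self.rate_bounds = rate_bounds

    def __getitem__(self, name: str) -> CongenerSpec:
        return self._specs[name]

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def family_members(self, family: str) -> list[str]:
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        return [n for n, s in self._specs.items() if s.family == family]

    def mdls(self) -> dict[str, float]:
        return {n: s.mdl for n, s in self._specs.items()}

    def with_rfd(self) -> list[str]:
        return [n for n, s in self._specs.items() if s.rfd is not None]

    def with_csf(self) -> list[str]:
        return [n for n, s in self._specs.items() if s.csf is not None]
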
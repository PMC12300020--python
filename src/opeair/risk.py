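"""Risk characterization (HQ, CR) and contribution-to-variance sensitivity.

Non-carcinogenic risk is screened with the hazard quotient

    HQ = EDI / RfD                       (both in ng/kg bw/day)

and carcinogenic risk with

    CR = EDI x 1e-6 x CSF                (CSF in (mg/kg bw/day)^-1,
                                          1e-6 bridges ng -> mg exactly once)

HQ > 1 flags potential non-carcinogenic risk; CR > 1e-6 flags potential
carcinogenic concern.  Totals sum only the congeners for which the relevant
toxicity value exists.  By default HQ/CR are computed from mean EDIs (the
conventional screening table); a full-distribution mode can be layered on by
passing percentile EDIs instead.

Sensitivity uses a contribution-to-variance decomposition in the style of
spreadsheet Monte Carlo tools: each input factor's Spearman rank correlation
with the output is squared (signs discarded — a factor entering inversely,
like body weight, still contributes variance) and normalized to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import Registry

__all__ = [
    "RiskTable",
    "SensitivityResult",
    "hazard_quotient",
    "carcinogenic_risk",
    "build_risk_table",
    "contribution_to_variance",
    "HQ_THRESHOLD",
    "CR_THRESHOLD",
]

HQ_THRESHOLD = 1.0
CR_THRESHOLD = 1e-6

#: unit bridge ng -> mg, applied exactly once inside carcinogenic_risk
_NG_TO_MG = 1e-6


def hazard_quotient(edi: float, rfd: float) -> float:
    """HQ = EDI/RfD (dimensionless); RfD must be positive."""
    if rfd <= 0:
        raise ValueError("rfd must be positive")
    if edi < 0:
        raise ValueError("edi must be non-negative")
    return edi / rfd


def carcinogenic_risk(edi: float, csf: float) -> float:
    """CR = EDI[ng/kg/day] x 1e-6 x CSF[(mg/kg/day)^-1] (dimensionless)."""
    if csf < 0:
        raise ValueError("csf must be non-negative")
    if edi < 0:
        raise ValueError("edi must be non-negative")
    return edi * _NG_TO_MG * csf


@dataclass
class RiskTable:
    """HQ/CR per (group, congener) with per-group totals and threshold flags.

    ``table`` holds one row per (group, congener) with NaN where the
    toxicity value is unavailable; ``totals`` one row per group summing only
    the congeners with the relevant value.
    """

    table: pd.DataFrame  # group, congener, edi, hq, cr, hq_exceeds, cr_exceeds
    totals: pd.DataFrame  # group, n_hq, hq_total, n_cr, cr_total, flags

    @property
    def any_hq_exceedance(self) -> bool:
        return bool(self.table["hq_exceeds"].any() or self.totals["hq_exceeds"].any())

    @property
    def any_cr_exceedance(self) -> bool:
        return bool(self.table["cr_exceeds"].any() or self.totals["cr_exceeds"].any())


def build_risk_table(
    edi_means: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    registry: Registry,
) -> RiskTable:
    """Risk table from mean EDIs.

    ``edi_means`` is either ``{group: {congener: mean EDI}}`` or a DataFrame
    with columns (group, congener, mean).  Congeners missing an RfD or CSF
    get NaN in that column and are excluded from the corresponding total.
    """
    if isinstance(edi_means, pd.DataFrame):
        nested: dict[str, dict[str, float]] = {}
        for _, row in edi_means.iterrows():
            nested.setdefault(str(row["group"]), {})[str(row["congener"])] = float(
                row["mean"]
            )
        edi_means = nested

    rows = []
    for group, per_congener in edi_means.items():
        for name, edi in per_congener.items():
            if name not in registry:
                raise KeyError(f"congener {name!r} not in registry")
            spec = registry[name]
            hq = hazard_quotient(edi, spec.rfd) if spec.rfd is not None else np.nan
            cr = (
                carcinogenic_risk(edi, spec.csf) if spec.csf is not None else np.nan
            )
            rows.append(
                {
                    "group": group,
                    "congener": name,
                    "edi": float(edi),
                    "hq": hq,
                    "cr": cr,
                    "hq_exceeds": bool(hq > HQ_THRESHOLD) if np.isfinite(hq) else False,
                    "cr_exceeds": bool(cr > CR_THRESHOLD) if np.isfinite(cr) else False,
                }
            )
    table = pd.DataFrame(rows)

    totals_rows = []
    for group, grp in table.groupby("group", sort=False):
        hq_avail = grp["hq"].dropna()
        cr_avail = grp["cr"].dropna()
        hq_total = float(hq_avail.sum()) if len(hq_avail) else np.nan
        cr_total = float(cr_avail.sum()) if len(cr_avail) else np.nan
        totals_rows.append(
            {
                "group": group,
                "n_hq": int(len(hq_avail)),
                "hq_total": hq_total,
                "n_cr": int(len(cr_avail)),
                "cr_total": cr_total,
                "hq_exceeds": bool(hq_total > HQ_THRESHOLD)
                if np.isfinite(hq_total)
                else False,
                "cr_exceeds": bool(cr_total > CR_THRESHOLD)
                if np.isfinite(cr_total)
                else False,
            }
        )
    return RiskTable(table=table, totals=pd.DataFrame(totals_rows))


@dataclass
class SensitivityResult:
    """Percent contribution of each Monte Carlo input factor to the output's
    variability (non-negative, normalized to 100)."""

    contributions: dict[str, float]  # factor -> percent
    correlations: dict[str, float]  # factor -> signed Spearman r

    def dominant_factor(self) -> str:
        return max(self.contributions, key=self.contributions.get)


def contribution_to_variance(
    input_draws: Mapping[str, np.ndarray] | Mapping[str, Sequence[float]],
    output_draws: np.ndarray | Sequence[float],
) -> SensitivityResult:
    """Normalized squared Spearman correlation of each factor with the output.

    contribution_f = 100 * r_f^2 / sum_g r_g^2.  A zero-variance factor
    contributes 0 (with a warning) — it cannot explain any output variance.
    Requires >= 100 trials for a stable rank correlation.
    """
    output = np.asarray(output_draws, dtype=float)
    if output.size < 100:
        raise ValueError("need at least 100 draws for a stable decomposition")
    r2: dict[str, float] = {}
    corr: dict[str, float] = {}
    for factor, draws in input_draws.items():
        arr = np.asarray(draws, dtype=float)
        if arr.shape != output.shape:
            raise ValueError(f"factor {factor!r} draws length mismatch")
        if float(np.var(arr)) == 0.0:
            warnings.warn(
                f"factor {factor!r} has zero variance; contribution set to 0",
                stacklevel=2,
            )
            r2[factor] = 0.0
            corr[factor] = 0.0
            continue
        r = float(stats.spearmanr(arr, output).statistic)
        corr[factor] = r
        r2[factor] = r * r
    denom = sum(r2.values())
    if denom == 0.0:
        contributions = {f: 0.0 for f in r2}
    else:
        contributions = {f: 100.0 * v / denom for f, v in r2.items()}
    return SensitivityResult(contributions=contributions, correlations=corr)
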
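"""Descriptive statistics for left-censored concentration tables.

Covers the descriptive layer of the assessment: detection frequencies,
summary statistics under a configurable non-detect substitution policy,
compositional profiles with structural-class aggregates, Spearman
congener-congener correlation screening, and microenvironment group
comparisons (one-way ANOVA plus pairwise t-tests on per-site totals).

Substitution policies (applied before any statistic):

- ``nd_zero_half_mdl`` (default): not_detected -> 0, below_mdl -> MDL/2
- ``zero_all``: both kinds of non-detect -> 0
- ``mdl_sqrt2``: both -> MDL/sqrt(2)
- ``detected_only``: drop undetected records

Percentiles use linear interpolation between closest ranks (numpy's default,
Hyndman-Fan type 7), pinned so summaries are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CensorFlag
from .registry import Registry

__all__ = [
    "SUBSTITUTION_POLICIES",
    "SummaryRow",
    "CompositionProfile",
    "GroupComparison",
    "substitute_values",
    "detection_frequency",
    "censored_summary",
    "summarize_table",
    "composition_profile",
    "spearman_matrix",
    "compare_groups",
]

SUBSTITUTION_POLICIES = ("nd_zero_half_mdl", "zero_all", "mdl_sqrt2", "detected_only")

_DETECTED = CensorFlag.DETECTED.value
_BELOW = CensorFlag.BELOW_MDL.value
_ND = CensorFlag.NOT_DETECTED.value


@dataclass(frozen=True)
class SummaryRow:
    """Summary-table row for one congener (concentrations in ng/m^3)."""

    congener: str
    n: int
    detection_frequency: float  # percent
    mean: float
    min: float
    p25: float
    p50: float
    p75: float
    p90: float
    max: float

    def as_dict(self) -> dict:
        return {
            "congener": self.congener,
            "n": self.n,
            "detection_frequency": self.detection_frequency,
            "mean": self.mean,
            "min": self.min,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p90": self.p90,
            "max": self.max,
        }


@dataclass(frozen=True)
class CompositionProfile:
    """Percent share of each congener in the summed mean concentration,
    plus structural-class aggregates."""

    shares: dict[str, float]  # congener -> percent of total
    class_shares: dict[str, float]  # family -> percent of total
    total_mean: float  # ng/m^3, sum of included congener means


@dataclass
class GroupComparison:
    """ANOVA + pairwise t-tests on per-site total concentrations."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p, significant
    group_means: dict[str, float]
    alpha: float
    degenerate: list[str] = field(default_factory=list)

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


def _select(
    table: pd.DataFrame,
    congener: str | None = None,
    microenvs: Iterable[str] | None = None,
) -> pd.DataFrame:
    sel = table
    if congener is not None:
        sel = sel[sel["congener"] == congener]
    if microenvs is not None:
        sel = sel[sel["microenvironment"].isin(set(microenvs))]
    return sel


def substitute_values(
    values: np.ndarray, flags: np.ndarray, mdl: float, policy: str
) -> np.ndarray:
    """Replace undetected entries per the policy; returns the working vector
    (shorter than the input under ``detected_only``)."""
    if policy not in SUBSTITUTION_POLICIES:
        raise ValueError(f"unknown substitution policy {policy!r}")
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags)
    detected = flags == _DETECTED
    if policy == "detected_only":
        return values[detected]
    out = values.copy()
    if policy == "nd_zero_half_mdl":
        out[flags == _ND] = 0.0
        out[flags == _BELOW] = mdl / 2.0
    elif policy == "zero_all":
        out[~detected] = 0.0
    elif policy == "mdl_sqrt2":
        out[~detected] = mdl / math.sqrt(2.0)
    return out


def detection_frequency(
    table: pd.DataFrame,
    congener: str,
    microenvs: Iterable[str] | None = None,
) -> float:
    """Percent of selected records flagged detected (below-MDL and
    not-detected records both count as undetected)."""
    sel = _select(table, congener, microenvs)
    if sel.empty:
        raise ValueError(f"no records for congener {congener!r}")
    return 100.0 * float((sel["censor"] == _DETECTED).mean())


def censored_summary(
    table: pd.DataFrame,
    congener: str,
    mdl: float,
    policy: str = "nd_zero_half_mdl",
    microenvs: Iterable[str] | None = None,
) -> SummaryRow:
    """Mean and percentile summary after non-detect substitution."""
    sel = _select(table, congener, microenvs)
    if sel.empty:
        raise ValueError(f"no records for congener {congener!r}")
    values = substitute_values(
        sel["value_ng_m3"].to_numpy(), sel["censor"].to_numpy(), mdl, policy
    )
    if values.size == 0:
        raise ValueError(
            f"{congener}: no detected records under policy 'detected_only'"
        )
    p25, p50, p75, p90 = np.percentile(values, [25, 50, 75, 90])
    return SummaryRow(
        congener=congener,
        n=len(sel),
        detection_frequency=detection_frequency(table, congener, microenvs),
        mean=float(values.mean()),
        min=float(values.min()),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p90=float(p90),
        max=float(values.max()),
    )


def summarize_table(
    table: pd.DataFrame,
    registry: Registry,
    policy: str = "nd_zero_half_mdl",
    microenvs: Iterable[str] | None = None,
    congeners: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-congener summary rows plus a total row over per-site sums."""
    names = list(congeners) if congeners is not None else registry.names
    rows = []
    for name in names:
        sel = _select(table, name, microenvs)
        if sel.empty:
            continue
        rows.append(
            censored_summary(table, name, registry[name].mdl, policy, microenvs).as_dict()
        )
    if not rows:
        raise ValueError("no records selected")
    out = pd.DataFrame(rows)

    totals = per_site_totals(table, registry, policy, microenvs, names)
    p25, p50, p75, p90 = np.percentile(totals, [25, 50, 75, 90])
    total_row = {
        "congener": f"total_{len(out)}OPEs",
        "n": len(totals),
        "detection_frequency": 100.0 * float((totals > 0).mean()),
        "mean": float(totals.mean()),
        "min": float(totals.min()),
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
        "p90": float(p90),
        "max": float(totals.max()),
    }
    return pd.concat([out, pd.DataFrame([total_row])], ignore_index=True)


def per_site_totals(
    table: pd.DataFrame,
    registry: Registry,
    policy: str = "nd_zero_half_mdl",
    microenvs: Iterable[str] | None = None,
    congeners: Sequence[str] | None = None,
) -> np.ndarray:
    """Sum of substituted congener concentrations per site (the per-sample
    total OPE burden)."""
    if policy == "detected_only":
        raise ValueError("per-site totals require a substitution policy that keeps all records")
    sel = _select(table, None, microenvs)
    if congeners is not None:
        sel = sel[sel["congener"].isin(set(congeners))]
    if sel.empty:
        raise ValueError("no records selected")
    parts = []
    for name, grp in sel.groupby("congener", sort=False):
        vals = substitute_values(
            grp["value_ng_m3"].to_numpy(),
            grp["censor"].to_numpy(),
            registry[name].mdl,
            policy,
        )
        parts.append(pd.Series(vals, index=grp["site_id"].to_numpy()))
    wide = pd.concat(parts, axis=1)
    return wide.fillna(0.0).sum(axis=1).to_numpy()


def composition_profile(
    summaries: Sequence[SummaryRow] | Mapping[str, float],
    registry: Registry,
    included: Iterable[str] | None = None,
) -> CompositionProfile:
    """Percent contribution of each congener's mean to the summed mean.

    ``summaries`` is either a list of :class:`SummaryRow` or a plain
    ``{congener: mean}`` mapping.  ``included`` restricts the congeners that
    enter the total (e.g. dropping congeners with negligible detection).
    """
    if isinstance(summaries, Mapping):
        means = dict(summaries)
    else:
        means = {s.congener: s.mean for s in summaries}
    if included is not None:
        included = list(included)
        missing = [c for c in included if c not in means]
        if missing:
            raise ValueError(f"no mean available for {missing}")
        means = {c: means[c] for c in included}
    total = sum(means.values())
    if total <= 0:
        raise ValueError("total mean concentration must be positive")
    shares = {c: 100.0 * m / total for c, m in means.items()}
    class_shares: dict[str, float] = {}
    for fam in ("chlorinated", "alkyl", "aryl"):
        members = set(registry.family_members(fam)) & means.keys()
        if members:
            class_shares[fam] = sum(shares[c] for c in members)
    return CompositionProfile(shares=shares, class_shares=class_shares, total_mean=total)


def spearman_matrix(
    table: pd.DataFrame,
    registry: Registry,
    microenvs: Iterable[str] | None = None,
    min_df: float = 25.0,
    policy: str = "nd_zero_half_mdl",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation screen between congeners.

    Congeners with detection frequency below ``min_df`` percent are excluded
    (rank correlations on mostly-substituted vectors are artefacts of the
    substitution constant).  Returns (r, p) DataFrames; pairs with fewer
    than 3 complete observations are NaN.
    """
    sel = _select(table, None, microenvs)
    if sel.empty:
        raise ValueError("no records selected")
    keep = [
        c
        for c in sel["congener"].unique()
        if detection_frequency(sel, c) >= min_df
    ]
    if len(keep) < 2:
        raise ValueError("need at least two congeners above the DF threshold")
    cols = {}
    for name in keep:
        grp = sel[sel["congener"] == name]
        vals = substitute_values(
            grp["value_ng_m3"].to_numpy(),
            grp["censor"].to_numpy(),
            registry[name].mdl,
            policy,
        )
        cols[name] = pd.Series(vals, index=grp["site_id"].to_numpy())
    wide = pd.DataFrame(cols)
    n = len(wide)
    r = pd.DataFrame(np.eye(len(keep)), index=keep, columns=keep)
    p = pd.DataFrame(np.zeros((len(keep), len(keep))), index=keep, columns=keep)
    for a, b in itertools.combinations(keep, 2):
        pair = wide[[a, b]].dropna()
        if len(pair) < 3:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.spearmanr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    r.attrs["n_sites"] = n
    return r, p


def compare_groups(
    table: pd.DataFrame,
    registry: Registry,
    policy: str = "nd_zero_half_mdl",
    alpha: float = 0.05,
    log_transform: bool = False,
) -> GroupComparison:
    """One-way ANOVA across microenvironments on per-site total
    concentrations, with pairwise two-sample t-tests.

    ``log_transform`` applies ln(total) first (off by default).  Groups with
    fewer than 2 sites or zero variance are flagged degenerate; a pairwise
    test involving a degenerate group reports NaN.
    """
    envs = list(dict.fromkeys(table["microenvironment"]))
    if len(envs) < 2:
        raise ValueError("need at least two microenvironments")
    samples: dict[str, np.ndarray] = {}
    degenerate = []
    for env in envs:
        totals = per_site_totals(table, registry, policy, microenvs=[env])
        if log_transform:
            totals = np.log(totals)
        samples[env] = totals
        if len(totals) < 2 or float(np.var(totals)) == 0.0:
            degenerate.append(env)

    valid = [samples[e] for e in envs if e not in degenerate]
    if len(valid) >= 2:
        f_stat, f_p = stats.f_oneway(*valid)
    else:
        f_stat, f_p = float("nan"), float("nan")

    rows = []
    for a, b in itertools.combinations(envs, 2):
        if a in degenerate or b in degenerate:
            t, pv = float("nan"), float("nan")
        else:
            t, pv = stats.ttest_ind(samples[a], samples[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p": float(pv),
                "significant": bool(pv < alpha) if not math.isnan(pv) else False,
            }
        )
    return GroupComparison(
        anova_f=float(f_stat),
        anova_p=float(f_p),
        pairwise=pd.DataFrame(rows),
        group_means={e: float(np.mean(samples[e])) for e in envs},
        alpha=alpha,
        degenerate=degenerate,
    )
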
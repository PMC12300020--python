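"""Censored descriptive layer: DF, summaries, composition, correlation,
group comparison — each checked against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opeair import (
    censored_summary,
    compare_groups,
    composition_profile,
    detection_frequency,
    spearman_matrix,
)
from opeair.censored import per_site_totals, substitute_values

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles


def oracle_percentile(values, q):
    """Linear interpolation between closest ranks, from first principles."""
    s = sorted(values)
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    if lo + 1 >= len(s):
        return s[-1]
    return s[lo] + (s[lo + 1] - s[lo]) * (h - lo)


def oracle_substitute(pairs, mdl, policy):
    out = []
    for value, flag in pairs:
        if flag == "detected":
            out.append(value)
        elif policy == "nd_zero_half_mdl":
            out.append(mdl / 2.0 if flag == "below_mdl" else 0.0)
        elif policy == "zero_all":
            out.append(0.0)
        elif policy == "mdl_sqrt2":
            out.append(mdl / math.sqrt(2.0))
        elif policy == "detected_only":
            continue
    return out


def oracle_spearman(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for untied data."""
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    n = len(x)
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1 - 6 * d2 / (n * (n**2 - 1))


# ---------------------------------------------------------------------------


class TestDetectionFrequency:
    @pytest.mark.parametrize("n_det,n_tot,expected", [(28, 62, 45.2), (39, 62, 62.9), (0, 10, 0.0)])
    def test_ratio_matches_printed_style_rounding(self, n_det, n_tot, expected):
        rows = [(f"s{i}", "home", "A", 1.0, "detected") for i in range(n_det)]
        rows += [(f"s{i + n_det}", "home", "A", 0.0, "not_detected") for i in range(n_tot - n_det)]
        assert detection_frequency(make_table(rows), "A") == pytest.approx(expected, abs=0.05)

    def test_below_mdl_counts_as_undetected(self):
        t = make_table(
            [("s1", "home", "A", 0.5, "below_mdl"), ("s2", "home", "A", 2.0, "detected")]
        )
        assert detection_frequency(t, "A") == pytest.approx(50.0)

    def test_empty_selection_rejected(self, toy_table):
        with pytest.raises(ValueError):
            detection_frequency(toy_table, "missing")


class TestCensoredSummary:
    def test_all_detected_plain_statistics(self):
        t = make_table([(f"s{i}", "home", "A", v, "detected") for i, v in enumerate([1, 2, 3, 4])])
        row = censored_summary(t, "A", mdl=0.5)
        assert row.mean == pytest.approx(2.5)
        assert row.p50 == pytest.approx(2.5)

    def test_default_policy_zero_nd(self, toy_table):
        row = censored_summary(toy_table, "A", mdl=1.0, policy="nd_zero_half_mdl")
        assert row.mean == pytest.approx(1.5)  # (0 + 0 + 2 + 4) / 4

    def test_mdl_over_sqrt2_policy(self, toy_table):
        row = censored_summary(toy_table, "A", mdl=1.0, policy="mdl_sqrt2")
        assert row.mean == pytest.approx((2 / math.sqrt(2) + 6) / 4, abs=1e-4)
        assert row.mean == pytest.approx(1.8536, abs=1e-4)

    def test_unknown_policy_rejected(self, toy_table):
        with pytest.raises(ValueError):
            censored_summary(toy_table, "A", mdl=1.0, policy="nope")

    def test_percentiles_ordered_and_reorder_invariant(self, rng):
        vals = rng.lognormal(1, 1, 50)
        rows = [(f"s{i}", "home", "A", v, "detected") for i, v in enumerate(vals)]
        a = censored_summary(make_table(rows), "A", mdl=0.0)
        b = censored_summary(make_table(rows[::-1]), "A", mdl=0.0)
        assert (a.min, a.p25, a.p50, a.p75, a.p90, a.max) == (
            b.min, b.p25, b.p50, b.p75, b.p90, b.max,
        )
        assert a.min <= a.p25 <= a.p50 <= a.p75 <= a.p90 <= a.max

    @given(
        pairs=st.lists(
            st.tuples(
                st.floats(0.01, 50.0),
                st.sampled_from(["detected", "below_mdl", "not_detected"]),
            ),
            min_size=1,
            max_size=6,
        ),
        mdl=st.floats(0.1, 5.0),
        policy=st.sampled_from(["nd_zero_half_mdl", "zero_all", "mdl_sqrt2"]),
    )
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence_on_small_tables(self, pairs, mdl, policy):
        """Mean and every percentile agree with brute-force recomputation on
        tables of up to six records."""
        pairs = [
            (0.0, f) if f == "not_detected" else (v, f) for v, f in pairs
        ]
        rows = [(f"s{i}", "home", "A", v, f) for i, (v, f) in enumerate(pairs)]
        row = censored_summary(make_table(rows), "A", mdl=mdl, policy=policy)
        expected = oracle_substitute(pairs, mdl, policy)
        assert row.mean == pytest.approx(np.mean(expected), rel=1e-9, abs=1e-12)
        for q, got in [(25, row.p25), (50, row.p50), (75, row.p75), (90, row.p90)]:
            assert got == pytest.approx(oracle_percentile(expected, q), rel=1e-9, abs=1e-12)


class TestCompositionProfile:
    def test_single_congener_is_all_of_it(self, mini_registry):
        prof = composition_profile({"A": 5.0}, mini_registry)
        assert prof.shares["A"] == pytest.approx(100.0)

    def test_shares_sum_to_100_after_rounding(self, mini_registry):
        prof = composition_profile({"A": 1.234, "B": 2.345, "C": 0.421}, mini_registry)
        assert sum(prof.shares.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(round(s, 1) for s in prof.shares.values()) == pytest.approx(100.0, abs=0.2)

    def test_class_aggregates_follow_family(self, mini_registry):
        prof = composition_profile({"A": 6.0, "B": 3.0, "C": 1.0}, mini_registry)
        assert prof.class_shares["chlorinated"] == pytest.approx(60.0)
        assert prof.class_shares["alkyl"] == pytest.approx(30.0)
        assert prof.class_shares["aryl"] == pytest.approx(10.0)

    def test_all_zero_means_rejected(self, mini_registry):
        with pytest.raises(ValueError):
            composition_profile({"A": 0.0, "B": 0.0}, mini_registry)


class TestSpearman:
    def _table(self, x, y):
        rows = [(f"s{i}", "car", "A", v, "detected") for i, v in enumerate(x)]
        rows += [(f"s{i}", "car", "B", v, "detected") for i, v in enumerate(y)]
        return make_table(rows)

    def test_monotone_pair_is_perfectly_correlated(self, mini_registry):
        r, p = spearman_matrix(self._table([1, 2, 3, 4, 5], [2, 4, 9, 16, 30]),
                               mini_registry, min_df=0)
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_antimonotone_pair(self, mini_registry):
        r, _ = spearman_matrix(self._table([1, 2, 3, 4], [8, 6, 4, 2]),
                               mini_registry, min_df=0)
        assert r.loc["A", "B"] == pytest.approx(-1.0)

    def test_rank_formula_oracle(self, mini_registry):
        x, y = [1, 2, 3, 4, 5], [3, 1, 2, 5, 4]
        r, _ = spearman_matrix(self._table(x, y), mini_registry, min_df=0)
        assert r.loc["A", "B"] == pytest.approx(0.6)
        assert r.loc["A", "B"] == pytest.approx(oracle_spearman(x, y))

    def test_invariant_under_monotone_transform(self, mini_registry, rng):
        x = rng.lognormal(0, 1, 30)
        y = rng.lognormal(0, 1, 30)
        r1, _ = spearman_matrix(self._table(x, y), mini_registry, min_df=0)
        r2, _ = spearman_matrix(self._table(np.exp(x / 10), y**3), mini_registry, min_df=0)
        assert r1.loc["A", "B"] == pytest.approx(r2.loc["A", "B"], abs=1e-12)

    def test_symmetric_unit_diagonal(self, mini_registry, rng):
        x = rng.lognormal(0, 1, 20)
        y = rng.lognormal(0, 1, 20)
        r, p = spearman_matrix(self._table(x, y), mini_registry, min_df=0)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)
        assert float(r.loc["A", "B"]) <= 1.0 and float(r.loc["A", "B"]) >= -1.0

    def test_low_df_congener_excluded(self, mini_registry):
        rows = [(f"s{i}", "car", "A", float(i + 1), "detected") for i in range(10)]
        rows += [(f"s{i}", "car", "B", 0.0, "not_detected") for i in range(10)]
        rows += [(f"s{i}", "car", "C", float(10 - i), "detected") for i in range(10)]
        r, _ = spearman_matrix(make_table(rows), mini_registry, min_df=25.0)
        assert "B" not in r.columns
        assert set(r.columns) == {"A", "C"}

    def test_too_few_pairs_flagged_nan(self, mini_registry):
        rows = [(f"s{i}", "car", "A", float(i + 1), "detected") for i in range(5)]
        rows += [("s0", "car", "B", 2.0, "detected"), ("s1", "car", "B", 1.0, "detected")]
        r, p = spearman_matrix(make_table(rows), mini_registry, min_df=0)
        assert math.isnan(r.loc["A", "B"]) and math.isnan(p.loc["A", "B"])


class TestCompareGroups:
    def _two_group_table(self, a, b):
        rows = [(f"h{i}", "home", "A", float(v), "detected") for i, v in enumerate(a)]
        rows += [(f"c{i}", "car", "A", float(v), "detected") for i, v in enumerate(b)]
        return make_table(rows)

    def test_identical_degenerate_groups_flagged(self, mini_registry):
        comp = compare_groups(self._two_group_table([1, 1, 1], [1, 1, 1]), mini_registry)
        assert set(comp.degenerate) == {"home", "car"}
        assert not comp.pairwise["significant"].any()

    def test_type_one_error_rate_near_alpha(self, mini_registry, rng):
        """Two groups from the same lognormal: rejection rate ~ 5%."""
        rejections = 0
        n_rep, n = 500, 200
        for _ in range(n_rep):
            a = rng.lognormal(1.0, 0.8, n)
            b = rng.lognormal(1.0, 0.8, n)
            comp = compare_groups(self._two_group_table(a, b), mini_registry)
            rejections += int(comp.pairwise["p"].iloc[0] < 0.05)
        assert rejections / n_rep == pytest.approx(0.05, abs=0.025)

    def test_detects_car_excess_at_campaign_scale(self, config, registry):
        """Generator defaults: cars carry ~6x the home total; ANOVA must see it."""
        from opeair import generate_site_table

        table = generate_site_table(config.generator_specs(), seed=17)
        comp = compare_groups(table, registry, config.stats.policy)
        assert comp.anova_p < 0.05
        assert comp.group_means["car"] > comp.group_means["home"]
        pair = comp.pairwise.set_index(["group_a", "group_b"])
        assert pair.loc[("home", "car"), "significant"]


class TestPerSiteTotals:
    def test_totals_sum_substituted_congeners(self, mini_registry):
        rows = [
            ("s1", "home", "A", 2.0, "detected"),
            ("s1", "home", "B", 0.4, "below_mdl"),
            ("s2", "home", "A", 1.0, "detected"),
            ("s2", "home", "B", 0.0, "not_detected"),
        ]
        totals = per_site_totals(make_table(rows), mini_registry)
        # B below_mdl -> mdl/2 = 0.5 ; not_detected -> 0
        assert sorted(totals) == pytest.approx([1.0, 2.5])

    def test_substitute_values_policies(self):
        values = np.array([3.0, 0.4, 0.0])
        flags = np.array(["detected", "below_mdl", "not_detected"])
        assert substitute_values(values, flags, 1.0, "nd_zero_half_mdl") == pytest.approx(
            [3.0, 0.5, 0.0]
        )
        assert substitute_values(values, flags, 1.0, "zero_all") == pytest.approx(
            [3.0, 0.0, 0.0]
        )
        got = substitute_values(values, flags, 1.0, "detected_only")
        assert got == pytest.approx([3.0])
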
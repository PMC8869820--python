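"""Aggregation, Pearson screening, bootstrap and subgroup machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from holocyte import (aggregate_sample, bh_adjust, bootstrap_stability,
                      bootstrap_stability_family, day_difference,
                      expected_missing_fraction, pearson_matrix,
                      subgroup_compare)
from holocyte.morpho import CellMeasurement
from holocyte.stats import significance_stars


def _cell(v, n=1.3497, label="lymphocyte"):
    return CellMeasurement(n_cell=n, radius_um=(3 * v / (4 * np.pi)) ** (1 / 3),
                           center_um=(0, 0), volume_um3=v,
                           dry_mass_pg=v / 0.2 * (n - 1.337),
                           area_um2=1.0, perimeter_um=1.0, ff=0.97,
                           residual_rms=0.01, label=label)


class TestAggregate:
    def test_identical_cells_have_zero_sd(self):
        agg = aggregate_sample([_cell(210.0)] * 150)
        assert agg.n_cells == 150
        assert agg.means["V_um3"] == 210.0
        assert agg.sds["V_um3"] == 0.0

    def test_hand_computed_mean_and_sd(self):
        agg = aggregate_sample([_cell(v) for v in (100.0, 200.0, 300.0)])
        assert agg.means["V_um3"] == 200.0
        assert agg.sds["V_um3"] == 100.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            aggregate_sample([])


class TestDayDifference:
    @staticmethod
    def _table():
        rows = []
        for pid, (v0, v1) in enumerate([(208, 218), (200, 205), (215, 230)]):
            rows.append({"patient_id": pid, "timepoint": "PreOP",
                         "cell_type": "lymphocyte", "V_mean_um3": v0})
            rows.append({"patient_id": pid, "timepoint": "d1",
                         "cell_type": "lymphocyte", "V_mean_um3": v1})
        return pd.DataFrame(rows)

    def test_same_timepoint_gives_zero(self):
        d, dropped = day_difference(self._table(), "d1", "d1", "V_mean_um3",
                                    "lymphocyte")
        assert (d == 0).all() and dropped == 0

    def test_worked_difference(self):
        d, _ = day_difference(self._table(), "d1", "PreOP", "V_mean_um3",
                              "lymphocyte")
        assert d.loc[0] == 10.0

    def test_missing_timepoint_dropped_and_counted(self):
        t = self._table()
        t = t[~((t.patient_id == 2) & (t.timepoint == "d1"))]
        d, dropped = day_difference(t, "d1", "PreOP", "V_mean_um3",
                                    "lymphocyte")
        assert len(d) == 2 and dropped == 1

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError):
            day_difference(self._table(), "d9", "PreOP", "V_mean_um3")


class TestPearson:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        (res,) = pearson_matrix(df)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance_sign(self):
        x = np.linspace(0, 1, 30)
        for a in (2.5, -0.7):
            df = pd.DataFrame({"x": x, "y": a * x + 3.0})
            (res,) = pearson_matrix(df)
            assert res.r == pytest.approx(np.sign(a), abs=1e-12)

    def test_constant_column_skipped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        assert pearson_matrix(df) == []

    def test_pairwise_complete_deletion(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, np.nan, 5],
                           "b": [2.0, 4, 6, 8, np.nan]})
        (res,) = pearson_matrix(df)
        assert res.n == 3

    def test_null_calibration_type_one_rate(self):
        # independent columns, n=25: two-sided test rejects at ~alpha
        rng = np.random.default_rng(2024)
        n_sims, n = 10_000, 25
        x = rng.standard_normal((n_sims, n))
        y = rng.standard_normal((n_sims, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        from scipy.stats import t as tdist
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * tdist.sf(np.abs(tstat), n - 2)
        rate = (p < 0.05).mean()
        assert 0.045 <= rate <= 0.055

    def test_sorted_by_absolute_r(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        df = pd.DataFrame({
            "x": x,
            "strong": -x + 0.1 * rng.standard_normal(200),
            "weak": 0.3 * x + rng.standard_normal(200),
        })
        res = pearson_matrix(df)
        assert [abs(r.r) for r in res] == sorted([abs(r.r) for r in res],
                                                 reverse=True)


class TestBootstrap:
    def test_constant_sample_is_perfectly_stable(self):
        res = bootstrap_stability(np.full(150, 3.14), n_boot=2000, seed=0)
        assert res.sample_p == 0.0

    def test_normal_sample_matches_clt_closed_form(self):
        # resample mean SD ~ sigma/sqrt(n); P(outside 0.3*SD corridor)
        # ~ 2*Phi(-0.3*sqrt(150)) ~ 2.4e-4
        rng = np.random.default_rng(77)
        values = rng.standard_normal(150)
        res = bootstrap_stability(values, n_boot=100_000, seed=1)
        closed_form = 2 * norm.cdf(-0.3 * np.sqrt(150))
        assert closed_form == pytest.approx(2.4e-4, abs=3e-5)
        assert res.sample_p < 0.005
        assert res.sample_p == pytest.approx(closed_form, abs=2e-3)

    def test_expected_missing_fraction_at_150(self):
        assert expected_missing_fraction(150) == pytest.approx(0.367, abs=5e-4)
        # simulation cross-check of the closed form
        rng = np.random.default_rng(3)
        fractions = [
            1 - np.unique(rng.integers(0, 150, 150)).size / 150
            for _ in range(2000)
        ]
        assert np.mean(fractions) == pytest.approx(
            expected_missing_fraction(150), abs=0.005)

    def test_monotone_in_corridor_width(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal(40)
        ps = [bootstrap_stability(values, n_boot=5000, corridor_sd=c,
                                  seed=11).sample_p
              for c in (0.05, 0.1, 0.2, 0.3, 0.5)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_deterministic_under_seed(self):
        values = np.random.default_rng(1).normal(size=30)
        a = bootstrap_stability(values, n_boot=1000, seed=42).sample_p
        b = bootstrap_stability(values, n_boot=1000, seed=42).sample_p
        assert a == b

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_stability(np.array([1.0]))

    def test_family_adjustment_never_below_raw(self):
        rng = np.random.default_rng(4)
        samples = {f"s{i}": rng.normal(size=20) for i in range(5)}
        res = bootstrap_stability_family(samples, n_boot=2000, seed=8)
        for r in res.values():
            assert r.bh_adjusted_p >= r.sample_p


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        # p=(0.01,0.02,0.03): p_(k)*m/k = (0.03,0.03,0.03) after monotone pass
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_adjusted_at_least_raw_and_permutation_equivariant(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = bh_adjust(np.asarray(ps)[perm])
        assert np.allclose(adj_perm, adj[perm])


class TestSubgroupCompare:
    def test_identical_groups_not_significant(self):
        vals = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 4))
        group = pd.Series([True] * 8 + [False] * 8)
        res = subgroup_compare(vals, group)
        assert res.difference == pytest.approx(0.0)
        assert res.p > 0.9

    def test_power_for_two_pooled_sd_shift(self):
        # groups shifted by 2 pooled SDs, n=8 vs 16: detection in >90% of seeds
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = pd.Series(np.concatenate([rng.normal(2.0, 1.0, 8),
                                             rng.normal(0.0, 1.0, 16)]))
            group = pd.Series([True] * 8 + [False] * 16)
            if subgroup_compare(vals, group).p < 0.05:
                hits += 1
        assert hits / n_seeds > 0.9

    def test_null_calibration(self):
        rejections = 0
        n_sims = 2000
        for seed in range(n_sims):
            rng = np.random.default_rng(10_000 + seed)
            vals = pd.Series(rng.standard_normal(25))
            group = pd.Series([True] * 9 + [False] * 16)
            if subgroup_compare(vals, group).p < 0.05:
                rejections += 1
        assert rejections / n_sims == pytest.approx(0.05, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            subgroup_compare(pd.Series([1.0, 2.0]), pd.Series([True, True]))

    def test_mannwhitney_variant(self):
        rng = np.random.default_rng(6)
        vals = pd.Series(np.concatenate([rng.normal(3, 1, 10),
                                         rng.normal(0, 1, 10)]))
        group = pd.Series([True] * 10 + [False] * 10)
        assert subgroup_compare(vals, group, test="mannwhitney").p < 0.01


def test_significance_star_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.2) == ""
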
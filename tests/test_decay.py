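"""Decay-course estimators: worked example, oracles, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promcoupling import decay, synthetic

from conftest import LN2, make_kinetics

positive = st.floats(min_value=1e-3, max_value=1e3,
                     allow_nan=False, allow_infinity=False)


class TestDeltaSwap:
    @pytest.mark.parametrize(
        "quad,expected", [((1, 1, 1, 1), 0.0), ((4, 1, 2, 1), 1.0)]
    )
    def test_examples(self, quad, expected):
        assert decay.delta_swap(*quad) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(positive, positive, positive, positive)
    def test_log_space_identity(self, sg, wg, sr, wr):
        expected = np.log2(sg) - np.log2(wg) - np.log2(sr) + np.log2(wr)
        assert decay.delta_swap(sg, wg, sr, wr) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(positive, positive, positive, positive)
    def test_antisymmetric_under_role_exchange(self, sg, wg, sr, wr):
        assert decay.delta_swap(sg, wg, sr, wr) == pytest.approx(
            -decay.delta_swap(sr, wr, sg, wg)
        )

    def test_nonpositive_level_names_offender(self):
        with pytest.raises(ValueError, match="wt_ref"):
            decay.delta_swap(1, 1, 1, 0)


class TestFitDecaySlope:
    def test_methods_worked_example(self):
        # ratio halves each 20 min: slope -0.05/min
        fit = decay.fit_decay_slope([0, 20, 40, 60], [0, -1, -2, -3])
        assert fit.slope == pytest.approx(-0.05)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        # implied relative level after 20 minutes is 2**(slope*20) = 0.5
        assert 2.0 ** (fit.slope * 20) == pytest.approx(0.5)

    def test_constant_ratio_gives_zero_slope(self):
        fit = decay.fit_decay_slope([0, 20, 40], [0.7, 0.7, 0.7])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        t = np.repeat([0.0, 20, 40, 60], 3)
        y = -0.03 * t + rng.normal(0, 0.2, t.size)
        fit = decay.fit_decay_slope(t, y)
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.slope == pytest.approx(beta[1])

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_slope_invariant_to_constant_shift(self, shift):
        t = [0, 20, 40, 60]
        y = np.array([0.1, -0.8, -2.2, -2.9])
        assert decay.fit_decay_slope(t, y + shift).slope == pytest.approx(
            decay.fit_decay_slope(t, y).slope
        )

    def test_mean_mode_equals_pooled_for_balanced_replicates(self):
        rng = np.random.default_rng(1)
        t = np.tile([0.0, 20, 40, 60], 3)
        y = -0.04 * t + rng.normal(0, 0.1, t.size)
        assert decay.fit_decay_slope(t, y, mode="mean").slope == pytest.approx(
            decay.fit_decay_slope(t, y, mode="pooled").slope
        )

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            decay.fit_decay_slope([20, 20], [0, 1])


class TestDeltaDeg:
    def test_zero_slope_gives_zero_effect(self):
        assert decay.delta_deg(0.0, 37.0) == 0.0

    def test_twofold_example(self):
        # slope -0.05 with t_half 20: (0.05+0.05)/0.05 = 2
        assert decay.delta_deg(-0.05, 20.0) == pytest.approx(1.0)

    def test_implied_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            decay.delta_deg(0.06, 20.0)

    def test_noiseless_recovery_of_rate_ratio(self):
        # kinetic identity: slope = -(k_SW - k_WT)/ln2, 1/t_half = k_WT/ln2
        k_wt = LN2 / 20.0
        for ratio in (0.5, 1.3, 2.0, 4.0):
            kin = make_kinetics(["g"], 1.0, k_wt, k_deg_2=k_wt * ratio)
            tc = synthetic.simulate_decay_timecourse(
                kin, [0, 20, 40, 60], n_replicates=1
            )
            piv = tc.pivot_table(index="time_min", columns="strain",
                                 values="level")
            fit = decay.fit_decay_slope(
                piv.index, np.log2(piv["SW"] / piv["WT"])
            )
            t_half_wt = LN2 / k_wt
            assert decay.delta_deg(fit.slope, t_half_wt) == pytest.approx(
                np.log2(ratio), abs=1e-9
            )


class TestIntervalChanges:
    def test_constant_levels_give_zeros(self):
        s = pd.Series([2.0, 2.0, 2.0, 2.0], index=[0, 20, 40, 60])
        np.testing.assert_allclose(decay.interval_changes(s), 0.0)

    def test_halving_gives_minus_one(self):
        s = pd.Series([8.0, 4.0, 2.0, 1.0], index=[0, 20, 40, 60])
        out = decay.interval_changes(s)
        np.testing.assert_allclose(out, -1.0)
        assert list(out.index) == [0, 20, 40]

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.5, 4.0, 5)
        s = pd.Series(vals, index=[0, 20, 40, 60, 80])
        out = decay.interval_changes(s)
        np.testing.assert_allclose(out, np.log2(vals[1:] / vals[:-1]))

    def test_missing_grid_point_omitted(self, caplog):
        s = pd.Series([4.0, 2.0, 1.0], index=[0, 20, 60])
        with caplog.at_level("WARNING"):
            out = decay.interval_changes(s)
        assert list(out.index) == [0]  # 20->40 missing, 40->60 unstartable
        assert "omitted" in caplog.text


def _course(levels_by_rep):
    rows = []
    for rep, series in levels_by_rep.items():
        for t, lv in series.items():
            rows.append((rep, float(t), lv))
    return pd.DataFrame(rows, columns=["replicate", "time_min", "level"])


class TestPairedIntervalTest:
    def test_identical_courses_give_p_one(self):
        c = _course({1: {0: 4, 20: 2, 40: 1, 60: 0.5}})
        t, p = decay.paired_interval_test(c, c)
        assert (t, p) == (0.0, 1.0)

    def test_textbook_one_sample_t(self):
        # SW halves per interval relative to WT with slight jitter:
        # differences {-1,-1,-1,-0.9,-1.1,-1.0}; hand computation gives
        # t = -1.0 / (0.0632456/sqrt(6)) = -38.7298, p = 2.16e-7 (df=5)
        wt = _course({1: {0: 1, 20: 1, 40: 1, 60: 1},
                      2: {0: 1, 20: 1, 40: 1, 60: 1}})
        sw_lv1 = {0: 1.0}
        for t0, d in zip((20, 40, 60), (-1.0, -1.0, -1.0)):
            sw_lv1[t0] = sw_lv1[t0 - 20] * 2.0 ** d
        sw_lv2 = {0: 1.0}
        for t0, d in zip((20, 40, 60), (-0.9, -1.1, -1.0)):
            sw_lv2[t0] = sw_lv2[t0 - 20] * 2.0 ** d
        sw = _course({1: sw_lv1, 2: sw_lv2})
        t, p = decay.paired_interval_test(sw, wt)
        assert t == pytest.approx(-38.7298334621, rel=1e-9)
        assert p == pytest.approx(2.1626e-07, rel=1e-3)

    def test_too_few_differences_rejected(self):
        c = _course({1: {0: 1, 20: 2}})
        with pytest.raises(ValueError, match=">= 2"):
            decay.paired_interval_test(c, c)

    def test_bulk_path_matches_scalar(self):
        scen = synthetic.CouplingScenario(model="independent", n_genes=5, seed=6)
        kin = synthetic.simulate_kinetics(scen, t_half_median=20.0)
        tc = synthetic.simulate_decay_timecourse(
            kin, [0, 20, 40, 60], sd_noise=0.15, n_replicates=2, seed=6
        )
        bulk = decay.paired_interval_tests_bulk(tc)
        for gene in kin["gene"]:
            sub = tc[tc["gene"] == gene]
            sw = sub[sub["strain"] == "SW"][["replicate", "time_min", "level"]]
            wt = sub[sub["strain"] == "WT"][["replicate", "time_min", "level"]]
            t, p = decay.paired_interval_test(sw, wt)
            assert bulk.loc[gene, "t_statistic"] == pytest.approx(t)
            assert bulk.loc[gene, "p_value"] == pytest.approx(p)

    def test_null_calibration_is_conservative(self):
        # Consecutive 20-min intervals share a level measurement, so the
        # paired differences have lag-1 autocorrelation -0.5 and the t-test
        # under-rejects: Monte-Carlo rate ~0.006 at nominal alpha 0.05.
        scen = synthetic.CouplingScenario(model="noise", n_genes=4000, seed=11)
        kin = synthetic.simulate_kinetics(scen, t_half_median=20.0,
                                          t_half_sd_log2=0.5)
        tc = synthetic.simulate_decay_timecourse(
            kin, [0, 20, 40, 60], sd_noise=0.1, n_replicates=2, seed=11
        )
        rate = (decay.paired_interval_tests_bulk(tc)["p_value"] <= 0.05).mean()
        assert 0.0 < rate < 0.02

    def test_power_above_080_at_spec_alternative(self):
        # |slope| = 0.025/min -> k_SW = k_WT + 0.025*ln2
        k_wt = LN2 / 20.0
        genes = [f"g{i}" for i in range(800)]
        kin = make_kinetics(genes, 1.0, k_wt, k_deg_2=k_wt + 0.025 * LN2)
        tc = synthetic.simulate_decay_timecourse(
            kin, [0, 20, 40, 60], sd_noise=0.1, n_replicates=2, seed=12
        )
        power = (decay.paired_interval_tests_bulk(tc)["p_value"] <= 0.05).mean()
        assert power > 0.8


class TestClassification:
    @pytest.mark.parametrize(
        "slope,p,expected",
        [
            (-0.05, 0.01, decay.INCREASED),
            (0.03, 0.5, decay.NOT_SIGNIFICANT),
            (0.03, 0.04, decay.DECREASED),
        ],
    )
    def test_effect_rules(self, slope, p, expected):
        assert decay.classify_effect(slope, p) == expected

    @pytest.mark.parametrize(
        "d,expected", [(1.0, True), (0.2, False), (-0.49, True)]
    )
    def test_steady_state_threshold(self, d, expected):
        assert decay.steady_state_effect_significance(d) is expected


class TestFitQuality:
    def test_perfect_exponential_scores_one(self):
        t = np.array([0, 20, 40, 60.0])
        assert decay.exponential_fit_quality(t, 8 * 0.5 ** (t / 20)) == \
            pytest.approx(1.0)

    def test_select_all_with_fraction_one(self):
        scores = pd.Series([0.2, 0.9, 0.5], index=list("abc"))
        assert set(decay.select_best_fit(scores, 1.0)) == {"a", "b", "c"}

    def test_best_fit_filter_finds_clean_decays(self):
        # 12 noiseless + 88 heavily noised genes; the noiseless ones win
        rng = np.random.default_rng(13)
        t = np.array([0, 20, 40, 60.0])
        scores = {}
        for i in range(100):
            clean = 4.0 * 0.5 ** (t / 25)
            noisy = clean * 2 ** rng.normal(0, 0.0 if i < 12 else 1.0, t.size)
            scores[f"g{i:03d}"] = decay.exponential_fit_quality(t, noisy)
        keep = decay.select_best_fit(pd.Series(scores), 0.12)
        assert set(keep) == {f"g{i:03d}" for i in range(12)}

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            decay.exponential_fit_quality([0, 20], [1.0, 0.5])


class TestReferenceNormalization:
    def _table(self, factor_by_time=None):
        k_g, k_r = LN2 / 20.0, LN2 / 40.0
        kin = make_kinetics(["g", "ref"], 1.0, [k_g, k_r],
                            k_deg_2=[2 * k_g, k_r])
        tc = synthetic.simulate_decay_timecourse(
            kin, [0, 20, 40, 60], n_replicates=2
        )
        if factor_by_time:
            for t0, f in factor_by_time.items():
                tc.loc[tc["time_min"] == t0, "level"] *= f
        return tc

    def test_common_factor_per_timepoint_cancels(self):
        plain = self._table()
        scaled = self._table({20: 3.0, 40: 0.2})
        for tab in (plain, scaled):
            r = decay.normalized_ratio_course(tab, "g", "ref")
            fit = decay.fit_decay_slope(r["time_min"], r["log2_ratio"])
            assert fit.slope == pytest.approx(-LN2 / 20.0 / LN2, abs=1e-9)
        a = decay.normalized_ratio_course(plain, "g", "ref")
        b = decay.normalized_ratio_course(scaled, "g", "ref")
        np.testing.assert_allclose(a["log2_ratio"], b["log2_ratio"])

    def test_analyze_gene_end_to_end(self):
        tab = self._table()
        eff = decay.analyze_gene(tab, "g", "ref", t_half=20.0)
        # k doubled: delta_deg = 1, SW decays faster -> increased
        assert eff.delta_deg == pytest.approx(1.0, abs=1e-9)
        assert eff.classification == decay.INCREASED
        assert eff.p_value < 0.05

    def test_circular_design_sums_to_unnormalized_ratios(self):
        # strains: WT, swap-of-A (B untouched), swap-of-B (A untouched)
        a_wt, a_sw = 2.0, 6.0
        b_wt, b_sw = 5.0, 2.5
        d_ab = decay.delta_swap(a_sw, a_wt, b_wt, b_wt)  # A vs ref B
        d_ba = decay.delta_swap(b_sw, b_wt, a_wt, a_wt)  # B vs ref A
        expected = np.log2((a_sw / a_wt) * (b_sw / b_wt))
        assert d_ab + d_ba == pytest.approx(expected)
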
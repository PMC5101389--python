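"""ICH validation statistics: linearity, sensitivity, accuracy/precision,
robustness, selectivity and the tablet assay."""

import numpy as np
import pandas as pd
import pytest

import chromdoe as cd
from chromdoe.datasets import (
    reference_calibration_table,
    reference_recovery_records,
    reference_recovery_table,
)
from chromdoe.simulator import (
    CalibrationSeries,
    MethodConditions,
    simulate_calibration,
    simulate_chromatogram,
    simulate_retention,
    simulate_tablet_sample,
)
from chromdoe.validation import (
    RecoveryRecord,
    RobustnessResult,
    assay_tablet,
    assess_accuracy,
    assess_precision,
    assess_selectivity,
    check_specification,
    fit_linearity,
    lod_loq_from_trace,
    loq_from_lod,
    recovery_records,
    relative_percent,
    robustness_ofat,
    t_critical,
)


class TestTCritical:
    @pytest.mark.parametrize("df, expected", [(7, 2.365), (9, 2.262)])
    def test_tabulated_values(self, df, expected):
        assert round(t_critical(0.05, df), 3) == expected

    def test_normal_limit(self):
        assert t_critical(0.05, 10**6) == pytest.approx(1.960, abs=0.01)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            t_critical(0.05, 0)


class TestLinearity:
    def test_perfect_line_through_origin(self):
        series = CalibrationSeries(
            "x", np.linspace(0.1, 1.0, 9), (24.0 * np.linspace(0.1, 1.0, 9))[:, None]
        )
        fit = fit_linearity(series)
        assert fit.r == pytest.approx(1.0)
        assert fit.t == pytest.approx(0.0, abs=1e-6)
        assert fit.passed

    def test_df_defaults_to_points_minus_two_and_is_overridable(self):
        series = simulate_calibration("impurity_a", seed=0)
        fit = fit_linearity(series)
        assert fit.df == 7
        fit9 = fit_linearity(series, df_override=9)
        assert fit9.df == 9 and fit9.t_crit == pytest.approx(t_critical(0.05, 9))

    def test_real_intercept_detection_matches_noncentral_t_power(self):
        """An intercept three times its own standard error is flagged at the
        rate the noncentral-t power calculation predicts (~73 % at df 7)."""
        from scipy import stats as st

        levels = np.linspace(0.1, 1.0, 9)
        slope = 25.0
        rng = np.random.default_rng(8)
        sigma = 0.2
        # SE of the OLS intercept for this x-grid and noise level
        n = len(levels)
        se_int = sigma * np.sqrt(1 / n + levels.mean() ** 2 /
                                 ((levels - levels.mean()) ** 2).sum())
        intercept = 3.0 * se_int
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = slope * levels + intercept + rng.normal(0, sigma, n)
            series = CalibrationSeries("x", levels, y[:, None])
            if not fit_linearity(series).pass_intercept:
                hits += 1
        tc = st.t.ppf(0.975, n - 2)
        power = 1 - st.nct.cdf(tc, n - 2, 3.0) + st.nct.cdf(-tc, n - 2, 3.0)
        # 200 Bernoulli trials: allow ~3.5 binomial SDs around the analytic power
        se = np.sqrt(power * (1 - power) / n_rep)
        assert abs(hits / n_rep - power) < 3.5 * se

    def test_too_few_levels_raise(self):
        with pytest.raises(ValueError):
            fit_linearity(CalibrationSeries("x", [1.0, 2.0], np.ones((2, 1))))

    def test_replicate_wise_regression(self):
        series = simulate_calibration("impurity_c", seed=1)
        fit = fit_linearity(series, on="replicates")
        assert fit.df == 9 * 3 - 2


class TestSensitivity:
    @pytest.mark.parametrize("lod, expected", [(0.012, 0.04), (0.024, 0.08), (0.3, 1.0)])
    def test_loq_from_lod_scaling(self, lod, expected):
        assert loq_from_lod(lod) == pytest.approx(expected)

    @pytest.mark.parametrize("conc, nominal, expected",
                             [(0.04, 100.0, 0.04), (0.0, 50.0, 0.0), (100.0, 100.0, 100.0)])
    def test_relative_percent(self, conc, nominal, expected):
        assert relative_percent(conc, nominal) == pytest.approx(expected)

    def test_lod_from_engineered_trace(self, truth):
        """A standard injected with S/N ≈ 30 at 0.12 µg/mL yields an LOD near
        0.012 µg/mL; the LOQ/LOD ratio is exactly 10/3 before rounding."""
        cond = MethodConditions()
        single = simulate_retention(truth, cond, noise=False,
                                    concentrations={"impurity_a": 0.12})
        height = single.height["impurity_a"]
        # engineer the baseline so that 2H/h == 30 given p-p noise ≈ 6.07 sigma
        # (median p-p of this window length, measured once offline)
        sigma = 2 * height / 30.0 / 6.07
        lods = []
        for seed in range(50):
            trace = simulate_chromatogram(single, sigma, seed=seed,
                                          include=("impurity_a",))
            tr, w = single.tr["impurity_a"], single.width["impurity_a"]
            res = lod_loq_from_trace(trace, (tr - w, tr + w), (0.2, 4.0),
                                     conc=0.12, round_sig=None)
            assert res.loq_conc / res.lod_conc == pytest.approx(10 / 3)
            lods.append(res.lod_conc)
        assert np.median(lods) == pytest.approx(0.012, rel=0.15)

    def test_doubling_concentration_doubles_sn_noiseless_peak(self, truth):
        cond = MethodConditions()
        rng_seed = 7
        sns = []
        for conc in (0.1, 0.2):
            single = simulate_retention(truth, cond, noise=False,
                                        concentrations={"impurity_b": conc})
            trace = simulate_chromatogram(single, 0.1, seed=rng_seed,
                                          include=("impurity_b",))
            tr, w = single.tr["impurity_b"], single.width["impurity_b"]
            res = lod_loq_from_trace(trace, (tr - w, tr + w), (0.2, 4.0),
                                     conc=conc, round_sig=None)
            sns.append(res.sn)
        assert sns[1] / sns[0] == pytest.approx(2.0, rel=0.05)

    def test_zero_noise_window_rejected(self, truth):
        cond = MethodConditions()
        single = simulate_retention(truth, cond, noise=False)
        trace = simulate_chromatogram(single, 0.0, include=("impurity_a",))
        tr, w = single.tr["impurity_a"], single.width["impurity_a"]
        with pytest.raises(ValueError, match="noise"):
            lod_loq_from_trace(trace, (tr - w, tr + w), (0.2, 4.0), conc=0.1)


class TestAccuracyPrecision:
    def test_all_published_rows_classified_pass(self):
        records = assess_precision(assess_accuracy(reference_recovery_records()))
        assert len(records) == 15
        assert all(r.pass_accuracy for r in records)
        assert all(r.pass_precision for r in records)

    def test_published_recovery_extremes(self):
        table = reference_recovery_table()
        impurities = table[table["compound"] != "moxonidine"]
        assert impurities["recovery_pct"].min() == pytest.approx(93.66)
        assert impurities["recovery_pct"].max() == pytest.approx(114.08)

    @pytest.mark.parametrize(
        "compound, role, nominal, recovery, expected",
        [
            ("moxonidine", "API", 100.0, 101.15, True),
            ("moxonidine", "API", 100.0, 97.0, False),     # below the 98-102 window
            ("impurity_c", "impurity", 1.0, 114.08, True),  # 1.0 % level, 80-120
            ("impurity_c", "impurity", 1.0, 121.0, False),
            ("impurity_a", "impurity", 0.04, 72.0, True),   # LOQ level, widest window
            ("impurity_a", "impurity", 0.04, 69.0, False),
        ],
    )
    def test_accuracy_windows(self, compound, role, nominal, recovery, expected):
        rec = RecoveryRecord(compound, "x", nominal, nominal * recovery / 100,
                             recovery, 1.0, role=role)
        assert assess_accuracy([rec])[0].pass_accuracy is expected

    @pytest.mark.parametrize(
        "compound, role, rsd, expected",
        [
            ("moxonidine", "API", 1.85, True),
            ("moxonidine", "API", 2.5, False),
            ("impurity_a", "impurity", 3.79, True),   # <= 15
            ("impurity_a", "impurity", 15.5, False),
            ("impurity_c", "impurity", 9.9, True),    # <= 10
            ("impurity_c", "impurity", 10.1, False),
        ],
    )
    def test_precision_thresholds(self, compound, role, rsd, expected):
        rec = RecoveryRecord(compound, "x", 1.0, 1.0, 100.0, rsd, role=role)
        assert assess_precision([rec])[0].pass_precision is expected

    def test_recovery_records_aggregation(self):
        samples = pd.DataFrame({
            "compound": ["impurity_a"] * 3,
            "level": ["100%"] * 3,
            "nominal_ug_ml": [0.5] * 3,
            "found_ug_ml": [0.50, 0.51, 0.49],
        })
        rec = recovery_records(samples)[0]
        assert rec.recovery_pct == pytest.approx(100.0)
        assert rec.rsd_pct == pytest.approx(100 * np.std([0.50, 0.51, 0.49], ddof=1) / 0.5)


class TestRobustness:
    def test_boundary_cases_of_the_pass_rule(self):
        base = dict(factor="acn_percent", delta=0.5)
        assert RobustnessResult(**base, area_change_pct=4.99, tr_change_pct=2.99,
                                rs_change_pct=2.99).passed
        assert not RobustnessResult(**base, area_change_pct=5.01, tr_change_pct=0,
                                    rs_change_pct=0).passed
        assert not RobustnessResult(**base, area_change_pct=0, tr_change_pct=3.01,
                                    rs_change_pct=0).passed
        assert not RobustnessResult(**base, area_change_pct=0, tr_change_pct=0,
                                    rs_change_pct=3.01).passed

    def test_zero_deltas_change_nothing(self, truth):
        results = robustness_ofat(truth, plan=(("ph", 0.0), ("flow", 0.0)))
        for r in results:
            assert r.area_change_pct == pytest.approx(0.0, abs=1e-12)
            assert r.tr_change_pct == pytest.approx(0.0, abs=1e-12)
            assert r.passed

    def test_default_plan_passes_at_the_optimum(self, truth):
        """The method is robust: all eight standard perturbations stay inside
        the 5 % / 3 % / 3 % windows."""
        results = robustness_ofat(truth)
        assert len(results) == 8
        assert all(r.passed for r in results)

    def test_exaggerated_acn_shift_fails(self, truth):
        results = robustness_ofat(truth, plan=(("acn_percent", 5.0),))
        assert not results[0].passed


class TestSelectivity:
    def _flat_trace(self):
        t = np.linspace(0, 12, 2000)
        return pd.DataFrame({"time_min": t, "signal": np.zeros_like(t)})

    def test_flat_placebo_passes(self):
        result = assess_selectivity(self._flat_trace(), {"a": (5.0, 6.0)}, {"a": 10.0})
        assert result == {"a": True}

    def test_interferent_at_analyte_window_fails(self):
        trace = self._flat_trace()
        t = trace["time_min"].to_numpy()
        trace["signal"] = 8.0 * np.exp(-0.5 * ((t - 5.5) / 0.05) ** 2)
        result = assess_selectivity(trace, {"a": (5.0, 6.0)}, {"a": 10.0})
        assert result == {"a": False}

    def test_infinite_threshold_always_passes(self):
        trace = self._flat_trace()
        trace["signal"] += 100.0
        result = assess_selectivity(trace, {"a": (5.0, 6.0)}, {"a": 10.0},
                                    threshold=np.inf)
        assert result == {"a": True}

    def test_window_outside_trace_raises(self):
        with pytest.raises(ValueError):
            assess_selectivity(self._flat_trace(), {"a": (20.0, 21.0)}, {"a": 1.0})


class TestAssay:
    def _calibrations(self, truth):
        cals = {}
        for name in ("moxonidine", "impurity_a", "impurity_b", "impurity_c",
                     "impurity_d"):
            series = simulate_calibration(name, noise_model=(0.0, 0.0), seed=0)
            cals[name] = fit_linearity(series)
        return cals

    def test_simulated_contents_recovered(self, truth):
        """The assay pipeline recovers the simulated tablet composition well
        within twice the response noise."""
        contents = {"moxonidine": 97.5, "impurity_c": 0.68, "impurity_d": 0.87}
        rsd = 0.005
        sample = simulate_tablet_sample(contents, truth=truth, rsd_response=rsd,
                                        seed=11)
        results = assay_tablet(sample, self._calibrations(truth))
        for name, expected in contents.items():
            tolerance = 2 * rsd / np.sqrt(3) * expected
            assert results[name].content_percent == pytest.approx(
                expected, abs=tolerance
            )

    def test_zero_response_flags_below_detection(self, truth):
        sample = simulate_tablet_sample({"impurity_a": 0.0}, truth=truth, seed=0)
        sens = {"impurity_a": cd.SensitivityResult("impurity_a", 0.012, 0.04,
                                                   0.012, 0.04, "scaled_from_lod")}
        results = assay_tablet(sample[sample["compound"] == "impurity_a"],
                               self._calibrations(truth), sens)
        assert results["impurity_a"].below_loq and results["impurity_a"].below_lod

    def test_specification_check(self):
        def res(name, pct, below=False):
            return cd.validation.AssayResult(name, pct, pct, below, below)

        contents = {"impurity_a": res("impurity_a", 0.0, below=True),
                    "impurity_b": res("impurity_b", 0.0, below=True),
                    "impurity_c": res("impurity_c", 0.68),
                    "impurity_d": res("impurity_d", 0.87)}
        assert check_specification(contents)
        contents["impurity_c"] = res("impurity_c", 1.2)
        assert not check_specification(contents)
        assert check_specification({})


class TestReferenceTables:
    def test_calibration_table_matches_the_tabulated_t_values(self):
        table = reference_calibration_table()
        assert len(table) == 5
        # every published intercept t statistic is below its critical value
        assert (table["t"] < table["t_tab"]).all()
        # the tabulated critical values correspond to df 7 (API) and 9 (impurities)
        assert round(t_critical(0.05, 7), 3) == table.loc[0, "t_tab"]
        assert (table.loc[1:, "t_tab"] == round(t_critical(0.05, 9), 3)).all()
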
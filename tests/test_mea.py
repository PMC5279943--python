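"""Rate correction, dose-response, Hill fits, arrhythmia, QC and mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qtsens as q
from qtsens.mea import BeatSeries, fit_hill, hill_curve


def _series(ibi, fpd, line="L1", conc=0.0):
    return BeatSeries(line_id=line, concentration=conc, ibi=np.asarray(ibi, float),
                      raw_fpd=np.asarray(fpd, float))


def _powerlaw_series(alpha, n=200, seed=0, cv=0.0, fpd0=300.0, ibi_mean=1200.0, ibi_sd=150.0):
    rng = np.random.default_rng(seed)
    ibi = np.clip(rng.normal(ibi_mean, ibi_sd, n), 300, None)
    fpd = fpd0 * (ibi / 1000.0) ** alpha
    if cv:
        fpd = fpd * (1 + rng.normal(0, cv, n))
    return _series(ibi, fpd)


class TestRateCorrection:
    def test_noise_free_exponent_recovered_exactly(self):
        corr = q.fit_rate_correction(_powerlaw_series(0.35))
        assert corr.alpha == pytest.approx(0.35, abs=1e-10)
        assert corr.intercept == pytest.approx(np.log(300.0), abs=1e-10)

    def test_noisy_recovery_within_tolerance(self):
        corr = q.fit_rate_correction(_powerlaw_series(0.35, cv=0.02, seed=1))
        assert abs(corr.alpha - 0.35) < 0.05

    def test_median_alpha_error_over_seeds(self):
        errs = [
            abs(q.fit_rate_correction(_powerlaw_series(0.35, cv=0.02, seed=s)).alpha - 0.35)
            for s in range(100)
        ]
        assert np.median(errs) < 0.05

    def test_bazett_overcorrects_smaller_true_exponent(self):
        """Adjusting α=0.35 data with the square-root exponent leaves a
        significant residual dependence of corrected FPD on rate."""
        s = _powerlaw_series(0.35, cv=0.02, seed=2)
        afpd = q.adjust_fpd(s.raw_fpd, s.ibi, 0.5)
        res = stats.linregress(s.ibi, afpd)
        assert res.slope < 0  # over-correction: corrected FPD falls with IBI
        assert res.pvalue < 1e-6

    def test_fitted_alpha_removes_rate_dependence(self):
        s = _powerlaw_series(0.35, cv=0.02, seed=3)
        corr = q.fit_rate_correction(s)
        assert corr.residual_slope_p > 0.01  # no residual trend on training data

    def test_degenerate_ibi_spread_raises(self):
        with pytest.raises(ValueError, match="degenerate IBI spread"):
            q.fit_rate_correction(_series([1000, 1000, 1000], [300, 301, 299]))


class TestAdjustFpd:
    def test_alpha_zero_is_identity(self):
        assert q.adjust_fpd(321.0, 888.0, 0.0) == pytest.approx(321.0)

    def test_one_second_ibi_is_identity_for_any_alpha(self):
        for alpha in (0.0, 1 / 3, 0.5, 1.0):
            assert q.adjust_fpd(250.0, 1000.0, alpha) == pytest.approx(250.0)

    def test_constant_ratio_in_noise_free_model(self):
        s = _powerlaw_series(0.35)
        ratio = s.raw_fpd / (s.ibi / 1000.0) ** 0.35
        assert np.allclose(ratio, ratio[0])


class TestDoseResponse:
    def test_change_arithmetic(self):
        corr = q.fit_rate_correction(_powerlaw_series(0.0))
        base = _series([1000] * 20, [250] * 20, conc=0.0)
        top = _series([1000] * 20, [325] * 20, conc=3e-5)
        dr = q.dose_response([base, top], corr)
        assert dr.change_at(3e-5) == pytest.approx(0.30)
        assert dr.change_at(0.0) == 0.0

    def test_identical_recordings_give_zero_change(self):
        corr = q.fit_rate_correction(_powerlaw_series(0.0))
        ss = [_series([1000] * 20, [250] * 20, conc=c) for c in (0.0, 1e-6, 1e-5)]
        dr = q.dose_response(ss, corr)
        assert np.allclose(dr.afpd_change, 0.0)
        assert dr.max_change == 0.0

    def test_missing_vehicle_raises(self):
        corr = q.fit_rate_correction(_powerlaw_series(0.0))
        with pytest.raises(ValueError, match="vehicle"):
            q.dose_response([_series([1000] * 20, [250] * 20, conc=1e-6)], corr)

    def test_recovered_change_at_ec50_near_half_emax(self):
        """Generator truth: mean aFPD change at c = EC50 ≈ Emax/2."""
        spec = q.MeaSpec(
            seed=9, concentrations=(0.0, 1e-6, 3e-6, 1e-5, 2e-5, 1e-4),
            arrhythmia_classes=(),
        )
        series, truth = q.simulate_mea(spec)
        by_line = {}
        for s in series:
            by_line.setdefault(s.line_id, []).append(s)
        highs = truth[truth["label"] == "high"]["line_id"]
        changes = []
        for lid in highs:
            ss = by_line[lid]
            corr = q.fit_rate_correction([s for s in ss if s.concentration == 0])
            changes.append(q.dose_response(ss, corr).change_at(2e-5))  # = high EC50
        assert np.mean(changes) == pytest.approx(spec.emax["high"] / 2, abs=0.05)


class TestHillFit:
    def test_noise_free_parameters_recovered(self):
        c = np.array([0.0, 1e-8, 5e-8, 2e-7, 1e-6, 5e-6])
        r = hill_curve(c, 0.5, 5e-8, 1.0)
        fit = fit_hill(c, r)
        assert fit.ec50 == pytest.approx(5e-8, rel=0.01)
        assert fit.emax == pytest.approx(0.5, rel=0.01)
        assert fit.hill_coef == pytest.approx(1.0, rel=0.01)

    def test_curve_at_ec50_is_half_emax(self):
        c = np.logspace(-8, -4, 6)
        r = hill_curve(c, 0.4, 1e-6, 1.7)
        fit = fit_hill(c, r)
        assert hill_curve(np.array([fit.ec50]), fit.emax, fit.ec50, fit.hill_coef)[0] == (
            pytest.approx(fit.emax / 2)
        )

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_hill(np.logspace(-8, -5, 5), np.zeros(5))

    def test_order_invariant(self):
        c = np.logspace(-8, -4, 6)
        r = hill_curve(c, 0.4, 1e-6, 1.0) + 1e-4
        perm = np.array([3, 0, 5, 1, 4, 2])
        f1 = fit_hill(c, r)
        f2 = fit_hill(c[perm], r[perm])
        assert f1.ec50 == pytest.approx(f2.ec50, rel=1e-6)

    def test_ec50_recovery_at_sparse_dose_sampling(self):
        """Median relative EC50 error < 20% with 5 doses and 2% noise."""
        c = np.array([0.0, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4])
        errs = []
        for s in range(100):
            rng = np.random.default_rng(s)
            r = hill_curve(c, 0.5, 2e-5, 1.0) + rng.normal(0, 0.01, c.size)
            fit = fit_hill(c, r)
            errs.append(abs(fit.ec50 - 2e-5) / 2e-5)
        assert np.median(errs) < 0.20


class TestArrhythmia:
    def _regular(self, n=50, ibi=1000.0):
        return _series([ibi] * n, [300] * n)

    def test_regular_beating_not_flagged(self):
        rng = np.random.default_rng(0)
        ibi = rng.normal(1000, 10, 60)
        call = q.detect_arrhythmia(_series(ibi, np.full(60, 300.0)), self._regular())
        assert not call.flag

    def test_single_short_beat_triggers_ectopic_rule(self):
        ibi = np.full(60, 1000.0)
        ibi[30] = 500.0  # 0.5 × median
        call = q.detect_arrhythmia(_series(ibi, np.full(60, 300.0)), self._regular())
        assert call.flag and call.ectopic

    def test_irregularity_rule_uses_cv(self):
        rng = np.random.default_rng(1)
        base = rng.normal(1000, 20, 60)  # CV 0.02
        post = np.clip(rng.normal(1000, 250, 60), 810, None)  # CV ≈ 0.25, no short beats
        call = q.detect_arrhythmia(
            _series(post, np.full(60, 300.0)), _series(base, np.full(60, 300.0))
        )
        assert call.flag and call.irregular and not call.ectopic

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            q.detect_arrhythmia(self._regular(5), self._regular())


class TestQcAndClassification:
    def test_seventeen_line_fixture_retains_fourteen(self):
        lines = q.load_fixture("lines")
        qc = q.qc_filter_lines(lines)
        kept = qc[qc["retained"]]
        assert len(kept) == 14
        assert (kept["group"] == "high").sum() == 7
        assert (kept["group"] == "low").sum() == 7
        dropped = qc[~qc["retained"]].set_index("line_id")["exclusion_reason"]
        assert dropped.loc["P11021"] == "e4031_non_responder"
        assert dropped.loc["P11023"] == "e4031_non_responder"
        assert dropped.loc["P11030"] == "abnormal_karyotype"

    def test_all_clean_is_identity_and_all_bad_empties(self):
        meta = pd.DataFrame(
            {"line_id": [f"L{i}" for i in range(17)], "karyotype_ok": True,
             "e4031_max_change": 0.4}
        )
        assert q.qc_filter_lines(meta)["retained"].all()
        meta["e4031_max_change"] = 0.0
        qc = q.qc_filter_lines(meta)
        assert (~qc["retained"]).all() and len(qc) == 17

    def test_classification_threshold_and_tie_rule(self, mea_panel):
        _, truth, _, responses = mea_panel
        labels = dict(zip(truth["line_id"], truth["label"]))
        cls = q.classify_lines(list(responses.values()), labels)
        assert set(cls["predicted"]) <= {"high", "low"}
        # explicit threshold arithmetic on constructed responses
        from qtsens.mea import DoseResponse

        def fake(line, change):
            return DoseResponse(line, np.array([0.0, 3e-5]), np.array([250.0, 250 * (1 + change)]),
                                np.array([0.0, change]), change, np.array([False, False]))

        out = q.classify_lines([fake("a", 0.30), fake("b", 0.20), fake("c", 0.25)], {})
        assert list(out["predicted"]) == ["high", "low", "low"]

    def test_calibrated_panel_classification_accuracy(self, mea_panel):
        """7 vs 7 calibrated lines: at least 12/14 correctly discriminated."""
        _, truth, _, responses = mea_panel
        labels = dict(zip(truth["line_id"], truth["label"]))
        cls = q.classify_lines(list(responses.values()), labels)
        assert cls["correct"].sum() >= 12


class TestMixedAnova:
    def _panel_response(self, mea_panel):
        _, truth, _, responses = mea_panel
        concs = list(responses.values())[0].concentrations
        resp = pd.DataFrame(
            {c: [responses[l].afpd_change[i] for l in responses] for i, c in enumerate(concs)},
            index=list(responses),
        )
        return resp, dict(zip(truth["line_id"], truth["label"]))

    def test_identical_groups_give_zero_group_f(self):
        block = np.array([[0.0, 0.1, 0.2], [0.05, 0.15, 0.3]])
        resp = pd.DataFrame(np.vstack([block, block]), index=["a1", "a2", "b1", "b2"])
        res = q.two_way_rm_anova(resp, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert res.f_group == pytest.approx(0.0, abs=1e-12)

    def test_ss_decomposition_sums_to_total(self, mea_panel):
        resp, groups = self._panel_response(mea_panel)
        res = q.two_way_rm_anova(resp, groups)
        assert res.table["ss"].sum() == pytest.approx(res.ss_total, rel=1e-10)

    def test_panel_effects_detected(self, mea_panel):
        resp, groups = self._panel_response(mea_panel)
        res = q.two_way_rm_anova(resp, groups)
        assert res.p_concentration < 0.0005
        assert res.p_group < 0.02

    def test_matches_pingouin_mixed_anova(self, mea_panel):
        pingouin = pytest.importorskip("pingouin")
        resp, groups = self._panel_response(mea_panel)
        long = resp.reset_index().melt(id_vars="index", var_name="conc", value_name="y")
        long["group"] = long["index"].map(groups)
        pg = pingouin.mixed_anova(
            data=long, dv="y", within="conc", subject="index", between="group"
        ).set_index("Source")
        res = q.two_way_rm_anova(resp, groups)
        assert res.f_group == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert res.f_concentration == pytest.approx(pg.loc["conc", "F"], rel=1e-6)
        assert res.f_interaction == pytest.approx(pg.loc["Interaction", "F"], rel=1e-6)

    def test_null_type_i_error_calibrated(self):
        """Pure-noise simulations keep each factor's rejection rate near 5%."""
        rng = np.random.default_rng(42)
        n_rep = 1000
        rej = np.zeros(3)
        groups = {f"l{i}": ("A" if i < 4 else "B") for i in range(8)}
        for _ in range(n_rep):
            resp = pd.DataFrame(rng.normal(size=(8, 4)), index=list(groups))
            res = q.two_way_rm_anova(resp, groups)
            rej += [res.p_group < 0.05, res.p_concentration < 0.05, res.p_interaction < 0.05]
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert np.all(np.abs(rej / n_rep - 0.05) <= 3 * se)

    def test_missing_cells_rejected(self):
        resp = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        resp.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            q.two_way_rm_anova(resp, dict(zip("abcd", "AABB")))
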
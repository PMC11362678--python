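"""Stabilized exposure and censoring weights: coefficient recovery,
mean-one diagnostics, hand-enumerated censoring weights and truncation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

import msmcurves as m
from msmcurves._glm import LogisticFit
from msmcurves.simulate import BASELINE_COVARIATES, WAVE2_COVARIATES
from msmcurves.weights import ExposureModels, WeightSet, build_design


def _randomized_cohort(n=20_000, seed=0):
    """Exposures assigned independently of all covariates."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "id": np.arange(n),
        "L": rng.standard_normal(n),
        "Lb": (rng.random(n) < 0.4).astype(float),
        "A1": (rng.random(n) < 0.3).astype(int),
        "A2": (rng.random(n) < 0.4).astype(int),
    })


class TestExposureModels:
    def test_randomized_exposure_coefficients_near_zero(self):
        """With randomized exposure every denominator covariate coefficient
        is within 3 standard errors of zero."""
        c = _randomized_cohort()
        models = m.fit_exposure_models(c, ["L", "Lb"], [], region_col=None)
        X, _ = build_design(c, ["L", "Lb"], None)
        ref = sm.GLM(c["A1"].to_numpy(float), X,
                     family=sm.families.Binomial()).fit()
        for j in (1, 2):
            assert abs(models.den_w1.params[j]) < 3 * ref.bse[j]

    def test_binary_confounder_logit_recovery(self):
        """P(A1|L=1)=0.8, P(A1|L=0)=0.2 gives intercept logit(0.2)=-1.386
        and slope logit(0.8)-logit(0.2)=2.772."""
        rng = np.random.default_rng(1)
        n = 50_000
        L = (rng.random(n) < 0.5).astype(float)
        A1 = (rng.random(n) < np.where(L == 1, 0.8, 0.2)).astype(int)
        c = pd.DataFrame({"id": np.arange(n), "L": L, "A1": A1,
                          "A2": (rng.random(n) < 0.3).astype(int)})
        models = m.fit_exposure_models(c, ["L"], [], region_col=None)
        est = models.den_w1.params_series()
        assert abs(est["const"] - (-1.386)) < 0.05
        assert abs(est["L"] - 2.772) < 0.07

    def test_numerator_intercept_is_sample_logit(self):
        c = _randomized_cohort(5_000, seed=2)
        models = m.fit_exposure_models(c, ["L"], [], region_col=None)
        p_hat = c["A1"].mean()
        assert abs(models.num_w1.params[0] - logit(p_hat)) < 1e-8

    def test_identical_num_den_design_gives_unit_weights(self):
        """When numerator and denominator share the design (no covariates)
        the stabilized weights are exactly 1."""
        c = _randomized_cohort(2_000, seed=3)
        models = m.fit_exposure_models(c, [], [], region_col=None)
        ws = m.compute_exposure_weights(models, c)
        np.testing.assert_allclose(ws.sw_A1, 1.0, atol=1e-10)
        np.testing.assert_allclose(ws.sw_A2, 1.0, atol=1e-10)

    def test_weight_ratio_arithmetic(self):
        """A subject with a1=1, P_num=0.5, P_den=0.8 gets sw = 0.625."""
        c = pd.DataFrame({"id": [0], "A1": [1], "A2": [0]})
        models = ExposureModels(
            den_w1=LogisticFit([logit(0.8)], ["const"], True, 1),
            num_w1=LogisticFit([logit(0.5)], ["const"], True, 1),
            den_w2=LogisticFit([logit(0.5), 0.0], ["const", "A1"], True, 1),
            num_w2=LogisticFit([logit(0.5), 0.0], ["const", "A1"], True, 1),
            baseline_covariates=[], timevarying_covariates=[], region_col=None)
        ws = m.compute_exposure_weights(models, c)
        assert ws.sw_A1[0] == pytest.approx(0.5 / 0.8)

    def test_mean_one_on_well_specified_simulation(self, benchmark_cohort_20k):
        models = m.fit_exposure_models(
            benchmark_cohort_20k, BASELINE_COVARIATES, WAVE2_COVARIATES)
        ws = m.compute_exposure_weights(models, benchmark_cohort_20k)
        assert 0.97 < np.mean(ws.sw_A1 * ws.sw_A2) < 1.03
        assert abs(np.mean(ws.sw_A1) - 1) < 0.05
        assert abs(np.mean(ws.sw_A2) - 1) < 0.05

    def test_positivity_floor_is_hard_error(self):
        c = _randomized_cohort(2_000, seed=4)
        models = m.fit_exposure_models(c, ["L"], [], region_col=None)
        with pytest.raises(m.PositivityError):
            m.compute_exposure_weights(models, c, positivity_floor=0.9)


class TestCensoringWeights:
    def test_no_censoring_degenerate_all_ones(self, small_cohort):
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        py["uncensored"] = 1
        models = m.fit_censoring_models(py, [], region_col=None)
        assert models.degenerate
        swc = m.compute_censoring_weights(models, py)
        np.testing.assert_array_equal(swc, 1.0)

    def test_independent_censoring_weights_near_one(self):
        """Censoring at a constant 5%/year independent of everything gives
        sw_C(k) ~ 1 for every k."""
        cfg = m.benchmark_config(20_000, seed=51,
                                 coef_cens={"const": float(logit(0.05))})
        c = m.generate_cohort(cfg)
        py = m.expand_person_years(c, 14, "all_cause",
                                   covariates=BASELINE_COVARIATES)
        models = m.fit_censoring_models(py, BASELINE_COVARIATES, region_col=None)
        swc = m.compute_censoring_weights(models, py)
        per_year = pd.Series(swc).groupby(py["k"].to_numpy()).mean()
        assert np.all(np.abs(per_year - 1) < 0.05)

    def test_hand_enumerated_single_period_weights(self):
        """One binary covariate, one period: P(censor|L=1)=0.5,
        P(censor|L=0)=0.25, P(L=1)=0.5.  Marginal P(uncensored)=0.625, so
        the stabilized weight is 0.625/0.5=1.25 for L=1 subjects and
        0.625/0.75=0.8333 for L=0 (hand enumeration of the four cells)."""
        reps = 80   # exact cell proportions, scaled up
        rows = []
        i = 0
        for L, cens, n in ((1, 1, 2), (1, 0, 2), (0, 1, 1), (0, 0, 3)):
            for _ in range(n * reps):
                rows.append({"id": i, "k": 1, "A1": 0, "A2": 0,
                             "uncensored": 1 - cens, "L": float(L)})
                i += 1
        py = pd.DataFrame(rows)
        models = m.fit_censoring_models(py, ["L"], region_col=None,
                                        time_terms="linear")
        swc = m.compute_censoring_weights(models, py)
        L = py["L"].to_numpy()
        np.testing.assert_allclose(swc[L == 1], 0.625 / 0.5, atol=1e-6)
        np.testing.assert_allclose(swc[L == 0], 0.625 / 0.75, atol=1e-6)

    def test_cumulative_recursion_identity(self, benchmark_cohort_20k):
        """sw_C(k) = sw_C(k-1) * ratio(k) exactly, by construction."""
        py = m.expand_person_years(benchmark_cohort_20k.head(3_000)
                                   .reset_index(drop=True), 14, "all_cause",
                                   covariates=["age", "smoking"])
        models = m.fit_censoring_models(py, ["age", "smoking"], region_col=None)
        swc = m.compute_censoring_weights(models, py)
        df = py[["id", "k"]].copy()
        df["swc"] = swc
        prev = df.groupby("id")["swc"].shift(1).fillna(1.0)
        ratio = df["swc"] / prev
        # recompute first-principles ratio from the fitted models
        from msmcurves.weights import _censoring_design
        Xn, _, Xd, _ = _censoring_design(py, ["age", "smoking"], None,
                                         "quadratic")
        expected = models.num.predict(Xn) / models.den.predict(Xd)
        np.testing.assert_allclose(ratio, expected, rtol=1e-10)


class TestTruncationAndCombination:
    def test_equal_weights_unchanged(self):
        ws = WeightSet(sw_A1=np.ones(100), sw_A2=np.ones(100),
                       sw_C=np.ones(100))
        out = m.truncate_weights(ws, 99)
        np.testing.assert_array_equal(out.sw_A_trunc, 1.0)
        np.testing.assert_array_equal(out.sw_C_trunc, 1.0)

    def test_cap_equals_empirical_percentile(self):
        values = np.concatenate([np.ones(1000), np.full(10, 50.0)])
        ws = WeightSet(sw_A1=values, sw_A2=np.ones_like(values))
        out = m.truncate_weights(ws, 99)
        thr = np.percentile(values, 99)   # linear-interpolation convention
        assert out.thresholds["sw_A"]["threshold"] == pytest.approx(thr)
        assert out.sw_A_trunc.max() == pytest.approx(thr)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=10, max_size=200),
           st.floats(60.0, 99.9))
    def test_truncation_contractive_from_above(self, vals, pct):
        ws = WeightSet(sw_A1=np.asarray(vals), sw_A2=np.ones(len(vals)))
        out = m.truncate_weights(ws, pct)
        assert out.sw_A_trunc.max() <= np.max(vals) + 1e-12
        assert out.sw_A_trunc.mean() <= np.mean(vals) + 1e-12

    def test_percentile_outside_range_rejected(self):
        ws = WeightSet(sw_A1=np.ones(10), sw_A2=np.ones(10))
        with pytest.raises(ValueError):
            m.truncate_weights(ws, 40)

    def test_combine_arithmetic(self):
        py = pd.DataFrame({"id": [0, 0, 0], "k": [1, 2, 3],
                           "A1": 0, "A2": 0, "event": 0, "uncensored": 1})
        ws = WeightSet(sw_A1=np.array([0.8]), sw_A2=np.array([1.0]),
                       sw_C=np.array([1.0, 1.0, 1.5]))
        out = m.combine_weights(m.truncate_weights(ws, 100), py)
        assert out.loc[2, "w_final"] == pytest.approx(0.8 * 1.5)

    def test_all_unit_components_give_unit_final(self, small_cohort):
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        n = small_cohort.shape[0]
        ws = m.truncate_weights(WeightSet(sw_A1=np.ones(n), sw_A2=np.ones(n),
                                          sw_C=np.ones(len(py))), 99)
        out = m.combine_weights(ws, py)
        np.testing.assert_array_equal(out["w_final"], 1.0)

    def test_weighted_person_years_close_to_unweighted(
            self, benchmark_cohort_20k):
        """Sum of final weights stays within 5% of the raw person-years on
        a well-specified simulation."""
        model = m.MSMPooledLogistic.from_dataframe(
            benchmark_cohort_20k, target_cause="all_cause")
        res = model.fit()
        w = res.pipeline.weights["w_final"]
        assert abs(w.sum() / len(w) - 1) < 0.05

    def test_row_mismatch_rejected(self):
        py = pd.DataFrame({"id": [0, 0], "k": [1, 2]})
        ws = m.truncate_weights(
            WeightSet(sw_A1=np.ones(1), sw_A2=np.ones(1), sw_C=np.ones(3)), 99)
        with pytest.raises(ValueError):
            m.combine_weights(ws, py)
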
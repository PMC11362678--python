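"""Person-year expansion, pooled logistic hazard fits, Kaplan-Meier
comparator and hazard prediction."""

import numpy as np
import pytest
from scipy.special import expit

import msmcurves as m
from conftest import tiny_cohort_frame


class TestExpansion:
    def test_suicide_death_terminal_event_row(self):
        c = tiny_cohort_frame([3], [1], ["X70"])
        py = m.expand_person_years(c, 14, "suicide")
        assert len(py) == 3
        np.testing.assert_array_equal(py["event"], [0, 0, 1])
        np.testing.assert_array_equal(py["uncensored"], [1, 1, 1])

    def test_survivor_full_follow_up(self):
        c = tiny_cohort_frame([14], [0])
        py = m.expand_person_years(c, 14, "suicide")
        assert len(py) == 14
        assert (py["event"] == 0).all()
        assert (py["uncensored"] == 1).all()

    def test_nontarget_death_is_cause_specific_censoring(self):
        """A non-suicide death under the suicide target ends follow-up
        event-free but is not loss to follow-up."""
        c = tiny_cohort_frame([5], [1], ["C34"])
        py = m.expand_person_years(c, 14, "suicide")
        assert len(py) == 5
        assert (py["event"] == 0).all()
        assert (py["uncensored"] == 1).all()

    def test_loss_to_follow_up_flags_final_row(self):
        c = tiny_cohort_frame([4], [0])     # alive, T < K: lost to follow-up
        py = m.expand_person_years(c, 14, "suicide")
        np.testing.assert_array_equal(py["uncensored"], [1, 1, 1, 0])

    def test_total_rows_equal_person_years(self, small_cohort):
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        assert len(py) == small_cohort["T"].sum()
        assert py["event"].sum() == small_cohort["event"].sum()

    def test_event_partition_by_cause(self, small_cohort):
        n_s = m.expand_person_years(small_cohort, 14, "suicide")["event"].sum()
        n_o = m.expand_person_years(small_cohort, 14, "non_suicide")["event"].sum()
        n_a = m.expand_person_years(small_cohort, 14, "all_cause")["event"].sum()
        assert n_s + n_o == n_a == small_cohort["event"].sum()

    def test_out_of_range_T_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            m.expand_person_years(tiny_cohort_frame([15], [0]), 14, "suicide")
        with pytest.raises(ValueError, match="outside"):
            m.expand_person_years(tiny_cohort_frame([0], [0]), 14, "suicide")


class TestPooledLogistic:
    def test_intercept_only_mle_is_event_rate(self, small_cohort):
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        hz = m.fit_pooled_logistic(py, terms=(), weight_col=None, K=14)
        rate = py["event"].mean()
        assert expit(hz.params[0]) == pytest.approx(rate, rel=1e-8)

    def test_parameter_recovery_known_dgp(self):
        """Correctly specified pooled logistic recovers the simulator's
        hazard coefficients (randomized exposures, no censoring)."""
        cfg = m.benchmark_config(
            60_000, seed=61,
            coef_A1={"const": 0.0}, coef_A2={"const": 0.0},
            region_effects_A1=np.zeros(4), region_effects_A2=np.zeros(4),
            region_effects_haz=np.zeros(4),
            coef_haz={"const": -6.0, "k": 0.05, "A1:A2": 0.9},
            coef_cens={"const": -50.0})
        c = m.generate_cohort(cfg)
        py = m.expand_person_years(c, 14, "all_cause")
        hz = m.fit_pooled_logistic(py, terms=("k", "A1", "A2", "A1:A2"),
                                   weight_col=None, K=14)
        est = hz.params_series()
        se = hz.robust_se()
        truth = {"const": -6.0, "k": 0.05, "A1": 0.0, "A2": 0.0, "A1:A2": 0.9}
        for term, val in truth.items():
            assert abs(est[term] - val) < 3 * se[term], term

    def test_weight_doubling_leaves_estimates_unchanged(self, small_cohort):
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        py["w"] = np.exp(0.2 * np.random.default_rng(0).standard_normal(len(py)))
        a = m.fit_pooled_logistic(py, terms=("k", "r11"), weight_col="w").params
        py["w"] *= 2.0
        b = m.fit_pooled_logistic(py, terms=("k", "r11"), weight_col="w").params
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_no_events_rejected(self):
        py = m.expand_person_years(tiny_cohort_frame([5, 5], [0, 0]), 14,
                                   "suicide")
        with pytest.raises(ValueError, match="no events"):
            m.fit_pooled_logistic(py, terms=("k",))

    def test_empty_regime_cell_warns(self):
        rng = np.random.default_rng(3)
        T = rng.integers(2, 15, 40)
        ev = (rng.random(40) < 0.5).astype(int)
        causes = ["X70" if e else "" for e in ev]
        c = tiny_cohort_frame(T, ev, causes, A1=np.r_[np.zeros(39, int), 1],
                              A2=np.r_[np.zeros(39, int), 1])
        c.loc[39, ["event", "cause_code", "T"]] = [0, "", 14]
        py = m.expand_person_years(c, 14, "suicide")
        with pytest.warns(UserWarning, match="alone-alone"):
            m.fit_pooled_logistic(py, terms=("k",), weight_col=None)


class TestPredictHazard:
    def _model(self, params, terms):
        from msmcurves.hazard import HazardModel
        return HazardModel(["const"] + list(terms), np.asarray(params, float),
                           None, True, 14)

    def test_zero_coefficients_give_half(self):
        hz = self._model([0.0, 0.0, 0.0], ["k", "r11"])
        assert m.predict_hazard(hz, (0, 0), 5) == pytest.approx(0.5)
        assert m.predict_hazard(hz, (1, 1), 9) == pytest.approx(0.5)

    def test_intercept_only_value(self):
        hz = self._model([-2.1972], [])
        assert m.predict_hazard(hz, (0, 0), 1) == pytest.approx(0.1000, abs=5e-5)

    def test_monotone_in_regime_coefficient(self):
        hz = self._model([-3.0, 0.0, 0.8], ["k", "r11"])
        assert m.predict_hazard(hz, (1, 1), 3) > m.predict_hazard(hz, (0, 0), 3)

    def test_no_extrapolation(self):
        hz = self._model([-3.0, 0.0], ["k"])
        with pytest.raises(ValueError, match="outside"):
            m.predict_hazard(hz, (0, 0), 15)
        with pytest.raises(ValueError, match="outside"):
            m.predict_hazard(hz, (0, 0), 0)


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        c = tiny_cohort_frame([5, 14, 3], [0, 0, 0])
        km = m.km_estimate(c, "suicide")
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        c = tiny_cohort_frame([1, 2, 2, 14, 14, 14, 14, 14],
                              [1, 1, 1, 0, 0, 0, 0, 0],
                              ["X60", "X61", "X62", "", "", "", "", ""])
        km = m.km_estimate(c, "suicide").set_index("k")["survival"]
        assert km[1] == pytest.approx(1 - 1 / 8)
        assert km[2] == pytest.approx(1 - 3 / 8)
        assert km[14] == pytest.approx(1 - 3 / 8)

    def test_hand_product_limit_with_censoring(self):
        """Times (1+, 2, 2, 3+, 4): S(2) = (4-2)/4 = 0.5 and S(4) =
        0.5 * (1 - 1/1) = 0 by the product-limit formula."""
        c = tiny_cohort_frame([1, 2, 2, 3, 4], [0, 1, 1, 0, 1],
                              ["", "X70", "X72", "", "X80"])
        km = m.km_estimate(c, "suicide").set_index("k")["survival"]
        assert km[2] == pytest.approx(0.5)
        assert km[4] == pytest.approx(0.0)

    def test_empty_group_warns(self):
        c = tiny_cohort_frame([5, 6], [1, 0], ["X70", ""],
                              A1=[0, 0], A2=[0, 0])
        with pytest.warns(UserWarning, match="empty group"):
            m.km_estimate(c, "suicide", group_by="regime")


class TestKMAgreement:
    def test_saturated_pooled_logistic_reproduces_km(self, small_cohort):
        """With categorical time, unweighted pooled logistic and KM are
        algebraically the same estimator."""
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        terms = tuple(f"k_{j}" for j in range(2, 15))
        hz = m.fit_pooled_logistic(py, terms=terms, weight_col=None, K=14)
        S_pl = np.cumprod([1 - m.predict_hazard(hz, (0, 0), k)
                           for k in range(1, 15)])
        km = m.km_estimate(small_cohort, "all_cause")
        S_km = km.loc[km["k"] > 0, "survival"].to_numpy()
        assert np.max(np.abs(S_pl - S_km)) < 1e-6

    def test_smooth_time_close_to_km(self, small_cohort):
        py = m.expand_person_years(small_cohort, 14, "all_cause")
        hz = m.fit_pooled_logistic(py, terms=("k", "k2"), weight_col=None, K=14)
        S_pl = np.cumprod([1 - m.predict_hazard(hz, (0, 0), k)
                           for k in range(1, 15)])
        km = m.km_estimate(small_cohort, "all_cause")
        S_km = km.loc[km["k"] > 0, "survival"].to_numpy()
        assert np.max(np.abs(S_pl - S_km)) < 0.02
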
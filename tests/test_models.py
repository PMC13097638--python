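import numpy as np
import pytest

import pathscreen as ps
from pathscreen.models import fit_model

from _oracles import ols_oracle, pearson_oracle
from conftest import EXPECTED_LABEL, FORM_TRUTH, small_config


class TestFitModel:
    @pytest.mark.parametrize(
        "form,x,y,a,b,r",
        [
            ("linear", (1, 2, 3), (3, 5, 7), 2.0, 1.0, 1.0),
            ("logarithmic", (1.0, np.e, np.e**2), (1, 4, 7), 3.0, 1.0, 1.0),
            ("power", (1, 2, 4), (8, 2, 0.5), 8.0, -2.0, -1.0),
            ("exponential", (0, 1, 2), (2, 2 * np.e, 2 * np.e**2), 2.0, 1.0, 1.0),
        ],
        ids=["exact-line", "exact-log", "exact-inverse-power", "exact-exponential"],
    )
    def test_exact_curves(self, form, x, y, a, b, r):
        fit = fit_model(form, np.array(x, float), np.array(y, float))
        assert fit.a == pytest.approx(a, abs=1e-10)
        assert fit.b == pytest.approx(b, abs=1e-10)
        assert fit.r_linearized == pytest.approx(r, abs=1e-10)

    def test_exponential_recovery_under_noise(self):
        """n = 100, linearized noise sd 0.05: coefficients within 10% of
        truth; expected values cross-checked against closed-form OLS on
        (x, ln y)."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 6.0, 100)
        a_true, b_true = 2.0, 0.5
        y = a_true * np.exp(b_true * x + rng.normal(0, 0.05, 100))
        fit = fit_model("exponential", x, y)
        assert fit.a == pytest.approx(a_true, rel=0.10)
        assert fit.b == pytest.approx(b_true, rel=0.10)
        icpt, slope = ols_oracle(x, np.log(y))
        assert fit.a == pytest.approx(np.exp(icpt), rel=1e-10)
        assert fit.b == pytest.approx(slope, rel=1e-10)

    def test_agrees_with_normal_equations_oracle(self, rng):
        """All four forms reduce to OLS on their linearized coordinates."""
        x = np.exp(rng.normal(3, 0.5, 200))
        y = np.exp(rng.normal(2, 0.7, 200))
        lin = {
            "linear": (x, y),
            "logarithmic": (np.log(x), y),
            "exponential": (x, np.log(y)),
            "power": (np.log(x), np.log(y)),
        }
        for form, (u, v) in lin.items():
            fit = fit_model(form, x, y)
            icpt, slope = ols_oracle(u, v)
            r = pearson_oracle(list(u), list(v))
            if form in ("exponential", "power"):
                assert fit.a == pytest.approx(np.exp(icpt), rel=1e-10)
            else:
                assert fit.a == pytest.approx(slope, rel=1e-10)
                assert fit.b == pytest.approx(icpt, rel=1e-10)
            assert fit.r_linearized == pytest.approx(r, abs=1e-10)

    @pytest.mark.parametrize(
        "form,x,y,match",
        [
            ("logarithmic", (0.0, 1, 2), (1, 2, 3), "positive x"),
            ("exponential", (1, 2, 3), (-1.0, 2, 3), "positive y"),
            ("power", (1, -2, 3), (1, 2, 3), "positive x"),
        ],
    )
    def test_nonpositive_where_log_required(self, form, x, y, match):
        with pytest.raises(ValueError, match=match):
            fit_model(form, np.array(x, float), np.array(y, float))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_model("linear", np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="zero variance"):
            fit_model("linear", np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_exponential_and_power_report_positive_a(self, rng):
        x = np.exp(rng.normal(3, 0.5, 50))
        y = np.exp(rng.normal(-2, 0.5, 50))
        for form in ("exponential", "power"):
            assert fit_model(form, x, y).a > 0


class TestClassifyRelationship:
    def test_exact_linear_is_rheostat(self):
        x = np.linspace(1, 10, 30)
        call = ps.classify_relationship(x, 2 * x + 1)
        assert call.best.form == "linear"
        assert call.switch_label == "rheostat"
        assert call.better_than_linear_p is None

    def test_exact_inverse_power_is_off_switch(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        call = ps.classify_relationship(x, 8.0 * x**-2)
        assert call.best.form == "power"
        assert call.best.b == pytest.approx(-2.0, abs=1e-10)
        assert call.switch_label == "off_switch"

    def test_seeded_logarithmic_data_called_on_switch(self):
        """Logarithmic truth (a=3, b=1, noise 0.1, n=108): the winning form
        is the one with maximal |r|, computed here independently for all
        four coordinate systems."""
        rng = np.random.default_rng(17)
        x = np.exp(rng.normal(1.5, 0.8, 108))
        y = 3.0 * np.log(x) + 1.0 + rng.normal(0, 0.1, 108)
        call = ps.classify_relationship(x, y)
        rs = {"linear": pearson_oracle(list(x), list(y)),
              "logarithmic": pearson_oracle(list(np.log(x)), list(y))}
        if np.all(y > 0):
            rs["exponential"] = pearson_oracle(list(x), list(np.log(y)))
            rs["power"] = pearson_oracle(list(np.log(x)), list(np.log(y)))
        assert call.best.form == max(rs, key=lambda f: abs(rs[f]))
        assert call.best.form == "logarithmic"
        assert call.switch_label == "on_switch"
        assert call.better_than_linear_p is not None

    def test_inadmissible_forms_skipped_not_errored(self):
        x = np.array([-1.0, 0.5, 2.0, 3.0])  # nonpositive x
        y = np.array([1.0, 2.0, 3.0, 4.0])
        call = ps.classify_relationship(x, y)
        assert "logarithmic" in call.inadmissible
        assert "power" in call.inadmissible
        assert "linear" in call.fits

    def test_tie_tolerance_resolves_toward_linear(self, rng):
        """Near-linear data with a whisker of curvature stays linear under
        the default 0.01 parsimony margin."""
        x = np.linspace(1, 10, 200)
        y = 2 * x + 1 + rng.normal(0, 0.05, 200)
        call = ps.classify_relationship(x, y)
        assert call.best.form == "linear"
        tight = ps.classify_relationship(x, y, tie_tolerance=0.0)
        # without the margin any hairline winner is allowed, but the label
        # taxonomy still applies
        assert abs(tight.best.r_linearized) >= abs(call.fits["linear"].r_linearized)

    def test_weak_best_fit_gets_no_switch_label(self, rng):
        x = np.exp(rng.normal(3, 0.5, 80))
        y = np.exp(rng.normal(2, 0.5, 80))  # independent noise
        call = ps.classify_relationship(x, y)
        assert abs(call.best.r_linearized) < 0.7
        assert call.switch_label == "none"

    def test_n_below_three_errors(self):
        with pytest.raises(ValueError, match="3"):
            ps.classify_relationship([1.0, 2.0], [1.0, 2.0])

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1, 2, 3, 4, np.nan, 6], float)
        y = 2 * x + 1
        y[1] = np.nan
        call = ps.classify_relationship(x, y)
        assert call.best.n == 4
        assert call.best.form == "linear"

    def test_dependent_rtoz_flag_switches_method(self, rng):
        x = np.exp(rng.normal(4, 0.6, 100))
        y = 5.0 * np.exp(0.02 * x + rng.normal(0, 0.1, 100))
        indep = ps.classify_relationship(x, y)
        dep = ps.classify_relationship(x, y, dependent_rtoz=True)
        assert indep.p_method == "independent_fisher_rtoz"
        assert dep.p_method == "dependent_steiger"
        assert indep.better_than_linear_p != dep.better_than_linear_p


class TestFormRecovery:
    @pytest.mark.parametrize("form", list(FORM_TRUTH))
    def test_generating_form_recovered_through_event_pipeline(self, form):
        """Cohort -> event medians -> classification recovers each
        generating form, its switch label and its coefficients (10%) in a
        handful of seeded replicates (the full 200-replicate rate check
        lives with the acceptance suite)."""
        spec = FORM_TRUTH[form]
        for seed in range(5):
            cfg = small_config(
                form, spec["a"], spec["b"], 0.05, spec["n"], seed=100 + seed,
                x_loc=spec.get("x_loc", 120.0), x_scale=spec.get("x_scale", 0.5),
            )
            ev, _ = ps.generate_cohort(cfg)
            m = ps.summarise_medians(ev)["ct"]
            call = ps.classify_relationship(m["X"], m["Y"])
            assert call.best.form == form
            assert call.switch_label == EXPECTED_LABEL[form]
            assert call.best.a == pytest.approx(spec["a"], rel=0.10)
            assert call.best.b == pytest.approx(spec["b"], rel=0.10)
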
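"""Response-surface regression: fitting, diagnostics, stepwise building."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import mcisim
from mcisim.regression import (
    TermSpec,
    fit_ols,
    main_effects,
    pareto_standardized_effects,
    predict,
    quadratic_candidates,
    residual_diagnostics,
    shapiro_francia,
    stepwise_build,
)


@pytest.fixture(scope="module")
def lattice():
    grid = mcisim.FactorGrid.staff_mix_lattice()
    vecs = grid.staff_vectors(mcisim.make_optimization_baseline().staff)
    return pd.DataFrame([v.as_dict() for v in vecs])


def _linear_data(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
    y = 5.0 + 2.0 * x1 - 3.0 * x2 + noise * rng.normal(size=n)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y})


class TestFitOls:
    def test_exact_linear_recovery(self):
        data = _linear_data()
        model, diag = fit_ols(data, "y")
        assert model.coef("Intercept") == pytest.approx(5.0, abs=1e-10)
        assert model.coef("x1") == pytest.approx(2.0, abs=1e-10)
        assert model.coef("x2") == pytest.approx(-3.0, abs=1e-10)
        assert diag.r2 == pytest.approx(1.0)

    def test_duplicated_predictor_rejected(self):
        data = _linear_data()
        data["x3"] = data["x1"]
        with pytest.raises(ValueError, match="rank"):
            fit_ols(data, "y")

    def test_underdetermined_rejected(self):
        data = _linear_data(n=3)
        with pytest.raises(ValueError, match="rows"):
            fit_ols(data, "y")

    def test_f_statistic_identity(self):
        """F = (R^2 / (1 - R^2)) * ((n - p - 1) / p) on every fit."""
        data = _linear_data(n=120, seed=3, noise=4.0)
        model, diag = fit_ols(data, "y")
        p = len(model.terms)
        expected = (diag.r2 / (1 - diag.r2)) * ((model.n - p - 1) / p)
        assert diag.f_stat == pytest.approx(expected, abs=1e-10 * expected)

    def test_orthogonal_design_coefficients_invariant_to_dropped_effects(self, lattice):
        """On the balanced factorial lattice, dropping another main effect
        does not move a coefficient estimate."""
        rng = np.random.default_rng(2)
        data = lattice.copy()
        data["y"] = 300 - 30 * data["radiology_assistants"] - 9 * data["rotation_physicians"] + rng.normal(0, 5, len(data))
        full, _ = fit_ols(data, "y", main_effects(list(mcisim.STAFF_CATEGORIES)))
        sub, _ = fit_ols(data, "y", main_effects(["radiology_assistants", "rotation_physicians"]))
        assert full.coef("radiology_assistants") == pytest.approx(sub.coef("radiology_assistants"), abs=1e-9)
        assert full.coef("rotation_physicians") == pytest.approx(sub.coef("rotation_physicians"), abs=1e-9)

    def test_press_equals_brute_force_leave_one_out(self):
        data = _linear_data(n=150, seed=4, noise=3.0)
        model, diag = fit_ols(data, "y")
        X = np.column_stack([np.ones(len(data)), data["x1"], data["x2"]])
        y = data["y"].to_numpy()
        press = 0.0
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            b, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            press += (y[i] - X[i] @ b) ** 2
        assert diag.press == pytest.approx(press, abs=1e-10 * press)


class TestPredict:
    def test_additivity_of_linear_terms(self):
        model, _ = fit_ols(_linear_data(), "y")
        base = {"x1": 2.0, "x2": 3.0}
        bumped = {"x1": 4.5, "x2": 3.0}
        assert predict(model, bumped) - predict(model, base) == pytest.approx(model.coef("x1") * 2.5)

    def test_missing_predictor_rejected(self):
        model, _ = fit_ols(_linear_data(), "y")
        with pytest.raises(ValueError, match="x2"):
            predict(model, {"x1": 1.0})


class TestPareto:
    def test_ranking_matches_standardized_beta_on_orthogonal_design(self, lattice):
        rng = np.random.default_rng(6)
        data = lattice.copy()
        data["y"] = (
            400
            - 34 * data["radiology_assistants"]
            - 9 * data["rotation_physicians"]
            - 3 * data["medical_assistants"]
            + rng.normal(0, 21, len(data))
        )
        model, _ = fit_ols(data, "y", main_effects(list(mcisim.STAFF_CATEGORIES)))
        pareto, crit = pareto_standardized_effects(model)
        by_beta = pareto.reindex(pareto.beta.abs().sort_values(ascending=False).index)
        assert pareto["term"].tolist() == by_beta["term"].tolist()
        assert crit > 0

    def test_tie_break_is_stable_by_name(self):
        data = _linear_data(n=40, seed=20, noise=1.0)
        model, _ = fit_ols(data, "y")
        model.t[2] = -model.t[1]  # force an exact |t| tie between x1 and x2
        pareto, _ = pareto_standardized_effects(model)
        assert pareto["term"].tolist() == ["x1", "x2"]


class TestStepwise:
    def test_true_signal_enters_first(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.uniform(0, 1, size=(200, 4)), columns=list("abcd"))
        data["y"] = 3.0 * data["a"] + rng.normal(0, 0.3, 200)
        report = stepwise_build(main_effects(list("abcd")), data, "y")
        assert report.term_order[0] == "a"

    def test_no_improvement_gives_empty_report(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame({"a": rng.uniform(size=40)})
        data["y"] = np.ones(40)  # constant response: nothing explains anything
        report = stepwise_build(main_effects(["a"]), data, "y")
        assert report.steps == []

    def test_strong_curvature_enters_before_weak_linear_terms(self, lattice):
        rng = np.random.default_rng(10)
        data = lattice.copy()
        x1, x2 = data["radiology_assistants"], data["rotation_physicians"]
        data["y"] = 300 - 30 * x1 - 12 * x2 + 6 * (x1 - 2) ** 2 + 3 * x1 * x2 + rng.normal(0, 2, len(data))
        report = stepwise_build(quadratic_candidates(list(mcisim.STAFF_CATEGORIES)), data, "y")
        order = report.term_order
        quad_pos = order.index("radiology_assistants^2")
        weak_linear = [order.index(t) for t in order if ":" not in t and "^" not in t and t not in ("radiology_assistants", "rotation_physicians")]
        assert all(quad_pos < pos for pos in weak_linear)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            stepwise_build([], _linear_data(), "y")


class TestTermSpec:
    def test_invalid_terms_rejected(self):
        with pytest.raises(ValueError):
            TermSpec("interaction", ("a", "a"))
        with pytest.raises(ValueError):
            TermSpec("quadratic", ("a", "b"))
        with pytest.raises(ValueError):
            TermSpec("cubic", ("a",))


class TestResidualDiagnostics:
    def test_type_one_error_near_nominal_on_normal_residuals(self):
        """All four normality tests reject about 5% of truly normal samples
        (500 repetitions at n = 2000, within binomial noise of nominal)."""
        rng = np.random.default_rng(2)
        from scipy import stats as ss
        from statsmodels.stats.diagnostic import lilliefors, normal_ad

        rej = np.zeros(4)
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=2000)
            ps = [ss.jarque_bera(x).pvalue, normal_ad(x)[1], lilliefors(x)[1], shapiro_francia(x)[1]]
            rej += np.asarray(ps) < 0.05
        assert np.all(np.abs(rej / reps - 0.05) <= 0.02)

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(3)
        from scipy import stats as ss
        from statsmodels.stats.diagnostic import lilliefors, normal_ad

        rej = np.zeros(4)
        reps = 100
        for _ in range(reps):
            x = rng.standard_t(2, size=2000)
            ps = [ss.jarque_bera(x).pvalue, normal_ad(x)[1], lilliefors(x)[1], shapiro_francia(x)[1]]
            rej += np.asarray(ps) < 0.05
        assert np.all(rej / reps > 0.95)

    def test_full_suite_on_fitted_model(self):
        data = _linear_data(n=500, seed=12, noise=2.0)
        model, _ = fit_ols(data, "y")
        out = residual_diagnostics(model)
        assert set(out["normality"]) == {"jarque_bera", "anderson_darling", "lilliefors", "shapiro_francia"}
        for stat, p in out["normality"].values():
            assert 0 <= p <= 1
        assert 0 <= out["heteroscedasticity"]["breusch_pagan_lm"][1] <= 1

    def test_constant_residuals_rejected(self):
        model, _ = fit_ols(_linear_data(), "y")  # exact fit: residuals ~ 1e-14 but not constant
        model.residuals = np.zeros(len(model.residuals))
        with pytest.raises(ValueError, match="constant"):
            residual_diagnostics(model)

    def test_shapiro_francia_matches_reference_implementation(self, tmp_path):
        """Cross-check statistic and p-value against the R nortest package."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=200) + 0.3 * rng.standard_t(3, size=200)
        w, p = shapiro_francia(x)
        f = tmp_path / "x.txt"
        np.savetxt(f, x)
        r = subprocess.run(
            [
                "Rscript",
                "-e",
                f'suppressMessages(library(nortest)); x<-scan("{f}"); r<-sf.test(x); cat(sprintf("%.12f %.12f", r$statistic, r$p.value))',
            ],
            capture_output=True,
            text=True,
            timeout=120,
        )
        assert r.returncode == 0, r.stderr
        w_ref, p_ref = map(float, r.stdout.split())
        assert w == pytest.approx(w_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)
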
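"""Linear and degree-1 MARS model fitting, pruning and tuning."""
import numpy as np
import pandas as pd
import pytest

from ergpred import (
    HingeTerm,
    MARSModel,
    cv_tune,
    fit_linear,
    gcv_score,
    mars_forward,
    mars_prune,
    r_squared,
)
from ergpred.exceptions import (
    CollinearityError,
    FoldError,
    InsufficientDataError,
)
from ergpred.mars import prune_path


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction(self):
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0

    def test_three_point_worked_case(self):
        assert r_squared([1, 2, 3], [1, 2, 2]) == pytest.approx(0.5)

    def test_constant_y_defined_as_zero(self):
        assert r_squared([5, 5, 5], [5, 5, 5]) == 0.0


class TestLinear:
    def test_exact_linear_data(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=30), "x2": rng.normal(size=30)})
        y = 2.0 + 3.0 * X["x1"] - 1.5 * X["x2"]
        m = fit_linear(X, y.to_numpy())
        assert m.score(X, y.to_numpy()) == pytest.approx(1.0)
        assert m.coefficients["x1"] == pytest.approx(3.0)

    def test_constant_y_gives_zero_slopes(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=20)})
        m = fit_linear(X, np.full(20, 7.0))
        assert m.coefficients["x"] == 0.0
        assert m.intercept == 7.0

    def test_agrees_with_normal_equations(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = rng.normal(size=10)
        m = fit_linear(X, y)
        A = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        assert m.coefficients["a"] == pytest.approx(beta[1], abs=1e-8)
        assert m.coefficients["b"] == pytest.approx(beta[2], abs=1e-8)

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(CollinearityError):
            fit_linear(X, rng.normal(size=20))

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(InsufficientDataError):
            fit_linear(X, np.array([1.0, 2.0]))


class TestForwardPass:
    def test_hinge_recovery(self, rng):
        x = rng.uniform(0, 4, 200)
        y = 3.0 * np.maximum(0, x - 2.0) + rng.normal(0, 1e-6, 200)
        m = mars_forward(pd.DataFrame({"x": x}), y, max_terms=2)
        pos = [t for t in m.terms if t.direction == "+"]
        assert pos and abs(pos[0].knot - 2.0) < 0.1
        assert pos[0].coefficient == pytest.approx(3.0, abs=0.05)

    def test_linear_data_fit_exactly_by_one_pair(self, rng):
        x = rng.uniform(0, 1, 100)
        y = 1.0 + 2.0 * x
        m = mars_forward(pd.DataFrame({"x": x}), y, max_terms=2)
        assert m.score(pd.DataFrame({"x": x}), y) == pytest.approx(1.0)

    def test_constant_y_gives_intercept_only(self):
        X = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        m = mars_forward(X, np.full(50, 3.0), max_terms=10)
        assert m.terms == []
        assert m.intercept == pytest.approx(3.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            mars_forward(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), np.ones(3))

    def test_matches_brute_force_single_knot_regression(self, rng):
        # max_terms=2 is exactly one reflected pair: best segmented fit
        for trial in range(5):
            n = 30 + 5 * trial
            x = rng.uniform(-2, 2, n)
            y = rng.normal(size=n) + 0.5 * x
            X = pd.DataFrame({"x": x})
            m = mars_forward(X, y, max_terms=2)
            rss_m = float(np.sum((y - m.predict(X)) ** 2))
            best = np.inf
            for t in np.unique(x):
                B = np.column_stack([np.ones(n), np.maximum(0, x - t), np.maximum(0, t - x)])
                c, *_ = np.linalg.lstsq(B, y, rcond=None)
                best = min(best, float(np.sum((y - B @ c) ** 2)))
            assert rss_m == pytest.approx(best, abs=1e-8)

    def test_predictions_are_continuous_piecewise_linear(self, rng):
        x = rng.uniform(0, 10, 150)
        y = np.sin(x) * 5 + rng.normal(0, 0.5, 150)
        m = mars_forward(pd.DataFrame({"x": x}), y, max_terms=20)
        grid = pd.DataFrame({"x": np.linspace(0, 10, 4001)})
        pred = m.predict(grid)
        step = 10 / 4000
        max_slope = sum(abs(t.coefficient) for t in m.terms) + 1e-9
        assert np.max(np.abs(np.diff(pred))) <= max_slope * step * 1.0001


class TestGCV:
    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(size=50)
        m = MARSModel(intercept=float(y.mean()), terms=[], feature_names=["x"])
        X = pd.DataFrame({"x": rng.normal(size=50)})
        n = 50
        rss = float(np.sum((y - y.mean()) ** 2))
        expected = (rss / n) / (1 - 1 / n) ** 2
        assert gcv_score(m, X, y) == pytest.approx(expected)

    def test_useless_term_increases_gcv(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 1, 60)})
        y = rng.normal(size=60)
        base = MARSModel(intercept=float(y.mean()), terms=[], feature_names=["x"])
        # a hinge with zero coefficient leaves RSS unchanged but raises C
        padded = MARSModel(
            intercept=float(y.mean()),
            terms=[HingeTerm("x", 0.5, "+", 0.0)],
            feature_names=["x"],
        )
        assert gcv_score(padded, X, y) > gcv_score(base, X, y)

    def test_oversized_model_scores_infinite(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 1, 8)})
        y = rng.normal(size=8)
        terms = [HingeTerm("x", k, "+", 0.1) for k in np.linspace(0.1, 0.9, 5)]
        m = MARSModel(intercept=0.0, terms=terms, feature_names=["x"])
        assert gcv_score(m, X, y) == np.inf


class TestPruning:
    def test_noise_term_pruned(self, rng):
        # one true hinge plus one pure-noise hinge: pruning drops the latter
        from ergpred.mars import _refit_terms

        x = rng.uniform(0, 4, 100)
        z = rng.uniform(0, 4, 100)
        y = 3.0 * np.maximum(0, x - 2.0) + rng.normal(0, 0.3, 100)
        X = pd.DataFrame({"x": x, "z": z})
        model = _refit_terms(
            [HingeTerm("x", 2.0, "+"), HingeTerm("z", 1.5, "+")], X, y, ["x", "z"], 40
        )
        pruned = mars_prune(model, X, y)
        assert [t.variable for t in pruned.terms] == ["x"]

    def test_prune_intercept_only_is_noop(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 1, 30)})
        y = rng.normal(size=30)
        m = MARSModel(intercept=float(y.mean()), terms=[], feature_names=["x"])
        m.gcv = gcv_score(m, X, y)
        out = mars_prune(m, X, y)
        assert out.terms == []

    def test_pruned_gcv_never_worse(self, rng):
        x = rng.uniform(0, 4, 120)
        y = np.maximum(0, x - 1.5) + rng.normal(0, 0.5, 120)
        X = pd.DataFrame({"x": x})
        full = mars_forward(X, y, max_terms=12)
        assert mars_prune(full, X, y).gcv <= gcv_score(full, X, y) + 1e-12


class TestCVTune:
    def test_deterministic_under_fixed_seed(self, rng):
        x = rng.uniform(0, 4, 120)
        y = 2 * np.maximum(0, x - 1.0) + rng.normal(0, 0.3, 120)
        X = pd.DataFrame({"x": x})
        m1 = cv_tune(X, y, k=5, seed=11)
        m2 = cv_tune(X, y, k=5, seed=11)
        assert m1.to_dict() == m2.to_dict()

    def test_pure_noise_collapses(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            X = pd.DataFrame({"x": r.normal(size=200)})
            m = cv_tune(X, r.normal(size=200), k=10, seed=s)
            hits += len(m.terms) <= 1
        assert hits >= 9

    def test_strong_hinge_signal_recovers_hinge_structure(self):
        # SNR ~ 10: the tuned model stays small, its knots sit near the
        # true breakpoint, and most runs select the single-knot model
        single = 0
        for s in range(10):
            r = np.random.default_rng(100 + s)
            x = r.uniform(0, 4, 200)
            y = 3.0 * np.maximum(0, x - 2.0) + r.normal(0, 0.19, 200)
            m = cv_tune(pd.DataFrame({"x": x}), y, k=10, seed=s)
            knots = sorted({t.knot for t in m.terms})
            assert 1 <= len(knots) <= 2
            assert all(abs(k - 2.0) < 0.45 for k in knots)
            slope_change = sum(t.coefficient for t in m.terms)
            assert slope_change == pytest.approx(3.0, abs=0.15)
            single += len(knots) == 1
        assert single >= 6

    def test_grouped_folds_keep_groups_together(self, rng):
        from ergpred.mars import make_folds

        groups = np.repeat(np.arange(20), 2)
        folds = make_folds(40, 5, rng, groups)
        assert sorted(np.concatenate(folds).tolist()) == list(range(40))
        for fold in folds:
            gs = set(groups[fold])
            others = np.concatenate([f for f in folds if f is not fold])
            assert gs.isdisjoint(set(groups[others]))

    def test_fold_count_guard(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(FoldError):
            cv_tune(X, rng.normal(size=10), groups=np.zeros(10), k=5)
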
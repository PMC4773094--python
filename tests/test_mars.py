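"""Multi-response MARS: basis search, pruning, GLM refit, prediction,
deviance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from marsflora.grids import GridSpec, PredictorStack, Raster
from marsflora.mars import (BasisTerm, HingeBasis, MarsModel,
                            build_response_matrix, design_matrix,
                            deviance_diagnostics, evaluate_basis, fit_forward,
                            fit_mars, predict_probability, prune_backward_gcv,
                            refit_binomial_glm, _candidate_knots)
from conftest import make_table


class TestResponseMatrix:
    def test_single_kept_species_rejected(self):
        t = make_table([("A", 0, 0), ("A", 1, 1), ("B", 2, 2)])
        with pytest.raises(ValueError, match="at least two"):
            build_response_matrix(t, min_records=2)

    def test_two_species_indicator_structure(self):
        t = make_table([("A", 0, 0), ("A", 1, 1), ("B", 2, 2), ("B", 3, 3)])
        Y = build_response_matrix(t, min_records=2)
        assert Y.shape == (4, 2)
        np.testing.assert_array_equal(Y.sum(axis=1), 1.0)
        assert Y.sum(axis=0).tolist() == [2.0, 2.0]

    def test_row_sums_always_one(self):
        rng = np.random.default_rng(3)
        recs = [(f"s{rng.integers(6)}", float(i), float(i)) for i in range(80)]
        Y = build_response_matrix(make_table(recs), min_records=2)
        np.testing.assert_array_equal(Y.sum(axis=1).to_numpy(), 1.0)
        counts = make_table(recs).record_counts()
        for sp in Y.columns:
            assert Y[sp].sum() == counts[sp]


class TestHinge:
    def test_scalar_values(self):
        assert evaluate_basis(HingeBasis("x", 0.5, 1), 0.7) == pytest.approx(0.2)
        assert evaluate_basis(HingeBasis("x", 0.5, 1), 0.3) == 0.0

    @given(x=st.floats(-10, 10), knot=st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_mirrored_pair_sums_to_absolute_difference(self, x, knot):
        up = evaluate_basis(HingeBasis("x", knot, 1), x)
        down = evaluate_basis(HingeBasis("x", knot, -1), x)
        assert up + down == pytest.approx(abs(x - knot), rel=1e-12, abs=1e-12)


def _forward_oracle(X, Yv, current_terms):
    """Exhaustive next-step search: for every (variable, candidate knot),
    full lstsq refit of [current basis + reflected pair]; smallest RSS wins
    (ties: lowest variable index, then smallest knot)."""
    n = len(X)
    base_cols = [np.ones(n)] + [t.evaluate(X) for t in current_terms]
    best = None
    for v_idx, name in enumerate(X.columns):
        x = X[name].to_numpy(float)
        for knot in _candidate_knots(x, 50, 3):
            cols = base_cols + [np.maximum(0, x - knot), np.maximum(0, knot - x)]
            B = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(B, Yv, rcond=None)
            rss = float(((Yv - B @ coef) ** 2).sum())
            key = (rss, v_idx, knot)
            if best is None or rss < best[0] - 1e-9:
                best = key
    return best


class TestForward:
    def test_recovers_single_noiseless_knot(self):
        x = np.linspace(0, 1, 201)
        X = pd.DataFrame({"x": x})
        y = np.maximum(0, x - 0.5)
        terms = fit_forward(X, y, max_terms=5)
        assert terms, "no terms selected"
        cands = _candidate_knots(x, 50, 3)
        step = np.max(np.diff(cands))
        assert min(abs(t.hinges[0].knot - 0.5) for t in terms) <= step + 1e-12

    def test_constant_response_yields_no_terms(self):
        X = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        assert fit_forward(X, np.full(50, 0.3), max_terms=7) == []

    def test_two_responses_two_knots(self):
        # expectation computed with the exhaustive step-by-step oracle: the
        # greedy pass first takes a compromise knot (0.59) serving both
        # responses, then refines at the true knots (0.31, 0.71) -- each
        # within one candidate step of truth.
        x = np.linspace(0, 1, 301)
        X = pd.DataFrame({"x": x})
        Y = pd.DataFrame({"a": np.maximum(0, x - 0.3),
                          "b": np.maximum(0, 0.7 - x)})
        terms = fit_forward(X, Y, max_terms=7, tol=1e-10)
        knots = sorted({t.hinges[0].knot for t in terms})
        cands = _candidate_knots(x, 50, 3)
        step = np.max(np.diff(cands))
        assert any(abs(k - 0.3) <= step + 1e-12 for k in knots)
        assert any(abs(k - 0.7) <= step + 1e-12 for k in knots)

    def test_each_step_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(61)
        n = 150
        X = pd.DataFrame({f"v{i}": rng.uniform(0, 1, n) for i in range(3)})
        eta = (2.0 * np.maximum(0, X["v0"] - 0.4)
               - 3.0 * np.maximum(0, 0.6 - X["v1"]))
        Yv = np.column_stack([
            eta + 0.05 * rng.standard_normal(n),
            -eta + 0.05 * rng.standard_normal(n),
        ])
        got = fit_forward(pd.DataFrame(X), Yv, max_terms=7, tol=1e-8)
        # replay the greedy path with the oracle
        current: list[BasisTerm] = []
        i = 0
        while i < len(got):
            _, v_idx, knot = _forward_oracle(X, Yv, current)
            name = X.columns[v_idx]
            step_terms = [t for t in got[i:i + 2]
                          if t.hinges[0].variable == name
                          and t.hinges[0].knot == pytest.approx(knot)]
            assert step_terms, (
                f"step {i}: oracle chose ({name}, {knot}), got {got[i:i+2]}")
            current = got[:i + len(step_terms)]
            i += len(step_terms)

    def test_rss_non_increasing_in_terms(self):
        rng = np.random.default_rng(67)
        n = 120
        X = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)})
        y = np.sin(3 * X["a"]) + rng.standard_normal(n) * 0.1
        terms = fit_forward(X, y.to_numpy(), max_terms=9, tol=1e-10)
        y = y.to_numpy()
        prev = np.inf
        for k in range(len(terms) + 1):
            B = design_matrix(X, terms[:k])
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            rss = float(((y - B @ coef) ** 2).sum())
            assert rss <= prev + 1e-9
            prev = rss


class TestPrune:
    def test_intercept_only_unchanged(self):
        X = pd.DataFrame({"x": np.linspace(0, 1, 30)})
        assert prune_backward_gcv([], X, np.zeros(30)) == []

    def test_noise_term_removed(self):
        rng = np.random.default_rng(71)
        n = 200
        x = rng.uniform(0, 1, n)
        X = pd.DataFrame({"x": x, "junk": rng.uniform(0, 1, n)})
        y = 2 * np.maximum(0, x - 0.5) + 0.02 * rng.standard_normal(n)
        true_terms = [BasisTerm((HingeBasis("x", 0.5, 1),)),
                      BasisTerm((HingeBasis("x", 0.5, -1),))]
        noise_term = BasisTerm((HingeBasis("junk", 0.5, 1),))
        pruned = prune_backward_gcv(true_terms + [noise_term], X, y)
        assert noise_term not in pruned
        assert true_terms[0] in pruned

    def test_selected_subset_minimizes_path_gcv(self):
        rng = np.random.default_rng(73)
        n = 150
        X = pd.DataFrame({"x": rng.uniform(0, 1, n)})
        y = np.maximum(0, X["x"].to_numpy() - 0.3) + 0.1 * rng.standard_normal(n)
        terms = fit_forward(X, y, max_terms=9, tol=1e-10)
        pruned = prune_backward_gcv(terms, X, y, penalty=2.0)

        # oracle: rebuild the deletion path and evaluate GCV by the formula
        def rss_of(sub):
            B = design_matrix(X, sub)
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            return float(((y - B @ coef) ** 2).sum())

        def gcv(sub):
            M = 1 + len(sub)
            C = M + 2.0 * (M - 1) / 2
            return (rss_of(sub) / n) / (1 - C / n) ** 2

        path = [list(terms)]
        cur = list(terms)
        while cur:
            scores = [(rss_of(cur[:i] + cur[i + 1:]), i) for i in range(len(cur))]
            _, i = min(scores, key=lambda t: (t[0], t[1]))
            cur = cur[:i] + cur[i + 1:]
            path.append(list(cur))
        best = min(path, key=lambda sub: (gcv(sub), len(sub)))
        assert gcv(pruned) == pytest.approx(gcv(best), rel=1e-9)


class TestBinomialRefit:
    def test_intercept_only_closed_form(self):
        B = np.ones((4, 1))
        y = np.array([1.0, 1.0, 1.0, 0.0])
        beta, info = refit_binomial_glm(B, y)
        assert beta[0] == pytest.approx(np.log(3.0), abs=1e-6)
        assert info["converged"] and not info["boundary"]

    def test_all_zero_response_hits_boundary(self):
        B = np.ones((6, 1))
        with pytest.warns(UserWarning, match="boundary"):
            beta, info = refit_binomial_glm(B, np.zeros(6))
        assert info["boundary"]
        p = 1 / (1 + np.exp(-beta[0]))
        assert p <= 1e-4

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(79)
        n = 300
        B = np.column_stack([np.ones(n), rng.uniform(0, 2, n),
                             rng.uniform(-1, 1, n)])
        eta = 0.5 - 1.2 * B[:, 1] + 0.8 * B[:, 2]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, info = refit_binomial_glm(B, y)
        ref = sm.GLM(y, B, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        # score equations satisfied at the optimum
        p = 1 / (1 + np.exp(-(B @ beta)))
        assert np.linalg.norm(B.T @ (y - p)) < 1e-6


class TestPredictSurface:
    def _stack(self):
        spec = GridSpec(0, 5, 1.0, 5, 5)
        rng = np.random.default_rng(83)
        return PredictorStack.from_arrays(
            spec, {"a": rng.uniform(0, 1, (5, 5)), "b": rng.uniform(0, 1, (5, 5))})

    def test_zero_intercept_uniform_half(self):
        model = MarsModel([], ["s"], np.zeros((1, 1)), ["a"])
        out = predict_probability(model, self._stack(), "s")
        np.testing.assert_allclose(out.values, 0.5)

    def test_missing_layer_named(self):
        term = BasisTerm((HingeBasis("zzz", 0.2, 1),))
        model = MarsModel([term], ["s"], np.array([[0.0, 1.0]]), ["zzz"])
        with pytest.raises(KeyError, match="zzz"):
            predict_probability(model, self._stack(), "s")

    def test_matches_scalar_oracle_and_nodata(self):
        stack = self._stack()
        vals = stack["a"].values.copy()
        vals[0, 0] = np.nan
        stack = PredictorStack({"a": Raster(stack.spec, vals), "b": stack["b"]})
        terms = [BasisTerm((HingeBasis("a", 0.4, 1),)),
                 BasisTerm((HingeBasis("b", 0.6, -1),))]
        coef = np.array([[0.3, 1.5, -2.0]])
        model = MarsModel(terms, ["s"], coef, ["a", "b"])
        out = predict_probability(model, stack, "s")
        assert np.isnan(out.values[0, 0])
        for r in range(5):
            for c in range(5):
                a, b = stack["a"].values[r, c], stack["b"].values[r, c]
                if not np.isfinite(a):
                    continue
                eta = 0.3 + 1.5 * max(0, a - 0.4) - 2.0 * max(0, 0.6 - b)
                assert out.values[r, c] == pytest.approx(1 / (1 + np.exp(-eta)),
                                                         abs=1e-12)


class TestDiagnostics:
    def _fitted(self):
        rng = np.random.default_rng(89)
        n = 200
        X = pd.DataFrame({"u": rng.uniform(0, 1, n), "w": rng.uniform(0, 1, n)})
        p1 = 1 / (1 + np.exp(-(-1 + 4 * np.maximum(0, X["u"] - 0.5))))
        y1 = (rng.uniform(size=n) < p1).astype(float)
        Y = pd.DataFrame({"s1": y1, "s2": 1 - y1})
        model = fit_mars(X, Y, max_terms=9)
        return model, X, Y

    def test_null_deviance_closed_form(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        Y = pd.DataFrame({"a": [1.0, 0.0, 1.0, 0.0],
                          "b": [0.0, 1.0, 0.0, 1.0]})
        model = MarsModel([], ["a", "b"], np.zeros((2, 1)), ["x"])
        d = deviance_diagnostics(model, X, Y)
        # prevalence 0.5 over 4 observations: -2 * 4 * ln(0.5)
        assert d["per_species"].loc["a", "null_deviance"] == pytest.approx(
            -2 * 4 * np.log(0.5), rel=1e-9)

    def test_unused_variable_zero_delta(self):
        model, X, Y = self._fitted()
        d = deviance_diagnostics(model, X, Y)
        used = set(model.used_variables)
        for var in X.columns:
            if var not in used:
                assert d["per_variable"].loc[var, "delta_deviance"] == 0.0

    def test_deviances_match_probability_oracle(self):
        model, X, Y = self._fitted()
        d = deviance_diagnostics(model, X, Y)
        B = design_matrix(X, model.terms)
        for i, sp in enumerate(model.species_ids):
            y = Y[sp].to_numpy()
            p = 1 / (1 + np.exp(-(B @ model.coef[i])))
            p = np.clip(p, 1e-6, 1 - 1e-6)
            dev = -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
            assert d["per_species"].loc[sp, "residual_deviance"] == pytest.approx(
                dev, rel=1e-9)
        assert (d["per_species"]["pseudo_r2"] <= 1.0 + 1e-12).all()
        assert (d["per_variable"]["delta_deviance"] >= 0).all()

    def test_rank_ordering(self):
        model, X, Y = self._fitted()
        d = deviance_diagnostics(model, X, Y)
        pv = d["per_variable"].sort_values("rank")
        assert (pv["delta_deviance"].diff().dropna() <= 1e-9).all()


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        terms = [BasisTerm((HingeBasis("a", 0.25, 1),)),
                 BasisTerm((HingeBasis("a", 0.25, -1), HingeBasis("b", 0.5, 1)))]
        coef = np.array([[0.1, 2.0, -1.0], [0.0, 0.5, 0.25]])
        model = MarsModel(terms, ["s1", "s2"], coef, ["a", "b"])
        p = tmp_path / "m.json"
        model.to_json(p)
        back = MarsModel.from_json(p)
        assert back.terms == terms
        assert back.species_ids == ["s1", "s2"]
        np.testing.assert_array_equal(back.coef, coef)


def test_degree_two_interactions_searchable():
    rng = np.random.default_rng(97)
    n = 300
    a, b = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    X = pd.DataFrame({"a": a, "b": b})
    y = 3 * np.maximum(0, a - 0.4) * np.maximum(0, b - 0.4)
    terms = fit_forward(X, y, max_terms=11, degree=2, tol=1e-8)
    assert any(t.degree == 2 for t in terms)
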
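"""Candidate model fits and index extraction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mips import (
    ModelSpec,
    ObservedData,
    build_index_matrix,
    fit_or_model,
    fit_ps_model,
)


def _binary_fixture():
    # x=1: 3 treated, 1 control; x=0: 1 treated, 3 controls
    x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float).reshape(-1, 1)
    a = np.array([1, 1, 1, 0, 1, 0, 0, 0])
    return ObservedData(y=np.zeros(8), a=a, x=x, columns=["X1"])


class TestLogisticFit:
    def test_saturated_two_by_two_closed_form(self):
        data = _binary_fixture()
        fit = fit_ps_model(data, ModelSpec("ps", ("X1",), "PS"))
        assert fit.converged
        # odds at x=0 are 1/3; odds ratio is 9
        assert fit.intercept == pytest.approx(np.log(1 / 3), abs=1e-6)
        assert fit.slopes[0] == pytest.approx(np.log(9), abs=1e-6)

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((30, 1))
        a = (rng.random(30) < 1 / (1 + np.exp(-(0.3 + 0.8 * x[:, 0])))).astype(int)
        data = ObservedData(y=np.zeros(30), a=a, x=x, columns=["X1"])
        fit = fit_ps_model(data, ModelSpec("ps", ("X1",), "PS"))

        def negll(theta):
            eta = theta[0] + theta[1] * x[:, 0]
            return float(np.sum(np.log1p(np.exp(eta)) - a * eta))

        # oracle: coarse grid then local refinement, independent of IRLS
        grid = [
            (b0, b1)
            for b0 in np.linspace(-3, 3, 25)
            for b1 in np.linspace(-3, 3, 25)
        ]
        best = min(grid, key=negll)
        opt = minimize(negll, best, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
        assert fit.intercept == pytest.approx(opt.x[0], abs=1e-4)
        assert fit.slopes[0] == pytest.approx(opt.x[1], abs=1e-4)

    def test_constant_treatment_flagged(self):
        data = ObservedData(
            y=np.zeros(6), a=np.ones(6, dtype=int), x=np.arange(6.0).reshape(-1, 1)
        )
        fit = fit_ps_model(data, ModelSpec("ps", ("X1",), "PS"))
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_separation_flagged(self):
        x = np.r_[np.arange(1.0, 6.0), -np.arange(1.0, 6.0)].reshape(-1, 1)
        a = (x[:, 0] > 0).astype(int)
        data = ObservedData(y=np.zeros(10), a=a, x=x)
        fit = fit_ps_model(data, ModelSpec("ps", ("X1",), "PS"))
        assert not fit.converged

    def test_collinear_terms_named(self):
        data = _binary_fixture()
        with pytest.raises(ValueError, match="collinear"):
            fit_ps_model(data, ModelSpec("ps", ("X1", "X1"), "PS"))


class TestLinearFit:
    def test_flat_response(self):
        rng = np.random.default_rng(0)
        data = ObservedData(
            y=np.full(20, 3.5),
            a=rng.integers(0, 2, 20),
            x=rng.standard_normal((20, 2)),
        )
        fit = fit_or_model(data, ModelSpec("or", ("X1", "X2"), "OR"))
        assert fit.intercept == pytest.approx(3.5, abs=1e-10)
        assert np.allclose(fit.slopes, 0, atol=1e-10)
        assert fit.treat_coef == pytest.approx(0, abs=1e-10)

    def test_noiseless_line_recovered(self):
        x = np.linspace(-2, 2, 25).reshape(-1, 1)
        a = np.tile([0, 1], 13)[:25]
        data = ObservedData(y=1 + 2 * x[:, 0], a=a, x=x)
        fit = fit_or_model(data, ModelSpec("or", ("X1",), "OR"))
        assert fit.intercept == pytest.approx(1, abs=1e-10)
        assert fit.slopes[0] == pytest.approx(2, abs=1e-10)

    def test_treatment_only_model_gives_group_mean_difference(self, small_data):
        # intercept + treatment alone saturates the group means
        fit = fit_or_model(
            small_data, ModelSpec("or", (), "OR0", include_treatment=True)
        )
        y, a = small_data.y, small_data.a
        diff = y[a == 1].mean() - y[a == 0].mean()
        assert fit.treat_coef == pytest.approx(diff, abs=1e-10)

    def test_residual_orthogonality(self, small_data):
        spec = ModelSpec("or", ("X1", "X2^2"), "OR")
        fit = fit_or_model(small_data, spec)
        resid = small_data.y - fit.predict_outcome(small_data, small_data.a)
        design = spec.transform(small_data)
        assert np.all(np.abs(design.T @ resid) / len(resid) < 1e-8)

    def test_underdetermined_rejected(self):
        data = ObservedData(y=np.zeros(3), a=[0, 1, 0], x=np.eye(3))
        with pytest.raises(ValueError, match="identify"):
            fit_or_model(data, ModelSpec("or", ("X1", "X2", "X3"), "OR"))

    def test_group_separate_fit_exact_model(self):
        x = np.linspace(-1, 1, 30).reshape(-1, 1)
        a = np.tile([0, 1], 15)
        data = ObservedData(y=x[:, 0] + a, a=a, x=x)
        pair = fit_or_model(data, ModelSpec("or", ("X1",), "OR"), by_group=True)
        from mips import or_estimate

        assert or_estimate(data, pair) == pytest.approx(1.0, abs=1e-10)


class TestIndexMatrix:
    def test_double_index_has_two_columns(self, bench_data):
        data, _ = bench_data
        ps = fit_ps_model(data, ModelSpec("ps", ("X1", "X2"), "PS1"))
        orf = fit_or_model(data, ModelSpec("or", ("X1", "X3"), "OR1"))
        idx = build_index_matrix(data, [ps], [orf])
        assert idx.d == 2
        assert idx.labels == ["PS1", "OR1"]

    def test_standardized_columns(self, bench_data):
        data, _ = bench_data
        ps = fit_ps_model(data, ModelSpec("ps", ("X1", "X2"), "PS1"))
        idx = build_index_matrix(data, [ps], [])
        assert abs(idx.s[:, 0].mean()) < 1e-12
        assert idx.s[:, 0].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_zero_slope_index_flagged(self, bench_data):
        data, _ = bench_data
        ps = fit_ps_model(data, ModelSpec("ps", ("X1",), "PS1"))
        from mips import FittedIndex

        dead = FittedIndex(
            spec=ModelSpec("ps", ("X1",), "PSdead"), intercept=0.0,
            slopes=np.zeros(1),
        )
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            idx = build_index_matrix(data, [ps, dead], [])
        assert idx.degenerate == ["PSdead"]
        assert np.all(idx.s[:, 1] == 0)

    def test_row_permutation_equivariance(self, bench_data):
        data, _ = bench_data
        ps = fit_ps_model(data, ModelSpec("ps", ("X1", "X4"), "PS1"))
        idx = build_index_matrix(data, [ps], [])
        perm = np.random.default_rng(3).permutation(data.n)
        permuted = ObservedData(
            y=data.y[perm], a=data.a[perm], x=data.x[perm], columns=data.columns
        )
        ps2 = fit_ps_model(permuted, ModelSpec("ps", ("X1", "X4"), "PS1"))
        idx2 = build_index_matrix(permuted, [ps2], [])
        assert np.allclose(idx2.s[:, 0], idx.s[perm, 0], atol=1e-8)

    def test_covariate_rescaling_leaves_standardized_index_unchanged(self, bench_data):
        data, _ = bench_data
        spec = ModelSpec("ps", ("X1", "X2"), "PS1")
        idx = build_index_matrix(data, [fit_ps_model(data, spec)], [])
        scaled = ObservedData(
            y=data.y, a=data.a,
            x=data.x * np.r_[10.0, np.ones(data.p - 1)],
            columns=data.columns,
        )
        fit_scaled = fit_ps_model(scaled, spec)
        idx_scaled = build_index_matrix(scaled, [fit_scaled], [])
        # raw slope on X1 shrinks by 10; the standardized index is invariant
        fit_raw = fit_ps_model(data, spec)
        assert fit_scaled.slopes[0] == pytest.approx(fit_raw.slopes[0] / 10, rel=1e-6)
        assert np.allclose(idx_scaled.s, idx.s, atol=1e-8)

    def test_requires_at_least_one_candidate(self, bench_data):
        data, _ = bench_data
        with pytest.raises(ValueError, match="at least one"):
            build_index_matrix(data, [], [])


class TestModelSpec:
    def test_ps_never_includes_treatment(self):
        spec = ModelSpec("ps", ("X1",), "PS", include_treatment=True)
        assert not spec.include_treatment

    def test_malformed_term_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            ModelSpec("ps", ("X1**2",), "PS")

    def test_empty_terms_rejected_for_ps(self):
        with pytest.raises(ValueError, match="non-empty"):
            ModelSpec("ps", (), "PS")
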
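"""Point estimators: fixtures, reductions and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mips import (
    ANNConfig,
    FittedIndex,
    KernelConfig,
    ModelSpec,
    ObservedData,
    PropensityVector,
    aipw_estimate,
    build_index_matrix,
    estimate_ate,
    fit_or_model,
    fit_ps_model,
    hajek_ipw,
    nw_mips,
    or_estimate,
    specs_from_bitmask,
)


class TestHajek:
    def test_constant_propensity_reduces_to_group_means(self):
        y = np.array([3.0, 1.0, 2.0, 0.0])
        a = np.array([1, 1, 0, 0])
        assert hajek_ipw(y, a, np.full(4, 0.5)) == pytest.approx(1.0)

    def test_hand_evaluated_fixture(self):
        y = np.array([3.0, 1.0, 2.0, 0.0])
        a = np.array([1, 1, 0, 0])
        pi = np.array([0.8, 0.4, 0.5, 0.2])
        # (1.25*3 + 2.5*1)/3.75 - (2*2 + 1.25*0)/3.25 = 5/3 - 16/13
        assert hajek_ipw(y, a, pi) == pytest.approx(5 / 3 - 16 / 13, abs=1e-12)

    def test_constant_outcome_gives_zero(self):
        y = np.full(6, 4.2)
        a = np.array([1, 0, 1, 0, 1, 0])
        pi = np.array([0.3, 0.6, 0.2, 0.9, 0.5, 0.1])
        assert hajek_ipw(y, a, pi) == pytest.approx(0.0, abs=1e-12)

    def test_zero_propensity_on_treated_rejected(self):
        with pytest.raises(ValueError, match="treated"):
            hajek_ipw(np.zeros(2), np.array([1, 0]), np.array([0.0, 0.5]))

    def test_unit_propensity_on_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            hajek_ipw(np.zeros(2), np.array([1, 0]), np.array([0.5, 1.0]))

    def test_unit_propensity_on_treated_allowed(self):
        # an isolated treated point may receive kernel score exactly 1
        y = np.array([1.0, 2.0, 3.0])
        a = np.array([1, 1, 0])
        est = hajek_ipw(y, a, np.array([1.0, 0.5, 0.5]))
        assert np.isfinite(est)

    def test_out_of_range_scores_warn_but_compute(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        a = np.array([1, 0, 1, 0])
        with pytest.warns(RuntimeWarning, match="outside"):
            est = hajek_ipw(y, a, np.array([0.5, -0.1, 0.5, 0.5]))
        assert np.isfinite(est)

    def test_groupwise_weight_scaling_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(30)
        a = np.r_[np.ones(15, int), np.zeros(15, int)]
        pi = rng.uniform(0.2, 0.8, 30)
        base = hajek_ipw(y, a, pi)
        # self-normalization: the estimate only sees weight ratios
        w1 = 1 / pi[a == 1]
        direct = (7.0 * w1 @ y[a == 1]) / (7.0 * w1.sum()) - (
            1 / (1 - pi[a == 0]) @ y[a == 0]
        ) / (1 / (1 - pi[a == 0])).sum()
        assert direct == pytest.approx(base, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_affine_equivariance(self, shift, scale):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(40)
        a = np.r_[np.ones(20, int), np.zeros(20, int)]
        pi = rng.uniform(0.2, 0.8, 40)
        base = hajek_ipw(y, a, pi)
        assert hajek_ipw(y + shift, a, pi) == pytest.approx(base, abs=1e-9)
        assert hajek_ipw(scale * y, a, pi) == pytest.approx(scale * base, rel=1e-9)


class TestOREstimate:
    def test_joint_fit_returns_treatment_coefficient(self, small_data):
        fit = fit_or_model(small_data, ModelSpec("or", ("X1", "X2", "X8"), "OR"))
        # row-wise contrast of fitted means collapses to the A coefficient
        assert or_estimate(small_data, fit) == pytest.approx(fit.treat_coef, abs=1e-12)

    def test_intercept_treatment_model_gives_group_mean_difference(self, small_data):
        fit = fit_or_model(small_data, ModelSpec("or", (), "OR0"))
        y, a = small_data.y, small_data.a
        assert or_estimate(small_data, fit) == pytest.approx(
            y[a == 1].mean() - y[a == 0].mean(), abs=1e-10
        )


class TestAIPW:
    def _fits(self, data):
        ps = fit_ps_model(data, ModelSpec("ps", ("X1", "X2"), "PS"))
        orf = fit_or_model(data, ModelSpec("or", ("X1", "X2"), "OR"))
        return ps, orf

    def test_matches_term_by_term_evaluation(self):
        y = np.array([1.2, -0.5, 2.0, 0.3, -1.1, 0.8])
        a = np.array([1, 0, 1, 0, 1, 0])
        x = np.array(
            [[0.5, -1.0], [1.2, 0.3], [-0.4, 0.8], [0.0, 0.0], [0.9, -0.2], [-1.1, 1.4]]
        )
        data = ObservedData(y=y, a=a, x=x)
        ps, orf = self._fits(data)
        got = aipw_estimate(data, ps, orf)

        # oracle: literal loop over the augmented influence terms
        pi = ps.predict_ps(data)
        mu1 = orf.predict_outcome(data, 1)
        mu0 = orf.predict_outcome(data, 0)
        total = 0.0
        for i in range(6):
            t1 = a[i] * y[i] / pi[i] - (a[i] - pi[i]) * mu1[i] / pi[i]
            t0 = (1 - a[i]) * y[i] / (1 - pi[i]) + (a[i] - pi[i]) * mu0[i] / (1 - pi[i])
            total += t1 - t0
        assert got == pytest.approx(total / 6, abs=1e-12)

    def test_zero_augmentation_reduces_to_horvitz_thompson(self, small_data):
        ps = fit_ps_model(small_data, ModelSpec("ps", ("X1",), "PS"))
        zero_or = FittedIndex(
            spec=ModelSpec("or", ("X1",), "OR0"),
            intercept=0.0,
            slopes=np.zeros(1),
            treat_coef=0.0,
        )
        got = aipw_estimate(small_data, ps, zero_or)
        pi = ps.predict_ps(small_data)
        y, a = small_data.y, small_data.a
        ht = np.mean(a * y / pi) - np.mean((1 - a) * y / (1 - pi))
        assert got == pytest.approx(ht, abs=1e-12)

    def test_exact_outcome_model_recovers_truth(self):
        # noiseless linear outcome; constant propensity at the treated share
        rng = np.random.default_rng(21)
        x = rng.standard_normal((40, 1))
        a = np.r_[np.ones(20, int), np.zeros(20, int)]
        y = 2.0 + 1.5 * x[:, 0] + 3.0 * a
        data = ObservedData(y=y, a=a, x=x)
        or_fit = fit_or_model(data, ModelSpec("or", ("X1",), "OR"))
        const_ps = FittedIndex(
            spec=ModelSpec("ps", ("X1",), "PSc"),
            intercept=0.0,  # expit(0) = 0.5 = observed treated share
            slopes=np.zeros(1),
        )
        assert aipw_estimate(data, const_ps, or_fit) == pytest.approx(3.0, abs=1e-9)


class TestEstimateATE:
    def test_ipw_path_equals_direct_hajek(self, bench_data):
        data, _ = bench_data
        ps_specs, _ = specs_from_bitmask("1000")
        est = estimate_ate(data, ps_specs=ps_specs, method="ipw")
        fit = fit_ps_model(data, ps_specs[0])
        direct = hajek_ipw(data.y, data.a, fit.predict_ps(data))
        assert est.estimate == pytest.approx(direct, abs=1e-12)
        assert est.label == "IPW"

    def test_kernel_mips_double_index_equals_manual_path(self, bench_data):
        # K = L = 1 is exactly the double-index estimator
        data, _ = bench_data
        ps_specs, or_specs = specs_from_bitmask("1010")
        est = estimate_ate(data, ps_specs=ps_specs, or_specs=or_specs,
                           method="ker_mips")
        idx = build_index_matrix(
            data,
            [fit_ps_model(data, ps_specs[0])],
            [fit_or_model(data, or_specs[0])],
        )
        manual = hajek_ipw(data.y, data.a, nw_mips(idx, data.a))
        assert est.estimate == pytest.approx(manual, abs=1e-12)
        assert est.label == "Ker.MiPS-1010"

    def test_ann_mips_is_seed_deterministic(self, small_data, fast_ann):
        ps_specs, or_specs = specs_from_bitmask("1010")
        kw = dict(ps_specs=ps_specs, or_specs=or_specs, method="ann_mips",
                  ann=fast_ann, seed=5)
        e1 = estimate_ate(small_data, **kw)
        e2 = estimate_ate(small_data, **kw)
        assert e1.estimate == e2.estimate

    def test_ann_scores_reported_in_unit_interval(self, small_data, fast_ann):
        ps_specs, or_specs = specs_from_bitmask("1010")
        est = estimate_ate(small_data, ps_specs=ps_specs, or_specs=or_specs,
                           method="ann_mips", ann=fast_ann, seed=1)
        prop = est.diagnostics["propensity"]
        assert 0 < prop["min"] <= prop["max"] < 1

    def test_extended_bitmask_label(self, bench_data):
        data, _ = bench_data
        ps_specs, or_specs = specs_from_bitmask("1111-2PS2OR")
        assert len(ps_specs) == 4 and len(or_specs) == 4
        est = estimate_ate(data, ps_specs=ps_specs, or_specs=or_specs,
                           method="ker_mips")
        assert est.label == "Ker.MiPS-1111-2PS2OR"

    def test_mips_without_candidates_rejected(self, small_data):
        with pytest.raises(ValueError, match="candidate"):
            estimate_ate(small_data, method="ann_mips")

    def test_unknown_method_rejected(self, small_data):
        with pytest.raises(ValueError, match="unknown method"):
            estimate_ate(small_data, method="tmle")

    def test_or_ann_runs_with_linear_output(self, small_data, fast_ann):
        est = estimate_ate(small_data, method="or_ann", ann=fast_ann, seed=2)
        assert np.isfinite(est.estimate)
        assert est.label == "OR.ANN"


class TestBitmask:
    @pytest.mark.parametrize("mask,k,l", [("1000", 1, 0), ("0010", 0, 1),
                                          ("1010", 1, 1), ("1111", 2, 2),
                                          ("1111-2PS", 4, 2), ("1111-2OR", 2, 4)])
    def test_candidate_counts(self, mask, k, l):
        ps, orm = specs_from_bitmask(mask)
        assert (len(ps), len(orm)) == (k, l)

    def test_all_zero_mask_rejected(self):
        with pytest.raises(ValueError, match="0000"):
            specs_from_bitmask("0000")

    def test_malformed_mask_rejected(self):
        with pytest.raises(ValueError):
            specs_from_bitmask("10")
        with pytest.raises(ValueError):
            specs_from_bitmask("1111-3PS")
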
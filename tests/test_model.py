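"""Unit and property tests for the configuration space, densities, lfdr,
EM fitting and the cumulative-mean rejection rule."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import replimix as rm
from replimix.model import enumerate_configurations, reject_at_fdr

from conftest import model_generated_z
from oracles import naive_lfdr_from_fit


class TestConfigurations:
    def test_canonical_two_cohort_ordering(self):
        """The nine K=2 configurations appear in the canonical listing with
        the two same-sign vectors as the alternative space."""
        cfg = enumerate_configurations(2)
        expected = [
            (0, 0), (0, -1), (0, 1), (-1, 0), (1, 0),
            (-1, -1), (-1, 1), (1, -1), (1, 1),
        ]
        assert [tuple(h) for h in cfg.configs] == expected
        assert cfg.n_configs == 9
        assert sorted(cfg.alternative_indices.tolist()) == [5, 8]
        assert len(cfg.null_indices) == 7

    @pytest.mark.parametrize("K", [2, 3, 4, 5])
    def test_counts_and_partition(self, K):
        cfg = enumerate_configurations(K)
        assert cfg.n_configs == 3**K
        alt = cfg.configs[cfg.alternative_indices]
        assert {tuple(h) for h in alt} == {(1,) * K, (-1,) * K}
        assert len(cfg.null_indices) + 2 == 3**K
        # exhaustive and disjoint
        assert len({tuple(h) for h in cfg.configs}) == 3**K

    @pytest.mark.parametrize("K", [1, 0, 9])
    def test_out_of_range_rejected(self, K):
        with pytest.raises(ValueError):
            enumerate_configurations(K)


class TestConfigDensity:
    def test_all_null_closed_form(self, manual_fit):
        """f(0 | all-null) is the K-fold product of standard normal at 0."""
        val = rm.config_density(np.zeros(2), np.zeros(2, dtype=int), manual_fit)
        assert val == pytest.approx((2 * np.pi) ** -1, rel=1e-12)

    def test_alternative_at_its_mode(self, manual_fit):
        """With mu=(3,3) and unit variances, f((3,3) | (1,1)) = (2*pi)^-1."""
        val = rm.config_density([3.0, 3.0], [1, 1], manual_fit)
        assert val == pytest.approx(1.0 / (2 * np.pi), rel=1e-12)

    def test_reflection_symmetry(self, fitted_model):
        """density(z, h) = density(-z, -h) for every configuration."""
        rng = np.random.default_rng(3)
        Z = rng.normal(scale=3, size=(20, 2))
        for h in fitted_model.configurations.configs:
            np.testing.assert_allclose(
                rm.config_density(Z, h, fitted_model),
                rm.config_density(-Z, -h, fitted_model),
                rtol=1e-12,
            )

    def test_non_finite_z_rejected(self, manual_fit):
        with pytest.raises(ValueError):
            rm.config_density([np.nan, 0.0], [0, 0], manual_fit)

    def test_normalization_by_quadrature(self, fitted_model):
        """Each per-cohort alternative density integrates to 1."""
        from scipy.integrate import quad
        from scipy.stats import norm

        for k in range(fitted_model.K):
            lam, mu, tau2 = fitted_model.lam[k], fitted_model.mu[k], fitted_model.tau2[k]
            total, _ = quad(
                lambda x: sum(
                    l * norm.pdf(x, m, np.sqrt(t)) for l, m, t in zip(lam, mu, tau2)
                ),
                -12,
                12,
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_implied_priors_sum_to_one(self, fitted_model):
        assert fitted_model.config_priors().sum() == pytest.approx(1.0, abs=1e-12)


class TestLfdr:
    def test_matches_brute_force_oracle(self, fitted_model):
        """Vectorized lfdr equals per-variant summation over all 3^K
        configurations to within 1e-10 relative error on 1,000 variants."""
        rng = np.random.default_rng(17)
        Z = rng.normal(scale=2.5, size=(1000, 2))
        got = rm.lfdr(Z, fitted_model)
        want = naive_lfdr_from_fit(Z, fitted_model)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_frozen_regression_value(self, manual_fit):
        """lfdr at z=(4,4) under the hand-specified model; the constant was
        computed with the brute-force configuration-sum oracle."""
        val = rm.lfdr(np.array([[4.0, 4.0]]), manual_fit)[0]
        assert val == pytest.approx(0.004459758905535368, rel=1e-10)

    def test_all_null_prior_gives_unit_lfdr(self):
        fit = rm.CsmGmmFit(
            K=2, M=1, pattern_weights=[1.0, 0.0, 0.0, 0.0],
            mu=[[3.0], [3.0]], tau2=[[1.0], [1.0]], lam=[[1.0], [1.0]],
        )
        Z = np.random.default_rng(0).normal(size=(50, 2)) * 3
        np.testing.assert_allclose(rm.lfdr(Z, fit), 1.0)

    def test_sign_symmetry(self, fitted_model):
        Z = np.random.default_rng(1).normal(scale=3, size=(200, 2))
        np.testing.assert_allclose(
            rm.lfdr(Z, fitted_model), rm.lfdr(-Z, fitted_model), rtol=1e-12
        )

    def test_no_contradiction_on_grid(self, fitted_model):
        """Componentwise larger same-sign |z| never increases the lfdr
        (the conditional-symmetry guarantee), over a dense K=2 grid."""
        g = np.arange(0.0, 8.01, 0.25)
        XX, YY = np.meshgrid(g, g)
        L = rm.lfdr(np.column_stack([XX.ravel(), YY.ravel()]), fitted_model)
        L = L.reshape(XX.shape)
        assert np.all(np.diff(L, axis=0) <= 1e-12)
        assert np.all(np.diff(L, axis=1) <= 1e-12)

    def test_no_contradiction_on_three_cohort_rays(self):
        """lfdr is non-increasing along random positive rays for K=3."""
        w = np.full(8, 0.01)
        w[0] = 1 - w[1:].sum()
        fit = rm.CsmGmmFit(
            K=3, M=2, pattern_weights=w,
            mu=[[2.5, 4.0], [3.0, 5.0], [2.0, 3.5]],
            tau2=[[1.0, 1.2]] * 3, lam=[[0.5, 0.5]] * 3,
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.uniform(0.2, 1.0, size=3)
            ts = np.linspace(0.1, 9.0, 60)
            vals = rm.lfdr(ts[:, None] * d[None, :], fit)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_stronger_signal_pair_never_less_replicated(self, fitted_model):
        """The worked two-cohort check: (5.3, 5.4) cannot receive a larger
        lfdr than (5.1, 5.2) under a symmetric fitted model."""
        vals = rm.lfdr(np.array([[5.1, 5.2], [5.3, 5.4]]), fitted_model)
        assert vals[1] <= vals[0]


class TestFitEM:
    def test_loglik_monotone(self, fitted_model):
        ll = np.asarray(fitted_model.loglik_trace)
        assert ll.size >= 2
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_parameter_recovery(self):
        """EM recovers the generating location (within 0.15) and the
        replicated-pattern mass (within a factor [0.7, 1.4]) at J=200,000."""
        H, Z = model_generated_z(
            J=200_000,
            pattern_probs={(1, 1): 0.001, (1, 0): 0.005, (0, 1): 0.005},
            mu=4.0,
            seed=123,
        )
        fit = rm.fit_em(Z, M=1)
        assert fit.converged
        assert np.all(np.abs(fit.mu.ravel() - 4.0) < 0.15)
        ratio = fit.pattern_weights[3] / 0.001
        assert 0.7 < ratio < 1.4

    def test_pure_null_mass_concentrates(self):
        Z = np.random.default_rng(9).normal(size=(50_000, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = rm.fit_em(Z)
        assert fit.pattern_weights[0] > 0.99
        assert fit.pattern_weights[1:].sum() < 0.01

    def test_nan_rejected(self):
        Z = np.zeros((20_000, 2))
        Z[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm.fit_em(Z)

    def test_degenerate_input_flagged(self):
        Z = np.ones((20_000, 2))
        with pytest.warns(RuntimeWarning):
            fit = rm.fit_em(Z)
        assert not fit.converged

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError):
            rm.fit_em(np.zeros((100, 2)) + np.random.default_rng(0).normal(size=(100, 2)))


class TestRejectAtFdr:
    def test_prefix_mean_rule(self):
        res = reject_at_fdr(np.array([0.01, 0.05, 0.20]), 0.1)
        assert res.rejected.all()  # mean 0.0867 <= 0.1

    def test_no_rejections_when_all_large(self):
        res = reject_at_fdr(np.array([0.5, 0.9]), 0.1)
        assert res.n_rejected == 0

    def test_appending_unit_lfdr_changes_nothing(self):
        rng = np.random.default_rng(4)
        lfdrs = rng.random(100)
        base = reject_at_fdr(lfdrs, 0.1)
        extended = reject_at_fdr(np.append(lfdrs, 1.0), 0.1)
        np.testing.assert_array_equal(base.rejected, extended.rejected[:-1])
        assert not extended.rejected[-1]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
        st.floats(min_value=0.01, max_value=0.5),
    )
    def test_rejection_set_is_largest_valid_prefix(self, lfdrs, q):
        """The rejected set is exactly the longest ascending prefix whose
        running mean stays at or below q, and its mean lfdr is <= q."""
        lfdrs = np.array(lfdrs)
        res = reject_at_fdr(lfdrs, q)
        srt = np.sort(lfdrs)
        means = np.cumsum(srt) / np.arange(1, srt.size + 1)
        valid = np.flatnonzero(means <= q)
        expected_n = valid[-1] + 1 if valid.size else 0
        assert res.n_rejected == expected_n
        if expected_n:
            assert lfdrs[res.rejected].mean() <= q + 1e-12

    def test_tie_break_by_input_index(self):
        res = reject_at_fdr(np.array([0.05, 0.05, 0.05, 0.9]), 0.1)
        assert res.rank[:3].tolist() == [0, 1, 2]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reject_at_fdr(np.array([0.5, 1.5]), 0.1)
        with pytest.raises(ValueError):
            reject_at_fdr(np.array([0.5]), 0.0)
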
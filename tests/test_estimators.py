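"""Unit and property tests of the closed-form information estimators.

Monte-Carlo oracles use the exact Gaussian population, for which the
Wishart sampling theory behind the corrections holds verbatim.
"""

import numpy as np
import pytest
from scipy import stats

import fisherinfo as fi
from fisherinfo.data import MomentSummary
from fisherinfo.estimators import (
    DivergentVarianceError,
    RankDeficiencyError,
    UnusableRegimeError,
    batched_moments,
    bc_info_kernel,
    crossed_info_kernel,
    naive_info_kernel,
    shuffle_info_kernel,
)


def scalar_summary(dmu=2.0, s2=1.0, T=100, dtheta=1.0):
    return MomentSummary(
        mu_plus=np.array([1.0]), mu_minus=np.array([1.0 - dmu * dtheta]),
        S_plus=np.array([[2 * s2]]), S_minus=np.array([[0.0]]),
        S_pooled=np.array([[s2]]), dmu_dtheta=np.array([dmu]),
        T=T, N=1, dtheta=dtheta,
    )


class TestScalarArithmetic:
    def test_naive_scalar(self):
        assert fi.naive_info(scalar_summary()).value == pytest.approx(4.0)

    def test_naive_zero_derivative(self):
        assert fi.naive_info(scalar_summary(dmu=0.0)).value == 0.0

    def test_bc_scalar(self):
        # 4*(196/198) - 2/100
        est = fi.bc_info(scalar_summary(), warn_noisy=False)
        assert est.value == pytest.approx(4 * 196 / 198 - 0.02)
        assert est.method == "bias_corrected"

    def test_shuffle_scalar(self):
        # 4*(98/99) - 0.02
        est = fi.bc_info_shuffle(scalar_summary())
        assert est.value == pytest.approx(4 * 98 / 99 - 0.02)

    def test_correction_factors(self):
        cf = fi.CorrectionFactors(T=100, N=1, dtheta=1.0)
        assert cf.c_cov == pytest.approx(196 / 198)
        assert cf.gamma == pytest.approx(0.02)
        assert 0 < cf.c_cov < 1
        assert cf.alpha == pytest.approx(2 / (197 * 194))
        assert cf.beta == pytest.approx(196 / (197 * 194))


class TestRegimeGuards:
    def test_naive_rank_deficiency(self):
        rng = np.random.default_rng(0)
        ts = fi.TrialSet(rng.normal(size=(3, 8)), rng.normal(size=(3, 8)), 1.0)
        with pytest.raises(RankDeficiencyError, match="2\\(T-1\\)"):
            fi.naive_info(fi.summarize_trials(ts))

    def test_bc_unusable_regime(self):
        # T <= (N+2)/2: covariance inversion refused
        rng = np.random.default_rng(0)
        N, T = 12, 7  # T = (N+2)/2
        ts = fi.TrialSet(rng.normal(size=(T, N)), rng.normal(size=(T, N)), 1.0)
        with pytest.raises(UnusableRegimeError, match="T > \\(N\\+2\\)/2"):
            fi.bc_info(fi.summarize_trials(ts))

    def test_variance_divergence_at_boundary(self):
        # T = (N+5)/2 exactly
        with pytest.raises(DivergentVarianceError, match="diverges"):
            fi.bc_info_variance(1.0, T=10, N=15, dtheta=1.0)

    def test_bc_between_regimes_has_no_variance(self):
        # (N+2)/2 < T <= (N+5)/2: estimate returned, variance absent
        rng = np.random.default_rng(1)
        N, T = 13, 8
        ts = fi.TrialSet(rng.normal(size=(T, N)) + 1, rng.normal(size=(T, N)), 1.0)
        est = fi.bc_info(fi.summarize_trials(ts), warn_noisy=False)
        assert est.analytic_variance is None
        assert np.isfinite(est.value)

    def test_shuffle_zero_variance_neuron_named(self):
        m = scalar_summary()
        m.S_plus[0, 0] = m.S_minus[0, 0] = 0.0
        with pytest.raises(ZeroDivisionError, match="\\[0\\]"):
            fi.bc_info_shuffle(m)


class TestVarianceFormula:
    def test_large_dtheta_limit(self):
        # dtheta -> inf: Var -> 2 I^2 / (2T - N - 5)
        v = fi.bc_info_variance(3.0, T=50, N=10, dtheta=1e9)
        assert v == pytest.approx(2 * 9 / (100 - 10 - 5))

    def test_zero_information_finite_limit(self):
        T, N, dth = 40, 10, 0.5
        v = fi.bc_info_variance(0.0, T, N, dth)
        assert v == pytest.approx(8 * N * (2 * T - 3) / ((2 * T - N - 5) * T**2 * dth**4))

    def test_monte_carlo_calibration(self, gauss20):
        # empirical Var within 5% of the analytic formula at 10^4 reps
        pop = fi.GaussianPopulation.random(20, info=5.0, dtheta=0.5, seed=4)
        rp, rm = pop.simulate_batch(100, 10_000, seed=12)
        dmu, S, *_ = batched_moments(rp, rm, 0.5)
        bc = bc_info_kernel(dmu, S, 100, 0.5)
        pred = fi.bc_info_variance(pop.info_true, 100, 20, 0.5)
        assert bc.var(ddof=1) == pytest.approx(pred, rel=0.05)


class TestUnbiasedness:
    def test_bc_unbiased_gaussian(self, gauss20):
        rp, rm = gauss20.simulate_batch(60, 10_000, seed=11)
        dmu, S, *_ = batched_moments(rp, rm, gauss20.dtheta)
        bc = bc_info_kernel(dmu, S, 60, gauss20.dtheta)
        se = bc.std(ddof=1) / 100
        assert abs(bc.mean() - gauss20.info_true) < 3 * se

    def test_naive_bias_closed_form(self, gauss20):
        # <I_nv> = (2T-2)/(2T-N-3) * (I + 2N/(T dtheta^2))
        T, N = 50, 20
        rp, rm = gauss20.simulate_batch(T, 10_000, seed=14)
        dmu, S, *_ = batched_moments(rp, rm, gauss20.dtheta)
        nv = naive_info_kernel(dmu, S)
        pred = (2 * T - 2) / (2 * T - N - 3) * (
            gauss20.info_true + 2 * N / (T * gauss20.dtheta**2)
        )
        se = nv.std(ddof=1) / 100
        assert abs(nv.mean() - pred) < 3 * se

    def test_shuffle_unbiased_independent_population(self, gauss_diag):
        rp, rm = gauss_diag.simulate_batch(50, 10_000, seed=13)
        dmu, _, Sp, Sm = batched_moments(rp, rm, gauss_diag.dtheta)
        s2 = 0.5 * (np.einsum("rii->ri", Sp) + np.einsum("rii->ri", Sm))
        sh = shuffle_info_kernel(dmu, s2, 50, gauss_diag.dtheta)
        se = sh.std(ddof=1) / 100
        assert abs(sh.mean() - gauss_diag.info_shuffle_true) < 3 * se


class TestCrossedAndDiag:
    def test_crossed_bias_small_and_decaying(self):
        """The crossed estimator removes the O(N/T) covariance-inversion
        bias; the residual O(1/T) bias (numerator squaring) must be small
        at moderate T and shrink roughly as 1/T."""
        N, dth = 10, 1.0
        popA = fi.GaussianPopulation.random(N, info=5.0, dtheta=dth, seed=21)
        popB = fi.GaussianPopulation.random(N, info=7.0, dtheta=dth, seed=22)
        wA = np.linalg.solve(popA.Sigma, popA.f_prime)
        I_AB = float(popB.f_prime @ wA) ** 2 / float(wA @ popB.Sigma @ wA)
        bias = {}
        for T, nrep in [(100, 4000), (400, 4000)]:
            rpA, rmA = popA.simulate_batch(T, nrep, seed=31)
            rpB, rmB = popB.simulate_batch(T, nrep, seed=32)
            dmuA, SA, *_ = batched_moments(rpA, rmA, dth)
            dmuB, SB, *_ = batched_moments(rpB, rmB, dth)
            v, deg = crossed_info_kernel(dmuA, SA, dmuB, SB, T, dth)
            assert not deg.any()
            bias[T] = (v.mean() - I_AB) / I_AB
        assert abs(bias[400]) < 0.05
        assert abs(bias[400]) < 0.5 * abs(bias[100])

    def test_crossed_matches_bc_for_identical_populations(self):
        # A and B drawn from the same population at large T: crossed ~ bc
        pop = fi.GaussianPopulation.random(8, info=4.0, dtheta=1.0, seed=25)
        T = 1600  # 200 N
        dataA = pop.simulate(T, seed=41)
        dataB = pop.simulate(T, seed=42)
        mA, mB = fi.summarize_trials(dataA), fi.summarize_trials(dataB)
        crossed = fi.bc_info_crossed(mA, mB).value
        bc = fi.bc_info(mA, warn_noisy=False).value
        band = 3 * np.sqrt(2 * fi.bc_info_variance(pop.info_true, T, 8, 1.0))
        assert abs(crossed - bc) < band

    def test_diag_mean_near_closed_form(self):
        # analytic I_diag = (f' D^-1 f')^2 / (f' D^-1 Sigma D^-1 f')
        pop = fi.GaussianPopulation.random(10, info=5.0, dtheta=1.0, seed=23)
        vals = [
            fi.bc_info_diag(pop.simulate(200, seed=900 + r), seed=r).value
            for r in range(400)
        ]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        # residual O(1/T) bias allowed on top of Monte-Carlo error
        assert abs(vals.mean() - pop.info_diag_true) < 0.03 * pop.info_diag_true + 3 * se

    def test_all_estimators_agree_for_independent_population(self, gauss_diag):
        data = gauss_diag.simulate(600, seed=51)
        m = fi.summarize_trials(data)
        bc = fi.bc_info(m, warn_noisy=False).value
        sh = fi.bc_info_shuffle(m).value
        dg = fi.bc_info_diag(data, seed=0).value
        band = 3 * np.sqrt(fi.bc_info_variance(gauss_diag.info_true, 600, 12,
                                               gauss_diag.dtheta))
        assert abs(bc - sh) < band and abs(bc - dg) < band

    def test_crossed_requires_matching_shapes(self, gauss20):
        mA = fi.summarize_trials(gauss20.simulate(60, seed=0))
        other = fi.GaussianPopulation.random(5, info=1.0, dtheta=gauss20.dtheta, seed=1)
        mB = fi.summarize_trials(other.simulate(60, seed=1))
        with pytest.raises(ValueError, match="share N"):
            fi.bc_info_crossed(mA, mB)


class TestInvarianceProperties:
    def test_bc_invariant_under_linear_transform(self, gauss20):
        """Fisher information is preserved by any invertible linear map of
        the responses; the bias-corrected estimator inherits this exactly."""
        data = gauss20.simulate(80, seed=61)
        rng = np.random.default_rng(62)
        A = rng.standard_normal((20, 20)) + 3 * np.eye(20)
        data2 = fi.TrialSet(data.responses_plus @ A.T, data.responses_minus @ A.T,
                            data.dtheta)
        v1 = fi.bc_info(fi.summarize_trials(data), warn_noisy=False).value
        v2 = fi.bc_info(fi.summarize_trials(data2), warn_noisy=False).value
        assert v1 == pytest.approx(v2, rel=1e-8)

    def test_coarse_fine_consistency(self, small_trials):
        """A coarse experiment with proportionally separated means (same
        dmu/dtheta, same covariance) yields the same plug-in information;
        the corrected estimators differ from it only by the analytic
        derivative-noise term, which genuinely depends on dtheta."""
        m = fi.summarize_trials(small_trials)
        c = 4.0
        m2 = MomentSummary(
            m.mu_plus, m.mu_minus, m.S_plus, m.S_minus, m.S_pooled,
            m.dmu_dtheta, m.T, m.N, c * m.dtheta,   # same derivative, coarser dtheta
        )
        assert fi.naive_info(m).value == pytest.approx(fi.naive_info(m2).value)
        gamma_shift = (2 * m.N / (m.T * m.dtheta**2)) * (1 - 1 / c**2)
        bc1 = fi.bc_info(m, warn_noisy=False).value
        bc2 = fi.bc_info(m2, warn_noisy=False).value
        assert bc2 - bc1 == pytest.approx(gamma_shift, rel=1e-10)
        sh1 = fi.bc_info_shuffle(m).value
        sh2 = fi.bc_info_shuffle(m2).value
        assert sh2 - sh1 == pytest.approx(gamma_shift, rel=1e-10)

    def test_negative_estimates_returned_unclipped(self):
        # pure-noise data at small T routinely yields negative corrected values
        rng = np.random.default_rng(5)
        vals = []
        for r in range(50):
            ts = fi.TrialSet(rng.normal(size=(12, 8)), rng.normal(size=(12, 8)), 0.3)
            vals.append(fi.bc_info(fi.summarize_trials(ts), warn_noisy=False).value)
        assert min(vals) < 0

    def test_noisy_estimate_warns(self):
        rng = np.random.default_rng(6)
        ts = fi.TrialSet(rng.normal(size=(12, 8)), rng.normal(size=(12, 8)), 0.3)
        with pytest.warns(UserWarning, match="standard error"):
            fi.bc_info(fi.summarize_trials(ts))


class TestGroundTruthHelpers:
    def test_identity_covariance_unit_derivative(self):
        assert fi.true_linear_info(np.ones(1), np.eye(1)) == pytest.approx(1.0)

    def test_poisson_limit_diagonal(self):
        f = np.array([2.0, 5.0, 1.0])
        fp = np.array([0.3, -0.2, 0.5])
        got = fi.true_linear_info(fp, np.diag(f))
        assert got == pytest.approx(np.sum(fp**2 / f))

    def test_coarse_form_divides_by_dtheta_squared(self):
        df = np.array([2.0, 1.0])
        got = fi.true_linear_info(df, np.eye(2), dtheta=2.0)
        assert got == pytest.approx(5.0 / 4.0)

    def test_non_pd_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fi.true_linear_info(np.ones(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_optimal_weights_hand_case(self):
        w = fi.optimal_weights(np.array([1.0, 1.0]), np.array([[1.0, 0], [0, 4.0]]))
        np.testing.assert_allclose(w / w[0], [1.0, 0.25])
        # normalized form: f'^T w = 1
        assert np.array([1.0, 1.0]) @ w == pytest.approx(1.0)

    def test_optimal_readout_variance_is_inverse_information(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((6, 6))
        Sigma = A @ A.T + np.eye(6)
        fp = rng.standard_normal(6)
        w = fi.optimal_weights(fp, Sigma)
        I = fi.true_linear_info(fp, Sigma)
        assert w @ Sigma @ w == pytest.approx(1.0 / I)

    def test_identity_covariance_weights_parallel_fprime(self):
        fp = np.array([1.0, 2.0, -1.0])
        w = fi.optimal_weights(fp, np.eye(3), normalize=False)
        np.testing.assert_allclose(w, fp)


class TestPercentCorrect:
    def test_chance_and_saturation(self):
        assert fi.info_to_percent_correct(0.0, 7.0) == pytest.approx(50.0)
        assert fi.info_to_percent_correct(1e9, 7.0) == pytest.approx(100.0)

    def test_negative_info_rejected(self):
        with pytest.raises(ValueError):
            fi.info_to_percent_correct(-0.1, 7.0)

    def test_matches_empirical_optimal_decoding(self):
        """Decode two Gaussian conditions with the optimal readout and the
        midpoint rule; the empirical fraction correct must match
        Phi(dtheta*sqrt(I)/2) within binomial error."""
        pop = fi.GaussianPopulation.random(6, info=0.25, dtheta=4.0, seed=71)
        n = 40_000
        rp, rm = pop.simulate_batch(n, 1, seed=72)
        w = fi.optimal_weights(pop.f_prime, pop.Sigma)
        thr = 0.5 * w @ (pop.f_plus + pop.f_minus)
        correct = np.concatenate([
            (rp[0] @ w > thr), (rm[0] @ w < thr)
        ])
        pred = fi.info_to_percent_correct(pop.info_true, pop.dtheta) / 100
        se = np.sqrt(pred * (1 - pred) / (2 * n))
        assert abs(correct.mean() - pred) < 4 * se
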
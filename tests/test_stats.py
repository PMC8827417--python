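import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import sparsebalance as sb
from sparsebalance.dynamics import Trajectory
from sparsebalance.stats import psi


def _traj(phi, x=None):
    phi = np.asarray(phi, dtype=float)
    x = phi.copy() if x is None else np.asarray(x, dtype=float)
    return Trajectory(x=x, phi=phi, times=np.arange(phi.shape[1], dtype=float))


class TestMeanResponseAndSparsity:
    def test_constant_rate_fixture(self):
        t = _traj(np.tile([[0.2], [0.6]], (1, 10)))
        assert sb.mean_response(t) == pytest.approx(0.4)

    def test_fraction_active_and_mu(self):
        t = _traj(np.tile([[0.2], [0.6], [0.0], [0.0]], (1, 8)))
        assert sb.fraction_active(t) == pytest.approx(0.5)
        from sparsebalance.stats import active_mean
        assert active_mean(t) == pytest.approx(0.4)

    def test_all_subthreshold(self):
        from sparsebalance.stats import active_mean
        t = _traj(np.zeros((3, 5)))
        assert sb.mean_response(t) == 0.0
        assert sb.fraction_active(t) == 0.0
        assert active_mean(t) == 0.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            sb.mean_response(np.zeros((0, 0)))

    @given(
        hnp.arrays(np.float64, (4, 20),
                   elements=st.floats(0, 5, allow_nan=False)),
    )
    @settings(max_examples=50, deadline=None)
    def test_product_identity_exact(self, phi):
        # phi_bar = f * mu on any input
        t = _traj(phi)
        from sparsebalance.stats import active_mean
        f, mu = sb.fraction_active(t), active_mean(t)
        assert sb.mean_response(t) == pytest.approx(f * mu, abs=1e-12)


class TestVarianceDecomposition:
    def test_static_heterogeneity_only(self):
        s = np.tile([[1.0], [3.0]], (1, 10))
        tot, vt, vq = sb.variance_decomposition(s)
        assert vt == 0.0
        assert vq == pytest.approx(1.0)  # population convention
        assert tot == pytest.approx(1.0)

    def test_shared_fluctuation_only(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(500)
        s = np.tile(trace, (4, 1))
        tot, vt, vq = sb.variance_decomposition(s)
        assert vq == pytest.approx(0.0, abs=1e-12)
        assert vt == pytest.approx(trace.var())

    @given(
        hnp.arrays(np.float64, (5, 30),
                   elements=st.floats(-10, 10, allow_nan=False)),
    )
    @settings(max_examples=50, deadline=None)
    def test_decomposition_identity(self, s):
        tot, vt, vq = sb.variance_decomposition(s)
        assert tot == pytest.approx(vt + vq, abs=1e-10)
        pooled = s.var()
        assert tot == pytest.approx(pooled, abs=1e-10)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sb.variance_decomposition(np.ones((1, 10)))


class TestAutocorrelation:
    def test_white_noise(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal((50, 4000))
        lags, R = sb.autocorrelation(s, max_lag=10.0, dt=1.0)
        assert R[0] == pytest.approx(1.0, rel=0.05)
        assert np.all(np.abs(R[1:]) < 0.02)

    def test_sinusoid_gives_half_cosine(self):
        # x_i(t) = sin(t + phase_i): R(tau) -> 0.5 cos(tau)
        dt = 0.02
        t = np.arange(0, 400, dt)
        rng = np.random.default_rng(2)
        phases = rng.uniform(0, 2 * np.pi, 16)
        s = np.sin(t[None, :] + phases[:, None])
        lags, R = sb.autocorrelation(s, max_lag=6.0, dt=dt)
        assert np.max(np.abs(R - 0.5 * np.cos(lags))) < 0.02

    def test_ou_process_exponential_decay(self):
        # OU with correlation time tau_c: R(tau)/R(0) ~ exp(-tau/tau_c)
        tau_c, dt, n = 2.0, 0.05, 60
        T = 12000
        rng = np.random.default_rng(3)
        x = np.zeros((n, T))
        noise = rng.standard_normal((n, T))
        for k in range(1, T):
            x[:, k] = x[:, k - 1] * (1 - dt / tau_c) + np.sqrt(2 * dt / tau_c) * noise[:, k]
        lags, R = sb.autocorrelation(x[:, 2000:], max_lag=4.0, dt=dt)
        assert np.max(np.abs(R / R[0] - np.exp(-lags / tau_c))) < 0.1
        tau_est = sb.correlation_time(lags, R)
        assert tau_est == pytest.approx(tau_c, rel=0.2)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError):
            sb.autocorrelation(np.zeros((3, 100)), max_lag=60.0, dt=1.0)


class TestCorrelationTime:
    def test_exponential_analytic(self):
        lags = np.linspace(0, 40, 4001)
        R = np.exp(-lags / 2.0)
        assert sb.correlation_time(lags, R) == pytest.approx(2.0, rel=1e-3)
        assert sb.decorrelation_rate(lags, R) == pytest.approx(0.5, rel=1e-3)

    def test_delta_like_limit(self):
        dt = 0.1
        lags = np.arange(0, 5, dt)
        R = np.zeros_like(lags)
        R[0] = 1.0
        R[1] = -1e-6  # immediate crossing
        tau = sb.correlation_time(lags, R)
        assert tau <= dt  # trapezoid weight of a single-bin peak
        assert sb.decorrelation_rate(lags, R) > 5.0

    def test_nonpositive_R0_rejected(self):
        with pytest.raises(ValueError):
            sb.correlation_time(np.arange(5.0), np.array([0.0, 1, 1, 1, 1]))


class TestSynchronyIndex:
    def test_identical_traces_give_one(self):
        rng = np.random.default_rng(4)
        tr = rng.standard_normal(300)
        assert sb.synchrony_index(np.tile(tr, (6, 1))) == pytest.approx(1.0)

    def test_independent_units_scale_inverse_N(self):
        rng = np.random.default_rng(5)
        idx = {}
        for n in (25, 100):
            x = rng.standard_normal((n, 20000))
            idx[n] = sb.synchrony_index(x)
            assert idx[n] == pytest.approx(1.0 / n, rel=0.4)
        assert idx[25] > idx[100]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sb.synchrony_index(np.ones((3, 10)))


class TestOnTimePsiBalance:
    def test_on_time_and_binary_psi(self):
        phi = np.array([[1.0, 1, 0, 0], [1.0, 0, 0, 0]])
        np.testing.assert_allclose(sb.on_time_fraction(_traj(phi)), [0.5, 0.25])
        assert psi(_traj(phi)) == pytest.approx(1.0)  # Heaviside: phi^2 = phi

    def test_constant_rate_psi(self):
        t = _traj(np.full((3, 6), 0.3))
        assert psi(t) == pytest.approx(0.3)

    def test_psi_undefined_for_silent_network(self):
        with pytest.raises(ValueError):
            psi(_traj(np.zeros((2, 5))))

    def test_balance_index_uncoupled(self):
        cfg = sb.SimulationConfig(I0=1.5, dt=0.02, T=40.0, burn_in=30.0,
                                  record_stride=1, seed=0)
        traj = sb.simulate(np.zeros((4, 4)), sb.Nonlinearity("rect_tanh"), cfg)
        assert sb.balance_index(traj, 1.5) == pytest.approx(1.0, abs=1e-3)

    def test_balance_index_requires_bias(self):
        with pytest.raises(ValueError):
            sb.balance_index(_traj(np.ones((2, 3))), 0.0)


class TestGaussianityReport:
    def test_standard_normal_shape(self):
        rng = np.random.default_rng(6)
        rep = sb.gaussianity_report(rng.standard_normal(200_000))
        assert abs(rep["skew"]) < 0.02
        assert abs(rep["excess_kurtosis"]) < 0.05
        assert rep["frac_above_threshold"] == pytest.approx(0.5, abs=0.01)

    def test_matched_sample_size_subsampling(self):
        rng = np.random.default_rng(7)
        rep = sb.gaussianity_report(rng.standard_normal(50_000), n_test=2000)
        assert rep["n_test"] == 2000


class TestSummarize:
    def test_full_suite_identities(self, small_chaotic_traj):
        _, traj = small_chaotic_traj
        st_ = sb.summarize(traj, I0=1.0)
        assert st_.phi_bar == pytest.approx(st_.f * st_.mu, abs=1e-9)
        assert st_.var_total_x == pytest.approx(st_.var_t_x + st_.var_q_x)
        # R_eta(0) equals the temporal variance of eta
        assert st_.R_eta[0] == pytest.approx(st_.var_t_eta, rel=1e-6)
        # low-pass filtering can only reduce temporal variance
        assert st_.var_total_eta > st_.var_total_x
        assert 0 < st_.f < 1
        assert np.all((st_.on_time >= 0) & (st_.on_time <= 1))
        assert st_.chi == pytest.approx(st_.x_bar / 1.0)

    def test_quenched_variance_shared_between_x_and_eta(self, small_chaotic_traj):
        # the low-pass filter only affects the temporal component
        _, traj = small_chaotic_traj
        st_ = sb.summarize(traj, I0=1.0)
        assert st_.var_q_x == pytest.approx(st_.var_q_eta, rel=0.25)
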
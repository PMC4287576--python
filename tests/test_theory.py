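import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfcx

from osnet import (ConfigurationError, ConvergenceError, DriveSpec,
                   NeuronParams, SiegertLookup, StabilityError, build_drive,
                   input_moments, lif_fixed_point, linear_rates,
                   rectified_fixed_point, refractory_correction, siegert_rate,
                   simulate, stability_margin)
from osnet.theory import rectified_active_set_oracle


def _drive(h_vec, j=1.0):
    """DriveSpec realizing an arbitrary non-negative drift vector (mV/s)."""
    return DriveSpec(ffw_rate=np.asarray(h_vec, float) / j, bkg_rate=0.0,
                     j_ffw=j, j_bkg=0.0)


class TestRefractoryCorrection:
    def test_closed_forms(self):
        assert refractory_correction(0.0, 2.0) == 0.0
        assert refractory_correction(123.0, 0.0) == 123.0
        assert refractory_correction(100.0, 2.0) == pytest.approx(100 / 1.2)

    def test_monotone_and_bounded(self):
        r = np.linspace(0, 5000, 200)
        out = refractory_correction(r, 2.0)
        assert (np.diff(out) > 0).all()
        assert (out < 500.0).all()  # 1000 / tau_ref


class TestLinearRates:
    def test_no_recurrence_is_drift_balance(self, lif):
        h = np.array([400.0, 800.0])
        w = np.zeros((2, 2))
        r = linear_rates(w, _drive(h), lif, apply_refractory=False)
        np.testing.assert_allclose(r, h / 20.0)
        r_corr = linear_rates(w, _drive(h), lif)
        np.testing.assert_allclose(r_corr, (h / 20) / (1 + (h / 20) * 0.002))

    def test_scalar_self_coupling_geometric_series(self):
        neuron = NeuronParams(model="pif", tau_m=np.inf, v_th=20.0,
                              tau_ref=0.0)
        w = np.array([[8.0]])   # w < DeltaV
        r = linear_rates(w, _drive([240.0]), neuron)
        assert r[0] == pytest.approx(240.0 / (20.0 - 8.0))

    def test_zero_input_zero_rates(self, tiny_weights, pif):
        r = linear_rates(tiny_weights, _drive(np.zeros(30)), pif)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_unstable_system_raises(self, lif):
        w = np.array([[25.0]])  # self-coupling beyond DeltaV
        with pytest.raises(StabilityError):
            linear_rates(w, _drive([100.0]), lif)

    def test_inhibition_dominated_margin_is_stable(self, tiny_weights, lif):
        # large negative row sums do not make the dynamics unstable
        assert stability_margin(tiny_weights, lif) < 1.0


class TestRectifiedFixedPoint:
    def test_scalar_closed_form(self):
        neuron = NeuronParams(model="pif", tau_m=np.inf, v_th=20.0,
                              tau_ref=0.0)
        w = np.array([[-10.0]])  # w = -DeltaV/2, h = DeltaV * 1 Hz
        r, trace = rectified_fixed_point(w, _drive([20.0]), neuron, tol=1e-12)
        assert r[0] == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert trace.converged

    def test_agrees_with_linear_when_solution_positive(self, tiny_weights,
                                                       pif, stim, tiny_pos):
        drive = build_drive(tiny_pos, 45.0, 1.0, stim)
        r_lin = linear_rates(tiny_weights, drive, pif)
        assert (r_lin > 0).all()
        r_rect, _ = rectified_fixed_point(tiny_weights, drive, pif, tol=1e-9)
        np.testing.assert_allclose(r_rect, r_lin, atol=1e-6)

    def test_fixed_point_identity_and_clamping(self, pif):
        rng = np.random.default_rng(5)
        n = 8
        w = rng.normal(0, 1, (n, n))
        w *= 0.7 * 20 / np.linalg.norm(w, 2)
        h = rng.normal(0, 60, n)  # mixed signs: some units silenced
        r, trace = rectified_fixed_point(w, h, pif, tol=1e-10)
        r_raw = trace.r_uncorrected
        rhs = np.maximum(0.0, (w @ r_raw + h) / 20.0)
        np.testing.assert_allclose(r_raw, rhs, atol=1e-8)
        assert (r_raw[(w @ r_raw + h) < 0] == 0).all()

    def test_matches_active_set_enumeration(self, pif):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(2, 8))
            w = rng.normal(0, 1, (n, n))
            w *= 0.8 * 20 / np.linalg.norm(w, 2)
            h = rng.normal(0, 80, n)
            r_oracle = rectified_active_set_oracle(w, h, 20.0)
            r, trace = rectified_fixed_point(w, h, pif, tol=1e-11)
            np.testing.assert_allclose(trace.r_uncorrected, r_oracle,
                                       atol=1e-8)

    def test_nonconvergence_carries_trace(self, tiny_weights, pif, stim,
                                          tiny_pos):
        drive = build_drive(tiny_pos, 0.0, 1.0, stim)
        with pytest.raises(ConvergenceError) as exc:
            rectified_fixed_point(tiny_weights, drive, pif, tol=1e-12,
                                  max_iter=3)
        assert exc.value.trace.iterations == 3

    def test_residuals_non_increasing_after_transient(self, tiny_weights,
                                                      pif, stim, tiny_pos):
        drive = build_drive(tiny_pos, 30.0, 1.0, stim)
        _, trace = rectified_fixed_point(tiny_weights, drive, pif, tol=1e-10)
        tail = trace.residuals[max(2, trace.iterations // 5):]
        assert (np.diff(tail) <= 1e-14).all()


class TestSiegert:
    def test_subthreshold_mean_vanishing_noise(self, lif):
        assert siegert_rate(10.0, 1e-9, lif) == 0.0
        assert siegert_rate(10.0, 0.0, lif) == 0.0

    def test_deterministic_limit_closed_form(self):
        neuron = NeuronParams(model="lif", tau_m=20.0, v_th=20.0, tau_ref=0.0)
        exact = 1.0 / (0.020 * np.log(2.0))
        assert siegert_rate(40.0, 0.0, neuron) == pytest.approx(exact)
        assert siegert_rate(40.0, 1e-6, neuron) == pytest.approx(exact,
                                                                 rel=1e-6)

    def test_matches_reference_quadrature(self, lif):
        """Independent route: direct scipy quad on the first-passage
        integrand, including the sqrt(2) free-potential normalization."""
        for mu, sig in [(5.0, 6.0), (14.0, 4.0), (19.5, 2.0), (24.0, 3.0)]:
            a = (lif.v_reset - mu) / (np.sqrt(2) * sig)
            b = (lif.v_th - mu) / (np.sqrt(2) * sig)
            integral, _ = quad(lambda u: erfcx(-u), a, b, epsrel=1e-12)
            ref = 1.0 / (0.002 + 0.02 * np.sqrt(np.pi) * integral)
            assert siegert_rate(mu, sig, lif) == pytest.approx(ref, rel=1e-9)

    def test_monotone_in_mu(self, lif):
        mus = np.linspace(-10, 40, 101)
        r = siegert_rate(mus, np.full_like(mus, 4.0), lif)
        assert (np.diff(r) > 0).all()

    def test_rate_bounded_by_refractory_period(self, lif):
        assert siegert_rate(200.0, 30.0, lif) < 500.0

    def test_lookup_interpolation_and_range_error(self, lif):
        table = SiegertLookup(lif, (0.0, 30.0), (1.0, 8.0), shape=(120, 60),
                              fallback=False)
        mu, sig = np.array([12.0, 22.0]), np.array([4.0, 3.0])
        np.testing.assert_allclose(table(mu, sig),
                                   siegert_rate(mu, sig, lif), rtol=2e-3)
        with pytest.raises(ConfigurationError):
            table(np.array([50.0]), np.array([4.0]))


class TestInputMoments:
    def test_zero_input_gives_rest_and_zero_sigma(self, lif):
        drive = DriveSpec(ffw_rate=np.zeros(3), bkg_rate=0.0, j_ffw=0.1,
                          j_bkg=0.1)
        mu, sig = input_moments(np.zeros((3, 3)), np.zeros(3), drive, lif)
        np.testing.assert_allclose(mu, lif.v_rest)
        np.testing.assert_allclose(sig, 0.0)

    def test_weight_scaling_of_mean_and_variance(self, lif):
        drive = DriveSpec(ffw_rate=np.zeros(2), bkg_rate=0.0, j_ffw=0.1,
                          j_bkg=0.1)
        rates = np.array([0.0, 10.0])
        w1 = np.array([[0.0, 0.5], [0.0, 0.0]])
        mu1, sig1 = input_moments(w1, rates, drive, lif)
        mu2, sig2 = input_moments(2 * w1, rates, drive, lif)
        assert mu2[0] - lif.v_rest == pytest.approx(2 * (mu1[0] - lif.v_rest))
        assert sig2[0] ** 2 == pytest.approx(4 * sig1[0] ** 2)

    def test_free_potential_variance_against_simulation(self):
        """sigma^2 = (tau_m/2) sum w^2 r matches the simulated stationary
        variance of a threshold-free LIF membrane."""
        neuron = NeuronParams(model="lif", tau_m=20.0, v_th=1e9, v_rest=0.0,
                              tau_ref=0.0)
        drive = DriveSpec(ffw_rate=np.array([40000.0]), bkg_rate=40000.0,
                          j_ffw=0.1, j_bkg=-0.1)
        mu, sig = input_moments(None, np.zeros(1), drive, neuron)
        _, tr = simulate(None, None, None, neuron, drive, duration=60000.0,
                         dt=0.05, seed=6, record_v=[0], v_init=[0.0])
        v = tr.v[0][tr.t > 500.0]
        assert v.mean() == pytest.approx(mu[0], abs=0.15)
        assert v.std() == pytest.approx(sig[0], rel=0.05)


class TestLifFixedPoint:
    def test_no_recurrence_reduces_to_siegert(self, lif):
        drive = DriveSpec(ffw_rate=np.array([50000.0, 80000.0]),
                          bkg_rate=30000.0, j_ffw=0.1, j_bkg=-0.1)
        mu, sig = input_moments(None, np.zeros(2), drive, lif)
        direct = siegert_rate(mu, sig, lif)
        r, trace = lif_fixed_point(np.zeros((2, 2)), drive, lif, tol=1e-10)
        np.testing.assert_allclose(r, direct, atol=1e-7)

    def test_self_consistency_residual(self, tiny_weights, lif, stim,
                                       tiny_pos):
        drive = build_drive(tiny_pos, 60.0, 1.0, stim)
        r, trace = lif_fixed_point(tiny_weights, drive, lif, tol=1e-8)
        mu, sig = input_moments(tiny_weights, r, drive, lif)
        np.testing.assert_allclose(r, siegert_rate(mu, sig, lif), atol=1e-5)
        assert trace.converged

    def test_small_network_against_simulation(self, lif):
        """Weakly coupled N=50 network: fixed-point rates vs a 60 s run."""
        from osnet import build_topology, build_weight_matrix
        topo = build_topology(40, 10, 8, 2, seed=21)
        w = build_weight_matrix(topo, 0.1, 5.0)
        drive = DriveSpec(ffw_rate=np.full(50, 30000.0), bkg_rate=10000.0,
                          j_ffw=0.1, j_bkg=0.1)
        r_th, _ = lif_fixed_point(w, drive, lif, tol=1e-8)
        from osnet import DelaySpec
        sp = simulate(topo, w, DelaySpec(mode="fixed", value=1.5), lif,
                      drive, duration=60000.0, seed=22)
        r_sim = sp.rates(500.0)
        se = np.sqrt(np.maximum(sp.counts(500.0), 1)) / 59.5
        z = np.abs(r_sim - r_th) / se
        assert np.mean(z < 3.0) > 0.9
        assert abs(r_sim.mean() - r_th.mean()) / r_th.mean() < 0.05
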
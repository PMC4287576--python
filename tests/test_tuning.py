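import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osnet import (ConfigurationError, NeuronParams, SpikeData,
                   TuningCurveSet, align_curves, cv_isi, dpo,
                   extract_tuning_curves, f0_f2, fit_von_mises,
                   free_membrane_potential, normalize_tuning, osi_po,
                   reconstruct_free_potential, selectivity_stats,
                   sharpening_coefficient, tuning_width)

THETA = np.arange(12) * 15.0


def _cos_curve(f0, m, phi, theta=THETA):
    return f0 * (1 + m * np.cos(np.deg2rad(2 * (theta - phi))))


class TestExtract:
    def _spikes(self, times, n=2, duration=3000.0, neuron=0):
        t = np.asarray(times, float)
        return SpikeData(ids=np.full(t.size, neuron, dtype=np.int64),
                         times=t, duration=duration, n_neurons=n)

    def test_counting_arithmetic(self):
        by_theta = {0.0: self._spikes(np.linspace(600, 2500, 10)),
                    90.0: self._spikes([], )}
        curves = extract_tuning_curves(by_theta, window=(500.0, 2500.0))
        assert curves.rates[0, 0] == pytest.approx(5.0)  # 10 spikes / 2 s
        assert curves.rates[0, 1] == 0.0
        assert curves.rates[1].sum() == 0.0

    def test_window_validation(self):
        by_theta = {0.0: self._spikes([1.0]), 90.0: self._spikes([2.0])}
        with pytest.raises(ConfigurationError):
            extract_tuning_curves(by_theta, window=(0.0, 9000.0))

    def test_poisson_rate_recovery(self):
        rng = np.random.default_rng(3)
        rates = {0.0: 40.0, 45.0: 10.0, 90.0: 5.0, 135.0: 20.0}
        dur = 20000.0
        by_theta = {}
        for th, r in rates.items():
            n = rng.poisson(r * dur / 1000.0)
            by_theta[th] = self._spikes(np.sort(rng.uniform(0, dur, n)),
                                        n=1, duration=dur)
        curves = extract_tuning_curves(by_theta, window=(0.0, dur))
        for k, th in enumerate(sorted(rates)):
            se = np.sqrt(rates[th] / (dur / 1000.0))
            assert abs(curves.rates[0, k] - rates[th]) < 3 * se


class TestCircularStats:
    def test_flat_curve_is_untuned(self):
        osi, _ = osi_po(np.full(12, 4.2), THETA)
        assert osi == pytest.approx(0.0, abs=1e-12)

    def test_single_orientation_is_perfectly_tuned(self):
        r = np.zeros(12)
        r[7] = 9.0
        osi, po = osi_po(r, THETA)
        assert osi == pytest.approx(1.0, abs=1e-12)
        assert po == pytest.approx(THETA[7], abs=1e-9)

    def test_cosine_curve_closed_form(self):
        m, phi = 0.7, 105.0
        osi, po = osi_po(_cos_curve(3.0, m, phi), THETA)
        assert osi == pytest.approx(m / 2.0, abs=1e-12)
        assert po == pytest.approx(phi, abs=1e-9)

    def test_all_zero_curve_flagged_nan(self):
        osi, po = osi_po(np.zeros(12), THETA)
        assert np.isnan(osi) and np.isnan(po)

    def test_f0_f2_cosine(self):
        f0, f2 = f0_f2(_cos_curve(1.0, 0.5, 0.0), THETA)
        assert f0 == pytest.approx(1.0, abs=1e-12)
        assert f2 == pytest.approx(0.5, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=12, max_size=12),
           st.floats(0.1, 50))
    def test_osi_f2_identity_and_scale_invariance(self, rates, scale):
        r = np.asarray(rates)
        osi, po = osi_po(r, THETA)
        f0, f2 = f0_f2(r, THETA)
        assert osi == pytest.approx(f2 / (2 * f0), abs=1e-12)
        osi2, po2 = osi_po(scale * r, THETA)
        assert osi2 == pytest.approx(osi, abs=1e-10)
        if osi > 1e-9:
            assert dpo(po2, po) == pytest.approx(0.0, abs=1e-6)


class TestDpo:
    @pytest.mark.parametrize("a,b,expected", [
        (30.0, 30.0, 0.0), (179.0, 1.0, -2.0), (0.0, 90.0, -90.0),
        (10.0, 170.0, 20.0)])
    def test_cases(self, a, b, expected):
        assert dpo(a, b) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 179.999), st.floats(0, 179.999))
    def test_range(self, a, b):
        d = dpo(a, b)
        assert -90.0 <= d < 90.0


class TestVonMises:
    def test_noiseless_recovery(self):
        a, kappa, phi = 10.0, 2.0, 60.0
        curve = a * np.exp(kappa * np.cos(np.deg2rad(2 * (THETA - phi))))
        fit = fit_von_mises(curve, THETA)
        assert fit.ok
        assert fit.amplitude == pytest.approx(a, rel=1e-6)
        assert fit.kappa == pytest.approx(kappa, rel=1e-6)
        assert fit.phi == pytest.approx(phi, abs=1e-5)
        assert fit.error_index == pytest.approx(0.0, abs=1e-6)

    def test_flat_curve_flagged(self):
        fit = fit_von_mises(np.full(12, 5.0), THETA)
        assert fit.flag == "flat"
        assert fit.amplitude == pytest.approx(5.0, rel=1e-5)
        assert np.isnan(fit.phi)

    def test_zero_curve_flagged(self):
        assert fit_von_mises(np.zeros(12), THETA).flag == "zero"

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_von_mises(np.ones(3), THETA[:3])


class TestTuningWidth:
    def test_closed_forms(self):
        assert tuning_width(0.0) == pytest.approx(45.0)
        assert tuning_width(1.0) == pytest.approx(
            0.5 * np.degrees(np.arccos(np.log(np.cosh(1.0)))), abs=1e-12)
        assert tuning_width(1.0) == pytest.approx(32.146, abs=1e-3)
        assert tuning_width(1e-7) == pytest.approx(45.0, abs=1e-4)
        assert tuning_width(500.0) < 2.0

    def test_strictly_decreasing_and_bounded(self):
        k = np.linspace(0.0, 30.0, 400)
        tw = tuning_width(k)
        assert (np.diff(tw) < 0).all()
        assert (tw > 0).all() and (tw <= 45.0).all()

    def test_sharpening_coefficient(self):
        assert sharpening_coefficient(45.0) == 1.0
        assert sharpening_coefficient(30.0, 45.0) == pytest.approx(2 / 3)
        with pytest.raises(ConfigurationError):
            sharpening_coefficient(30.0, 0.0)


class TestCvIsi:
    def _train(self, times, neuron=0, n=2):
        t = np.asarray(times, float)
        return SpikeData(ids=np.full(t.size, neuron, dtype=np.int64),
                         times=t, duration=float(t.max() + 1 if t.size else 1),
                         n_neurons=n)

    def test_periodic_train_has_zero_cv(self):
        out = cv_isi(self._train(np.arange(100) * 10.0), min_spikes=50)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_has_unit_cv(self):
        rng = np.random.default_rng(4)
        t = np.cumsum(rng.exponential(10.0, 5000))
        out = cv_isi(self._train(t), min_spikes=100)
        assert out[0] == pytest.approx(1.0, abs=0.05)

    def test_sparse_neurons_excluded(self):
        sp = self._train([1.0, 2.0, 3.0])
        assert cv_isi(sp, min_spikes=5) == {}
        with pytest.raises(ConfigurationError):
            cv_isi(sp, min_spikes=1)


class TestFreePotential:
    def test_zero_rate_identity(self, lif):
        assert free_membrane_potential(-3.2, 0.0, lif) == pytest.approx(-3.2)

    def test_correction_closed_form(self, lif):
        # tau_m = 20 ms, DeltaV = 20 mV, 10 Hz -> +4 mV
        assert free_membrane_potential(0.0, 10.0, lif) == pytest.approx(4.0)

    def test_reconstruction_equals_mu_moment(self, tiny_weights, lif, stim,
                                             tiny_pos):
        from osnet import build_drive, input_moments
        drive = build_drive(tiny_pos, 20.0, 1.0, stim)
        rates = np.linspace(0, 12, 30)
        v_rec = reconstruct_free_potential(tiny_weights, rates, drive, lif)
        mu, _ = input_moments(tiny_weights, rates, drive, lif)
        np.testing.assert_array_equal(v_rec, mu)


class TestNormalization:
    def _curves(self):
        rates = np.vstack([_cos_curve(10, 0.5, 30.0),
                           _cos_curve(4, 0.2, 120.0)])
        return TuningCurveSet(theta=THETA, rates=rates)

    def test_max_and_mean_modes(self):
        c = self._curves()
        out_max = normalize_tuning(c, "max")
        np.testing.assert_allclose(out_max.max(axis=1), 1.0)
        out_mean = normalize_tuning(c, "mean")
        np.testing.assert_allclose(out_mean.mean(axis=1), 1.0)

    def test_spontaneous_subtraction_rectifies_floor(self):
        c = self._curves()
        spont = c.rates.min(axis=1)
        out = normalize_tuning(c, "max", subtract_spont=True, spont=spont)
        assert out.min(axis=1) == pytest.approx(0.0)

    def test_zero_denominator_flagged(self):
        c = TuningCurveSet(theta=THETA, rates=np.zeros((1, 12)))
        out = normalize_tuning(c, "max")
        assert np.isnan(out).all()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_tuning(self._curves(), "median")


def test_align_curves_centers_preferred_orientation():
    phi = 30.0
    r = _cos_curve(5.0, 0.8, phi)
    aligned = align_curves(r, THETA, np.array([phi]))
    assert aligned[0].argmax() == 6  # grid center


def test_selectivity_stats_table(tiny_pos):
    rates = np.vstack([_cos_curve(8, 0.6, float(p)) for p in tiny_pos.po])
    curves = TuningCurveSet(theta=THETA, rates=rates, contrast=1.0)
    df = selectivity_stats(curves, input_po=tiny_pos.po,
                           error_threshold=10.0)
    assert len(df) == 30
    assert (df["osi"] - 0.3).abs().max() < 1e-9
    assert df["dpo_deg"].abs().max() < 8.0  # grid quantization of PO only
    assert set(df["flag"]) == {"ok"}
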
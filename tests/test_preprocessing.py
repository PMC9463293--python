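import numpy as np
import pytest
from scipy import signal as sps

from tissuediff import (
    FilterSpec,
    GeneratorConfig,
    add_gaussian_noise,
    apply_filter,
    design_bandstop,
    design_lowpass,
    fit_normalizer,
    generate_recording,
    make_filter,
)


@pytest.fixture(scope="module")
def lowpass():
    return design_lowpass(0.75, 3, 1000.0)


@pytest.fixture(scope="module")
def bandstop():
    return design_bandstop(1.2, 0.4, 1000.0)


def _quiet_recording(**overrides):
    cfg = GeneratorConfig(broadband_sigma=0.0, periodic_noise_fraction=0.0,
                          drift_slope=0.0, **overrides)
    return cfg, generate_recording(cfg, "soft", "soft-model0", 0)


class TestLowpassDesign:
    def test_unit_dc_gain(self, lowpass):
        assert lowpass.gain(0.0) == pytest.approx(1.0, abs=1e-9)

    def test_minus_3db_at_cutoff(self, lowpass):
        assert lowpass.gain(0.75) == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_third_order_rolloff_matches_analog_prototype(self, lowpass):
        # |H(f)| = 1/sqrt(1 + (f/fc)^6) for a third-order Butterworth
        for f in (1.5, 3.0, 7.5):
            expected = 1.0 / np.sqrt(1.0 + (f / 0.75) ** 6)
            assert lowpass.gain(f) == pytest.approx(expected, rel=0.05)

    def test_rejects_cutoff_at_nyquist(self):
        with pytest.raises(ValueError):
            design_lowpass(500.0, 3, 1000.0)


class TestBandstopDesign:
    def test_deep_null_at_center(self, bandstop):
        assert bandstop.gain(1.2) < 1e-3

    def test_unit_gain_at_dc(self, bandstop):
        assert bandstop.gain(0.0) == pytest.approx(1.0, abs=1e-6)

    def test_unit_gain_at_nyquist(self, bandstop):
        assert bandstop.gain(499.99) == pytest.approx(1.0, abs=1e-2)

    def test_half_power_points_bracket_center_with_width_center_over_q(self, bandstop):
        # root-find |H| = 1/sqrt(2) on a fine grid around the notch
        freqs = np.linspace(0.01, 8.0, 16000)
        mag = np.abs(bandstop.frequency_response(freqs))
        below = mag < 1 / np.sqrt(2)
        f_lo = freqs[below][0]
        f_hi = freqs[below][-1]
        assert f_lo < 1.2 < f_hi
        assert (f_hi - f_lo) == pytest.approx(1.2 / 0.4, rel=0.05)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            design_bandstop(600.0, 0.4, 1000.0)
        with pytest.raises(ValueError):
            design_bandstop(1.2, 0.0, 1000.0)


def test_both_filters_are_stable(lowpass, bandstop):
    for spec in (lowpass, bandstop):
        assert spec.is_stable()
        assert np.all(np.abs(spec.poles()) < 1.0)


def test_make_filter_names(lowpass):
    assert make_filter("raw") is None
    assert make_filter("none") is None
    assert make_filter("lowpass").kind == "lowpass_butterworth"
    assert make_filter("bandstop").kind == "bandstop_notch"
    with pytest.raises(ValueError):
        make_filter("median")


class TestApplyFilter:
    def test_constant_recording_is_invariant_under_lowpass(self, lowpass):
        # a globally constant signal passes unchanged (unit DC gain, zero phase)
        _, rec = _quiet_recording(idle_level=2.0, contact_level=2.0,
                                  class_separation=0.0)
        out = apply_filter(lowpass, rec)
        assert out.samples.shape == rec.samples.shape
        assert out.phase_bounds == rec.phase_bounds
        assert np.allclose(out.samples, rec.samples, atol=1e-9)

    def test_bandstop_removes_its_center_frequency(self, bandstop):
        cfg, rec = _quiet_recording(idle_level=0.0, contact_level=0.0,
                                    class_separation=0.0)
        t = np.arange(rec.samples.shape[1]) / cfg.fs
        rec.samples[:] = np.sin(2 * np.pi * 1.2 * t)
        out = apply_filter(bandstop, rec)
        interior = slice(500, -500)
        rms_in = np.sqrt(np.mean(rec.samples[:, interior] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[:, interior] ** 2))
        assert rms_out < 0.01 * rms_in

    def test_lowpass_attenuates_sinusoid_by_squared_gain(self, lowpass):
        # forward-backward filtering applies |H|^2
        cfg, rec = _quiet_recording(idle_level=0.0, contact_level=0.0,
                                    class_separation=0.0)
        t = np.arange(rec.samples.shape[1]) / cfg.fs
        rec.samples[:] = np.sin(2 * np.pi * 1.2 * t)
        out = apply_filter(lowpass, rec)
        interior = slice(1000, -1000)
        ratio = (np.sqrt(np.mean(out.samples[:, interior] ** 2))
                 / np.sqrt(np.mean(rec.samples[:, interior] ** 2)))
        assert ratio == pytest.approx(lowpass.gain(1.2) ** 2, rel=0.05)

    def test_zero_phase_introduces_no_delay(self, lowpass):
        cfg, rec = _quiet_recording(idle_level=0.0, contact_level=0.0,
                                    class_separation=0.0)
        t = np.arange(rec.samples.shape[1]) / cfg.fs
        rec.samples[:] = np.sin(2 * np.pi * 0.3 * t)  # passband sinusoid
        out = apply_filter(lowpass, rec)
        x = rec.samples[0, 1000:-1000]
        y = out.samples[0, 1000:-1000]
        lags = sps.correlation_lags(len(x), len(y))
        xc = sps.correlate(x - x.mean(), y - y.mean())
        assert lags[np.argmax(xc)] == 0

    def test_commutes_with_channel_permutation(self, bandstop):
        cfg = GeneratorConfig(periodic_noise_fraction=1.0, seed=13)
        rec = generate_recording(cfg, "soft", "soft-model0", 2)
        perm = np.random.default_rng(0).permutation(rec.n_channels)
        out_then_perm = apply_filter(bandstop, rec).samples[perm]
        rec.samples = np.ascontiguousarray(rec.samples[perm])
        perm_then_out = apply_filter(bandstop, rec).samples
        assert np.allclose(out_then_perm, perm_then_out)

    def test_fs_mismatch_raises(self, lowpass):
        _, rec = _quiet_recording(fs=500.0)
        with pytest.raises(ValueError):
            apply_filter(lowpass, rec)


def test_filterspec_json_roundtrip(bandstop):
    restored = FilterSpec.from_json(bandstop.to_json())
    assert restored.kind == bandstop.kind
    assert restored.params == bandstop.params
    assert np.allclose(restored.sos, bandstop.sos)


class TestNormalizer:
    def test_two_point_hand_case(self):
        norm = fit_normalizer(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.allclose(norm.mean_, [1.0, 1.0])
        assert np.allclose(norm.std_, [1.0, 1.0])

    def test_self_normalization_gives_zero_mean_unit_variance(self):
        X = np.random.default_rng(1).normal(3.0, 2.5, size=(500, 9))
        Z = fit_normalizer(X).transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.var(axis=0), 1.0, atol=1e-6)

    def test_no_leakage_into_test_partition(self):
        rng = np.random.default_rng(2)
        train = rng.normal(0.0, 1.0, size=(200, 4))
        test = rng.normal(1.5, 1.0, size=(200, 4))
        Z = fit_normalizer(train).transform(test)
        assert np.all(np.abs(Z.mean(axis=0)) > 0.5)  # test stats not re-centered

    def test_constant_feature_floored_with_warning(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        with pytest.warns(RuntimeWarning):
            norm = fit_normalizer(X)
        assert np.all(norm.std_ > 0)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.ones((1, 3)))


class TestGaussianNoise:
    def test_sigma_zero_is_identity(self):
        X = np.random.default_rng(0).normal(size=(50, 9))
        assert np.array_equal(add_gaussian_noise(X, 0.0, 1), X)

    def test_noise_std_matches_sigma(self):
        X = np.zeros((100_000, 1))
        out = add_gaussian_noise(X, 0.1, np.random.default_rng(3))
        assert np.std(out - X) == pytest.approx(0.1, abs=0.005)

    def test_same_rng_state_is_deterministic(self):
        X = np.random.default_rng(0).normal(size=(40, 9))
        a = add_gaussian_noise(X, 0.1, 99)
        b = add_gaussian_noise(X, 0.1, 99)
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(np.zeros((2, 2)), -0.1, 0)
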
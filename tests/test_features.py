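import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorscore import features as ft
from tremorscore.preprocess import derive_all
from tremorscore.simulate import DEFAULT_PROFILES, SimulationConfig, simulate_recording

FS = 125.0


def make_composite(values, fs=FS):
    return ft.CompositeSignal(values=np.asarray(values, dtype=float), sample_rate=fs)


def rectified_tone(freq=5.0, duration_s=30.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return np.abs(np.sin(2 * np.pi * freq * t))


class TestComposite:
    def test_three_four_five(self):
        tri = np.array([[3.0], [4.0], [0.0]])
        assert ft.composite(tri)[0] == pytest.approx(5.0)

    def test_zero_axes_give_zero(self):
        np.testing.assert_array_equal(ft.composite(np.zeros((3, 8))), np.zeros(8))

    def test_single_axis_sinusoid_is_rectified(self):
        t = np.arange(250) / FS
        x = 2.0 * np.sin(2 * np.pi * 5 * t)
        tri = np.vstack([x, np.zeros_like(x), np.zeros_like(x)])
        np.testing.assert_allclose(ft.composite(tri), np.abs(x))


class TestDetectPeaks:
    def test_rectified_five_hz_has_ten_lobes_per_second(self):
        c = make_composite(rectified_tone())
        train = ft.detect_peaks(c)
        assert abs(len(train.pos_times) - 300) <= 1

    def test_monotone_series_is_degenerate(self):
        train = ft.detect_peaks(make_composite(np.linspace(0, 1, 100)))
        assert train.degenerate

    def test_interleaving_on_simulated_recording(self, class_recording):
        sig = derive_all(class_recording(2))
        c = make_composite(ft.composite(sig.acceleration))
        train = ft.detect_peaks(c)
        events = sorted(
            [(t, +1) for t in train.pos_times] + [(t, -1) for t in train.neg_times]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        # every reported extremum is a true local extremum of the series
        x = c.values
        for t in train.pos_times:
            i = int(round(t * c.sample_rate))
            assert x[i] >= x[i - 1] and x[i] >= x[i + 1]
        for t in train.neg_times:
            i = int(round(t * c.sample_rate))
            assert x[i] <= x[i - 1] and x[i] <= x[i + 1]


def train_from(pos, neg):
    return ft.PeakTrain(
        pos_times=np.array([t for t, _ in pos], dtype=float),
        pos_mags=np.array([m for _, m in pos], dtype=float),
        neg_times=np.array([t for t, _ in neg], dtype=float),
        neg_mags=np.array([m for _, m in neg], dtype=float),
    )


class TestMeanAmplitude:
    def test_constant_amplitudes_recovered(self):
        pos = [(0.1, 2.0), (0.3, 2.0), (0.5, 2.0)]
        neg = [(0.0, 0.0), (0.2, 0.0), (0.4, 0.0), (0.6, 0.0)]
        assert ft.mean_amplitude(train_from(pos, neg)) == pytest.approx(2.0)

    def test_two_peak_train_hand_enumeration(self):
        # pp = (2, 4) flanked by minima at 0: terms (|2-0|+|0-2|)/2 = 2 and
        # (|4-0|+|0-4|)/2 = 4, mean = 3
        pos = [(0.1, 2.0), (0.3, 4.0)]
        neg = [(0.0, 0.0), (0.2, 0.0), (0.4, 0.0)]
        assert ft.mean_amplitude(train_from(pos, neg)) == pytest.approx(3.0)

    def test_degenerate_train_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert ft.mean_amplitude(train_from([(0.1, 1.0)], [(0.0, 0.0)])) == 0.0


class TestRegularity:
    def test_uniform_spacing(self):
        avg, sd = ft.regularity(train_from([(t, 1.0) for t in (0, 0.2, 0.4, 0.6)], []))
        assert avg == pytest.approx(0.2)
        assert sd == pytest.approx(0.0)

    def test_irregular_spacing(self):
        avg, _ = ft.regularity(train_from([(0, 1.0), (0.1, 1.0), (0.3, 1.0)], []))
        assert avg == pytest.approx(0.15)

    def test_rectified_tone_period(self):
        train = ft.detect_peaks(make_composite(rectified_tone()))
        avg, _ = ft.regularity(train)
        assert avg == pytest.approx(0.1, abs=1.0 / FS)


class TestAveragedSpectrum:
    def test_single_axis_energy_divided_by_three(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        tri = np.vstack([x, np.zeros_like(x), np.zeros_like(x)])
        sp = ft.averaged_spectrum(tri, FS)
        sp_single = ft.averaged_spectrum(np.vstack([x, x, x]), FS)
        np.testing.assert_allclose(sp.power, sp_single.power / 3, rtol=1e-10)

    def test_tone_located_within_one_bin(self):
        t = np.arange(3750) / FS
        x = np.sin(2 * np.pi * 5 * t)
        sp = ft.averaged_spectrum(np.vstack([x, x, x]), FS)
        assert abs(sp.freqs[np.argmax(sp.power)] - 5.0) <= FS / 512

    def test_white_noise_band_power_stable_across_seeds(self):
        totals = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=(3, 3750))
            sp = ft.averaged_spectrum(x, FS)
            totals.append(sp.power[(sp.freqs > 0) & (sp.freqs <= 16)].sum())
        totals = np.array(totals)
        assert totals.max() / totals.min() < 1.2

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            ft.averaged_spectrum(np.zeros((3, 100)), FS)


def hand_spectrum(freq_power: dict[float, float], step=1.0, f_max=16.0):
    freqs = np.arange(0, f_max + step, step)
    power = np.zeros_like(freqs)
    for f, p in freq_power.items():
        power[int(round(f / step))] = p
    return ft.Spectrum(freqs=freqs, power=power)


class TestSpectralFeatures:
    def test_point_mass_tone(self):
        pf, mf, pp, mp = ft.spectral_features(hand_spectrum({5.0: 2.0}))
        assert pf == 5.0 and mf == pytest.approx(5.0)
        assert pp == 2.0 and mp == 2.0

    def test_symmetric_pair_averages_to_center(self):
        _, mf, _, _ = ft.spectral_features(hand_spectrum({4.0: 1.0, 6.0: 1.0}))
        assert mf == pytest.approx(5.0)

    def test_weighted_mean_arithmetic(self):
        # (2*1 + 6*3) / 4 = 5
        _, mf, _, _ = ft.spectral_features(hand_spectrum({2.0: 1.0, 6.0: 3.0}))
        assert mf == pytest.approx(5.0)

    def test_zero_spectrum_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            assert ft.spectral_features(hand_spectrum({})) == (0.0, 0.0, 0.0, 0.0)

    @given(st.lists(st.tuples(st.integers(1, 16), st.floats(0.01, 100.0)), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mean_freq_bounded_by_support(self, tones):
        sp = hand_spectrum({float(f): p for f, p in tones})
        _, mf, _, _ = ft.spectral_features(sp)
        support = [float(f) for f, _ in tones]
        assert min(support) - 1e-9 <= mf <= max(support) + 1e-9


class TestBandFeatures:
    def test_bands_around_mean_freq_five(self):
        sp = hand_spectrum({1.0: 1.0, 5.0: 4.0, 10.0: 2.0})
        p_low, p_tr, p_high, *_ = ft.band_features(sp, 5.0)
        # bands: [0,2), [2,8], (8,16]
        assert (p_low, p_tr, p_high) == (1.0, 4.0, 2.0)

    def test_all_power_in_tremor_band(self):
        sp = hand_spectrum({5.0: 3.0})
        *_, prl_low, prl_tr, prl_high = ft.band_features(sp, 5.0)
        assert (prl_low, prl_tr, prl_high) == (0.0, 1.0, 0.0)

    def test_low_mean_freq_clamps_low_band_to_empty(self):
        sp = hand_spectrum({1.0: 1.0, 3.0: 1.0})
        p_low, *_ = ft.band_features(sp, 2.0)
        assert p_low == 0.0

    def test_relative_powers_sum_to_one(self):
        rng = np.random.default_rng(5)
        sp = ft.Spectrum(freqs=np.linspace(0, 20, 200), power=rng.uniform(size=200))
        *_, prl_low, prl_tr, prl_high = ft.band_features(sp, 6.3)
        assert prl_low + prl_tr + prl_high == pytest.approx(1.0, abs=1e-9)


class TestExtract:
    def test_relative_powers_sum_to_one_for_all_signals(self, class_recording):
        fv = ft.extract(derive_all(class_recording(2)))
        for s in ft.SIGNAL_NAMES:
            total = fv[f"{s}.Prl_low"] + fv[f"{s}.Prl_tr"] + fv[f"{s}.Prl_high"]
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_log_features_match_definition(self, class_recording):
        fv = ft.extract(derive_all(class_recording(3)))
        assert fv["acc.log_peak_power"] == pytest.approx(np.log10(fv["acc.peak_power"]))

    def test_tremor_amplitude_separates_classes(self, class_recording):
        quiet = ft.extract(derive_all(class_recording(0)))
        severe = ft.extract(derive_all(class_recording(3)))
        assert severe["acc.mean_amplitude"] >= 5 * quiet["acc.mean_amplitude"]

    def test_extraction_is_deterministic(self, class_recording):
        rec = class_recording(2)
        a = ft.extract(derive_all(rec))
        b = ft.extract(derive_all(rec))
        assert (a == b).all()
        assert list(a.index) == list(ft.FEATURE_NAMES)
        assert len(a) == 76

    def test_mean_amplitude_scales_linearly_with_tremor_amplitude(self):
        cfg = SimulationConfig(seed=0)
        base = DEFAULT_PROFILES[3]
        doubled = type(base)(
            label=base.label,
            tremor_amplitude=2 * base.tremor_amplitude,
            duty_cycle=base.duty_cycle,
            noise_sd=0.0,
            drift_sd=0.0,
        )
        clean = type(base)(
            label=base.label,
            tremor_amplitude=base.tremor_amplitude,
            duty_cycle=base.duty_cycle,
            noise_sd=0.0,
            drift_sd=0.0,
        )
        f1 = ft.extract(derive_all(simulate_recording(clean, cfg, seed=11)))
        f2 = ft.extract(derive_all(simulate_recording(doubled, cfg, seed=11)))
        assert f2["acc.mean_amplitude"] / f1["acc.mean_amplitude"] == pytest.approx(2.0, rel=0.05)
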
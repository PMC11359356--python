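"""Acoustic battery: normalization, framing, and the 76-feature blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from articulab.acoustic import (
    ACOUSTIC_FEATURE_NAMES,
    FULLBAND_NAMES,
    NOISEBAND_NAMES,
    TIME_DOMAIN_NAMES,
    NoiseSpectrum,
    extract_acoustic,
    formant_ratios_distances,
    frame_segment,
    fricative_formants,
    fullband_features,
    noise_band_spectrum,
    noise_cepstral,
    noise_energies,
    noise_peak,
    normalize_segment,
    time_domain_features,
)
from articulab.containers import AudioSegment, PipelineConfig
from articulab.profiles import ArticulationClass, Sibilant

FS = 44100


def windowed_frame(signal_1455: np.ndarray) -> np.ndarray:
    return signal_1455 * np.hamming(len(signal_1455))


def tone(freq, n=1455, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestNormalization:
    def test_affine_map_endpoints(self):
        np.testing.assert_allclose(normalize_segment([2, 4, 6]), [0, 0.5, 1])
        np.testing.assert_allclose(normalize_segment([-1, 1]), [0, 1])

    def test_constant_segment_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_segment([0.3, 0.3, 0.3])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_range_and_idempotence(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        y = normalize_segment(x)
        assert y.min() == 0.0 and y.max() == 1.0
        np.testing.assert_allclose(normalize_segment(y), y, atol=1e-12)


class TestFraming:
    @given(st.integers(1455, 14550))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_frame_count_is_floor_of_length(self, n):
        frames = frame_segment(np.random.default_rng(n).random(n))
        assert frames.shape == (n // 1455, 1455)

    def test_known_counts(self):
        assert len(frame_segment(np.ones(14553) * np.linspace(0, 1, 14553))) == 10
        assert len(frame_segment(np.linspace(0, 1, 1455))) == 1

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_segment(np.zeros(1454))

    def test_hamming_window_applied(self):
        frames = frame_segment(np.ones(1455))
        np.testing.assert_allclose(frames[0], np.hamming(1455))


class TestTimeDomain:
    def test_zcr_of_pure_tone(self):
        zcr, *_ = time_domain_features(windowed_frame(tone(1000)), FS)
        expected = 2 * 1000 / FS
        assert abs(zcr - expected) / expected < 0.05

    def test_all_zero_frame_energy(self):
        _, ste, _, _ = time_domain_features(np.zeros(1455), FS)
        assert ste == 0.0

    def test_pitch_of_200hz_tone(self):
        _, _, pitch, hr = time_domain_features(windowed_frame(tone(200)), FS)
        assert abs(pitch - 200) <= 5
        assert hr > 0.3

    def test_noise_is_unvoiced(self, rng):
        _, _, pitch, _ = time_domain_features(
            windowed_frame(rng.standard_normal(1455)), FS
        )
        assert pitch == 0.0


class TestFullband:
    def test_centroid_of_pure_tone(self):
        feats = fullband_features(windowed_frame(tone(5000)), fs=FS)
        centroid = feats[0]
        assert abs(centroid - 5000) / 5000 < 0.01

    def test_flatness_of_white_noise(self, rng):
        feats = fullband_features(windowed_frame(rng.standard_normal(1455)), fs=FS)
        flatness = feats[6]
        assert 0.4 <= flatness <= 1.0

    def test_first_frame_flux_is_zero(self):
        feats = fullband_features(windowed_frame(tone(3000)), prev_frame=None, fs=FS)
        assert feats[7] == 0.0

    def test_flux_positive_for_changing_spectrum(self):
        a, b = windowed_frame(tone(3000)), windowed_frame(tone(8000))
        assert fullband_features(b, prev_frame=a, fs=FS)[7] > 0


class TestNoiseBand:
    def test_band_span(self):
        ns = noise_band_spectrum(windowed_frame(tone(5000)), FS, 2000.0)
        assert ns.freqs_hz.min() >= 2000.0
        assert ns.freqs_hz.max() <= FS / 2

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            noise_band_spectrum(np.ones(1455), FS, 22050.0)

    def test_band_power_is_subset_of_total(self, rng):
        frame = windowed_frame(rng.standard_normal(1455))
        from articulab.acoustic import power_spectrum

        _, full = power_spectrum(frame, FS)
        ns = noise_band_spectrum(frame, FS, 2000.0)
        assert ns.power.sum() <= full.sum() + 1e-9


def synthetic_peak_spectrum(peaks_hz, width_hz=200.0, band_low=2000.0):
    freqs = np.linspace(band_low, FS / 2, 1024)
    power = np.full_like(freqs, 1e-6)
    for pk in peaks_hz:
        power += np.exp(-0.5 * ((freqs - pk) / width_hz) ** 2)
    return NoiseSpectrum(freqs_hz=freqs, power=power, band_low_hz=band_low, band_high_hz=FS / 2)


class TestFricativeFormants:
    def test_recovers_four_constructed_peaks(self):
        ns = synthetic_peak_spectrum([3000, 5000, 7000, 9000])
        nff, nffl = fricative_formants(ns)
        bin_w = ns.freqs_hz[1] - ns.freqs_hz[0]
        np.testing.assert_allclose(nff, [3000, 5000, 7000, 9000], atol=bin_w + 1)
        assert np.all(np.diff(nff) >= 0)

    def test_single_peak_padding(self):
        ns = synthetic_peak_spectrum([4000])
        nff, _ = fricative_formants(ns)
        assert len(set(np.round(nff))) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_frequencies_sorted_ascending(self, seed):
        rng = np.random.default_rng(seed)
        peaks = rng.uniform(2500, 20000, size=4)
        nff, _ = fricative_formants(synthetic_peak_spectrum(peaks))
        assert np.all(np.diff(nff) >= 0)


class TestRatiosDistances:
    def test_stated_conventions(self):
        nffr, nflr, nffd = formant_ratios_distances(
            [3000, 6000, 9000, 12000], [10, 20, 30, 40]
        )
        assert nffr[0] == pytest.approx(0.5)  # NFFR12
        assert nffd[1] == pytest.approx(3000)  # NFFD23
        assert nflr[0] == pytest.approx(0.5)

    def test_equal_formants(self):
        nffr, _, nffd = formant_ratios_distances([5e3] * 4, [1.0] * 4)
        assert all(r == pytest.approx(1.0) for r in nffr)
        assert all(d == 0.0 for d in nffd)

    def test_zero_denominator_guard(self):
        _, nflr, _ = formant_ratios_distances([3e3, 4e3, 5e3, 6e3], [1.0, 0.0, 2.0, 3.0])
        assert nflr[0] == 0.0  # level ratio 1/0 guarded


class TestNoiseEnergies:
    def test_flat_spectrum_gives_equal_subbands(self):
        freqs = np.linspace(2000, FS / 2, 2000)
        ns = NoiseSpectrum(freqs, np.ones_like(freqs), 2000.0, FS / 2)
        ne = noise_energies(ns)
        assert max(ne) - min(ne) < 0.1

    def test_power_scaling_shifts_all_bands_10db(self, rng):
        freqs = np.linspace(2000, FS / 2, 512)
        power = rng.random(512) + 0.1
        ne1 = noise_energies(NoiseSpectrum(freqs, power, 2000.0, FS / 2))
        ne2 = noise_energies(NoiseSpectrum(freqs, 10 * power, 2000.0, FS / 2))
        np.testing.assert_allclose(np.subtract(ne2, ne1), 10.0, atol=1e-6)

    def test_concentrated_power_dominates_first_band(self):
        freqs = np.linspace(2000, FS / 2, 512)
        power = np.where(freqs < 4005, 1.0, 1e-9)
        ne = noise_energies(NoiseSpectrum(freqs, power, 2000.0, FS / 2))
        assert ne[0] > max(ne[1:])


class TestNoiseCepstral:
    def test_flat_spectrum_concentrates_in_ncc0(self):
        freqs = np.linspace(2000, FS / 2, 2048)
        ns = NoiseSpectrum(freqs, np.ones_like(freqs), 2000.0, FS / 2)
        ncc = noise_cepstral(ns)
        assert len(ncc) == 13
        # discretized filter energies are equal up to grid resolution
        assert np.max(np.abs(ncc[1:])) < 1e-4

    def test_power_scaling_changes_only_ncc0(self, rng):
        freqs = np.linspace(2000, FS / 2, 1024)
        power = rng.random(1024) + 0.5
        a = noise_cepstral(NoiseSpectrum(freqs, power, 2000.0, FS / 2))
        b = noise_cepstral(NoiseSpectrum(freqs, 7.0 * power, 2000.0, FS / 2))
        assert abs(a[0] - b[0]) > 1e-6
        np.testing.assert_allclose(a[1:], b[1:], atol=1e-9)


class TestNoisePeak:
    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.linspace(2000, FS / 2, 401)
        power = np.full_like(freqs, 0.1)
        i3k = np.argmin(np.abs(freqs - 3000))
        i5k = np.argmin(np.abs(freqs - 5000))
        power[i3k] = power[i5k] = 1.0
        _, npf = noise_peak(NoiseSpectrum(freqs, power, 2000.0, FS / 2))
        assert npf == pytest.approx(freqs[i3k])

    def test_peak_at_least_band_low(self, rng):
        freqs = np.linspace(2000, FS / 2, 256)
        _, npf = noise_peak(NoiseSpectrum(freqs, rng.random(256), 2000.0, FS / 2))
        assert npf >= 2000.0


@pytest.fixture(scope="module")
def segment():
    rng = np.random.default_rng(77)
    return AudioSegment(
        samples=rng.standard_normal(14553),
        fs=FS,
        speaker_id="spk",
        word="sa",
        sibilant=Sibilant.S,
        articulation_class=ArticulationClass.DENTAL,
    )


class TestExtractAcoustic:

    def test_canonical_shape_and_order(self, segment):
        mat = extract_acoustic(segment)
        assert mat.shape == (10, 76)
        assert list(mat.columns) == ACOUSTIC_FEATURE_NAMES

    def test_block_sizes(self):
        assert len(TIME_DOMAIN_NAMES) == 4
        assert len(FULLBAND_NAMES) == 24
        assert len(NOISEBAND_NAMES) == 48

    def test_ordered_formants_in_output(self, segment):
        mat = extract_acoustic(segment)
        nff = mat[["NFF1", "NFF2", "NFF3", "NFF4"]].to_numpy()
        assert np.all(np.diff(nff, axis=1) >= 0)
        nffd = mat[["NFFD12", "NFFD23", "NFFD34"]].to_numpy()
        assert np.all(nffd >= 0)
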
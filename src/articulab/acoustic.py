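"""Acoustic feature battery: 76 features per 33-ms frame.

Three blocks, in canonical order:

* time domain (4): ``ZCRt, STEt, Pt, HRt``
* full-band spectral (24): ``SCenf, SSprf, SSkf, SCrf, SDf, SEf, SFlaf,
  SFlxf, SRPf, SKurtf, SSlf, MFCC0..MFCC12``
* noise-band spectral (48): ``NFF1-4, NFFL1-4, NFFR{12,13,14,23,24,34},
  NFLR{12,13,14,23,24,34}, NCC0-12, NE0-9, NFFD{12,23,34}, NPA, NPF``

Segments are min-max normalized to [0, 1], cut into non-overlapping
1455-sample Hamming frames, and analysed with a 2048-point FFT.  The
noise band is [2 kHz, fs/2] by default — the region where sibilant
frication noise and its formants live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import dct, rfft, rfftfreq

from .containers import AudioSegment, PipelineConfig

log = logging.getLogger("articulab")

_EPS = 1e-12

TIME_DOMAIN_NAMES = ["ZCRt", "STEt", "Pt", "HRt"]
FULLBAND_NAMES = [
    "SCenf", "SSprf", "SSkf", "SCrf", "SDf", "SEf", "SFlaf", "SFlxf",
    "SRPf", "SKurtf", "SSlf",
] + [f"MFCC{i}" for i in range(13)]
_PAIRS6 = ["12", "13", "14", "23", "24", "34"]
NOISEBAND_NAMES = (
    [f"NFF{i}" for i in range(1, 5)]
    + [f"NFFL{i}" for i in range(1, 5)]
    + [f"NFFR{p}" for p in _PAIRS6]
    + [f"NFLR{p}" for p in _PAIRS6]
    + [f"NCC{i}" for i in range(13)]
    + [f"NE{i}" for i in range(10)]
    + [f"NFFD{p}" for p in ("12", "23", "34")]
    + ["NPA", "NPF"]
)
ACOUSTIC_FEATURE_NAMES = TIME_DOMAIN_NAMES + FULLBAND_NAMES + NOISEBAND_NAMES
assert len(ACOUSTIC_FEATURE_NAMES) == 76

#: Category label per acoustic feature (time-domain / full-band / noise).
ACOUSTIC_CATEGORY = {
    **{n: "time-domain" for n in TIME_DOMAIN_NAMES},
    **{n: "full-band" for n in FULLBAND_NAMES},
    **{n: "noise" for n in NOISEBAND_NAMES},
}


# ---------------------------------------------------------------------------
# preprocessing

def normalize_segment(samples: np.ndarray) -> np.ndarray:
    """Min-max normalize a segment to the [0, 1] range."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("segment must be a 1-D vector of length >= 2")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot normalize a constant segment (zero range)")
    return (x - lo) / (hi - lo)


def frame_segment(
    samples: np.ndarray,
    fs: int = 44100,
    frame_ms: float = 33.0,
    overlap: float = 0.0,
) -> np.ndarray:
    """Cut a segment into non-overlapping Hamming-windowed frames.

    Returns an (n_frames, frame_len) array; the trailing partial frame is
    dropped.  ``n_frames = floor(len(samples) / frame_len)``.
    """
    if overlap != 0.0:
        raise ValueError("only non-overlapping framing is supported")
    x = np.asarray(samples, dtype=float)
    frame_len = int(round(frame_ms * fs / 1000.0))
    n_frames = len(x) // frame_len
    if n_frames < 1:
        raise ValueError(
            f"segment of {len(x)} samples is shorter than one {frame_len}-sample frame"
        )
    frames = x[: n_frames * frame_len].reshape(n_frames, frame_len)
    return frames * np.hamming(frame_len)


# ---------------------------------------------------------------------------
# time-domain block

def time_domain_features(
    frame: np.ndarray,
    fs: int = 44100,
    pitch_range_hz: Tuple[float, float] = (50.0, 500.0),
    voicing_threshold: float = 0.3,
) -> Tuple[float, float, float, float]:
    """ZCRt, STEt, Pt, HRt for one frame.

    The zero-cross rate and autocorrelation operate on the mean-centred
    frame (the normalized signal lives in [0, 1] and never crosses zero
    itself).  Pitch is the autocorrelation peak within the 50-500 Hz lag
    range, reported as 0 for unvoiced frames (harmonic ratio below the
    voicing threshold) — the expected outcome for frication noise.
    """
    x = np.asarray(frame, dtype=float)
    n = len(x)
    xc = x - np.mean(x)
    signs = np.sign(xc)
    signs[signs == 0] = 1
    zcr = float(np.count_nonzero(np.diff(signs))) / (n - 1)
    ste = float(np.mean(x**2))
    lag_min = int(np.floor(fs / pitch_range_hz[1]))
    lag_max = int(np.ceil(fs / pitch_range_hz[0]))
    lag_max = min(lag_max, n - 1)
    r = sps.correlate(xc, xc, mode="full")[n - 1 :]
    r0 = r[0] if r[0] > 0 else _EPS
    rn = r / r0
    window = rn[lag_min : lag_max + 1]
    if len(window) == 0:
        return zcr, ste, 0.0, 0.0
    best = int(np.argmax(window))
    hr = float(np.clip(window[best], 0.0, 1.0))
    pitch = fs / (lag_min + best) if hr >= voicing_threshold else 0.0
    return zcr, ste, float(pitch), hr


# ---------------------------------------------------------------------------
# spectra

def _fft_size(frame_len: int) -> int:
    n = 1
    while n < frame_len:
        n *= 2
    return n


def power_spectrum(frame: np.ndarray, fs: int) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a (windowed) frame, zero-padded FFT."""
    x = np.asarray(frame, dtype=float)
    nfft = _fft_size(len(x))
    spec = rfft(x, n=nfft)
    return rfftfreq(nfft, 1.0 / fs), np.abs(spec) ** 2


@dataclass
class NoiseSpectrum:
    """Power spectrum restricted to the frication-noise band."""

    freqs_hz: np.ndarray
    power: np.ndarray
    band_low_hz: float
    band_high_hz: float

    def __post_init__(self):
        if len(self.freqs_hz) != len(self.power):
            raise ValueError("freqs and power must have equal length")


def noise_band_spectrum(
    frame: np.ndarray, fs: int = 44100, band_low_hz: float = 2000.0
) -> NoiseSpectrum:
    """Restrict a frame's power spectrum to [band_low_hz, fs/2]."""
    if band_low_hz >= fs / 2:
        raise ValueError(
            f"noise band [{band_low_hz}, {fs / 2}] Hz is empty"
        )
    freqs, power = power_spectrum(frame, fs)
    sel = freqs >= band_low_hz
    return NoiseSpectrum(
        freqs_hz=freqs[sel], power=power[sel],
        band_low_hz=band_low_hz, band_high_hz=fs / 2.0,
    )


# ---------------------------------------------------------------------------
# full-band block

def _triangular_filterbank(
    edges: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Triangular filters with the given (n_filters+2) edge frequencies."""
    n_filters = len(edges) - 2
    fb = np.zeros((n_filters, len(freqs)))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(mid - lo, _EPS)
        down = (hi - freqs) / max(hi - mid, _EPS)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


class _FilterbankCache:
    """Per-(fs, nfft) cached filterbanks; construction is the slow part."""

    def __init__(self):
        self._mel = {}
        self._noise = {}

    def mel(self, fs: int, nfft: int, n_filters: int) -> np.ndarray:
        key = (fs, nfft, n_filters)
        if key not in self._mel:
            freqs = rfftfreq(nfft, 1.0 / fs)
            edges = _mel_inv(np.linspace(_mel(0.0), _mel(fs / 2.0), n_filters + 2))
            self._mel[key] = _triangular_filterbank(edges, freqs)
        return self._mel[key]

    def noise(self, fs: int, nfft: int, band_low: float, n_filters: int) -> np.ndarray:
        key = (fs, nfft, band_low, n_filters)
        if key not in self._noise:
            freqs = rfftfreq(nfft, 1.0 / fs)
            sel = freqs >= band_low
            edges = np.linspace(band_low, fs / 2.0, n_filters + 2)
            self._noise[key] = _triangular_filterbank(edges, freqs[sel])
        return self._noise[key]


_FB = _FilterbankCache()


def fullband_features(
    frame: np.ndarray,
    prev_frame: Optional[np.ndarray] = None,
    fs: int = 44100,
    n_mel_filters: int = 26,
) -> List[float]:
    """The 24 full-band spectral features of one frame.

    Moment features use the power spectrum as a distribution over
    frequency; flux compares sum-normalized magnitude spectra with the
    previous frame (0 for the first frame); MFCCs come from a 26-filter
    mel filterbank over [0, fs/2] followed by a DCT-II.
    """
    freqs, power = power_spectrum(frame, fs)
    total = float(np.sum(power))
    if total <= _EPS:
        log.warning("all-zero spectrum; full-band features set to 0")
        return [0.0] * 24
    p = power / total
    centroid = float(np.sum(freqs * p))
    dev = freqs - centroid
    var = float(np.sum(dev**2 * p))
    spread = np.sqrt(var)
    skew = float(np.sum(dev**3 * p)) / (spread**3 + _EPS)
    kurt = float(np.sum(dev**4 * p)) / (var**2 + _EPS)
    crest = float(np.max(power) / (np.mean(power) + _EPS))
    # spectral decrease (level drop relative to the first bin)
    k = np.arange(1, len(power))
    decrease = float(np.sum((power[1:] - power[0]) / k) / (np.sum(power[1:]) + _EPS))
    entropy = float(-np.sum(p * np.log2(p + _EPS)) / np.log2(len(p)))
    flatness = float(
        np.exp(np.mean(np.log(power + _EPS))) / (np.mean(power) + _EPS)
    )
    if prev_frame is not None:
        _, prev_power = power_spectrum(prev_frame, fs)
        prev_total = float(np.sum(prev_power))
        if prev_total <= _EPS:
            flux = 0.0
        else:
            flux = float(np.sum((p - prev_power / prev_total) ** 2))
    else:
        flux = 0.0
    cum = np.cumsum(power)
    rolloff = float(freqs[int(np.searchsorted(cum, 0.95 * cum[-1]))])
    # spectral slope: linear regression of power on frequency
    fm = freqs - np.mean(freqs)
    slope = float(np.sum(fm * (power - np.mean(power))) / (np.sum(fm**2) + _EPS))
    fb = _FB.mel(fs, _fft_size(len(frame)), n_mel_filters)
    mel_energy = fb @ power
    mfcc = dct(np.log(mel_energy + _EPS), type=2, norm="ortho")[:13]
    return [
        centroid, spread, skew, crest, decrease, entropy, flatness, flux,
        rolloff, kurt, slope, *map(float, mfcc),
    ]


# ---------------------------------------------------------------------------
# noise-band block

def fricative_formants(
    ns: NoiseSpectrum, smooth_bins: int = 9
) -> Tuple[np.ndarray, np.ndarray]:
    """Estimate the four noise-formant frequencies (NFF1-4, ascending) and
    levels in dB (NFFL1-4).

    The log-power spectrum is smoothed with a moving average and the four
    most prominent local maxima are retained; with fewer than four peaks
    the highest-frequency peak is repeated, and with none the global
    maximum is used for all four.
    """
    if len(ns.power) < 3:
        raise ValueError("noise spectrum too short for peak picking")
    logp = 10.0 * np.log10(ns.power + _EPS)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(logp, kernel, mode="same")
    peaks, props = sps.find_peaks(smooth, prominence=0.0)
    if len(peaks) == 0:
        log.warning("no noise-band spectral peaks; falling back to global maximum")
        idx = int(np.argmax(smooth))
        chosen = np.array([idx] * 4)
    else:
        order = np.argsort(props["prominences"])[::-1][:4]
        chosen = np.sort(peaks[order])
        while len(chosen) < 4:
            chosen = np.append(chosen, chosen[-1])
    freqs = ns.freqs_hz[chosen].astype(float)
    levels = smooth[chosen].astype(float)
    return freqs, levels


def formant_ratios_distances(
    nff: Sequence[float], nffl: Sequence[float]
) -> Tuple[List[float], List[float], List[float]]:
    """NFFRij = NFFi/NFFj, NFLRij = NFFLi/NFFLj for the six i<j pairs and
    NFFDij = NFFj - NFFi for consecutive pairs; zero denominators give 0."""
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def safe_ratio(a, b):
        if abs(b) < _EPS:
            log.warning("zero denominator in formant ratio; feature set to 0")
            return 0.0
        return float(a / b)

    nffr = [safe_ratio(nff[i], nff[j]) for i, j in pairs]
    nflr = [safe_ratio(nffl[i], nffl[j]) for i, j in pairs]
    nffd = [float(nff[j] - nff[i]) for i, j in ((0, 1), (1, 2), (2, 3))]
    return nffr, nflr, nffd


def noise_energies(ns: NoiseSpectrum) -> List[float]:
    """NE0-9: log energy (dB) in 10 equal-width sub-bands of the noise band."""
    edges = np.linspace(ns.band_low_hz, ns.band_high_hz, 11)
    idx = np.clip(np.searchsorted(edges, ns.freqs_hz, side="right") - 1, 0, 9)
    sums = np.bincount(idx, weights=ns.power, minlength=10)
    return [float(10.0 * np.log10(s + _EPS)) for s in sums]


def noise_cepstral(
    ns: NoiseSpectrum, fs: int = 44100, nfft: Optional[int] = None,
    n_filters: int = 20,
) -> List[float]:
    """NCC0-12: DCT of log energies from 20 linearly spaced triangular
    filters spanning the noise band."""
    if nfft is None:
        fb_edges = np.linspace(ns.band_low_hz, ns.band_high_hz, n_filters + 2)
        fb = _triangular_filterbank(fb_edges, ns.freqs_hz)
    else:
        fb = _FB.noise(fs, nfft, ns.band_low_hz, n_filters)
    energies = fb @ ns.power
    ncc = dct(np.log(energies + _EPS), type=2, norm="ortho")[:13]
    return [float(c) for c in ncc]


def noise_peak(ns: NoiseSpectrum) -> Tuple[float, float]:
    """(NPA, NPF): amplitude in dB and frequency of the noise-band power
    maximum; ties break toward the lower frequency."""
    idx = int(np.argmax(ns.power))
    npa = float(10.0 * np.log10(ns.power[idx] + _EPS))
    return npa, float(ns.freqs_hz[idx])


# ---------------------------------------------------------------------------
# frame/segment drivers

def frame_features(
    frame: np.ndarray,
    prev_frame: Optional[np.ndarray],
    cfg: PipelineConfig,
) -> List[float]:
    """All 76 features of one windowed frame, in canonical order."""
    zcr, ste, pitch, hr = time_domain_features(
        frame, cfg.fs, cfg.pitch_range_hz, cfg.voicing_threshold
    )
    full = fullband_features(frame, prev_frame, cfg.fs, cfg.n_mel_filters)
    ns = noise_band_spectrum(frame, cfg.fs, cfg.noise_band_low_hz)
    nff, nffl = fricative_formants(ns, cfg.formant_smooth_bins)
    nffr, nflr, nffd = formant_ratios_distances(nff, nffl)
    ne = noise_energies(ns)
    ncc = noise_cepstral(ns, cfg.fs, _fft_size(len(frame)), cfg.n_noise_filters)
    npa, npf = noise_peak(ns)
    row = [zcr, ste, pitch, hr] + full + (
        list(map(float, nff)) + list(map(float, nffl)) + nffr + nflr
        + ncc + ne + nffd + [npa, npf]
    )
    return row


def extract_acoustic(
    segment: AudioSegment, cfg: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Per-frame acoustic feature matrix (n_frames x 76) for one segment."""
    cfg = cfg or PipelineConfig()
    normalized = normalize_segment(segment.samples)
    frames = frame_segment(normalized, cfg.fs, cfg.frame_ms, cfg.overlap)
    rows = []
    prev = None
    for frame in frames:
        rows.append(frame_features(frame, prev, cfg))
        prev = frame
    return pd.DataFrame(rows, columns=ACOUSTIC_FEATURE_NAMES)
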
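"""Synthetic multimodal corpus generator.

Produces frication-noise audio segments and synchronized dual-camera
articulator mask sequences whose statistics depend on the articulation
class, so that the full extraction + statistics pipeline can be exercised
and calibrated without any recorded data.

The audio model is white noise shaped by a parallel bank of second-order
band-pass resonators (one per noise formant); the image model renders an
elliptical lip annulus around a mouth-interior region in which the tongue
appears with a class-dependent probability and area.  Left/right camera
views are independently jittered renderings of the same articulator state.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal

from .containers import (
    AudioSegment,
    Cohort,
    MaskFrame,
    PipelineConfig,
    SegmentData,
    SpeakerData,
    LABEL_LIPS,
    LABEL_MOUTH_INTERIOR,
    LABEL_TEETH,
    LABEL_TONGUE,
)
from .profiles import ALLOWED_CLASSES, ClassProfile, CohortConfig, DEFAULT_WORDS

#: Base gray intensities per mask label (background, lips, teeth, tongue,
#: mouth interior) used when rendering frames.
_BASE_INTENSITY = {0: 30.0, 1: 120.0, 2: 220.0, 3: 160.0, 4: 70.0}

_SILENCE_PAD_S = 0.05


def _segment_rng(master_seed: int, *counters: int) -> np.random.Generator:
    """Deterministic sub-stream: master seed plus a counter tuple."""
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *counters])


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def sample_speaker_profile(
    profile: ClassProfile, rng: np.random.Generator
) -> ClassProfile:
    """Draw one speaker's realization of a class profile.

    Children vary around their class pattern: the whole noise-formant
    stack shifts by a common N(0, speaker_peak_sd_hz) offset, tongue
    visibility is jittered on the logit scale, the speaker's mean tongue
    area is drawn from the class Normal(mean, sd) (truncated low), and the
    mouth axes get a small speaker-specific offset.  Frame-to-frame area
    variation within the speaker uses 15% of the speaker mean.
    """
    from dataclasses import replace

    sd = profile.speaker_peak_sd_hz
    shift = float(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd))
    prob = 1.0 / (1.0 + math.exp(-(_logit(profile.tongue_presence_prob)
                                   + rng.normal(0.0, profile.speaker_logit_sd))))
    area_mean = max(
        rng.normal(profile.tongue_area_mean_px, profile.tongue_area_sd_px), 50.0
    )
    axes = tuple(
        max(a + rng.normal(0.0, profile.speaker_axes_sd_px), 20.0)
        for a in profile.mouth_axes_px
    )
    return replace(
        profile,
        noise_peak_hz=profile.noise_peak_hz + shift,
        formant_freqs_hz=tuple(f + shift for f in profile.formant_freqs_hz),
        tongue_presence_prob=prob,
        tongue_area_mean_px=area_mean,
        tongue_area_sd_px=0.15 * area_mean,
        mouth_axes_px=axes,
    )


def synth_fricative_segment(
    profile: ClassProfile,
    duration_s: float,
    fs: int = 44100,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Generate one frication-noise segment.

    White noise is fed through a parallel bank of second-order band-pass
    filters centred at the profile's formant frequencies with the given
    relative gains, plus a weak broadband floor.  The strongest resonance
    sits at ``profile.noise_peak_hz`` so the power-spectrum argmax above
    the noise-band cutoff recovers it.

    Returns the raw float sample vector of length ``round(duration_s*fs)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    profile.validated_for_fs(fs)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    warmup = 2048
    white = rng.standard_normal(n + warmup)
    out = 0.02 * white  # broadband noise floor
    nyq = fs / 2.0
    for f0, gain_db in zip(profile.formant_freqs_hz, profile.formant_gains_db):
        # dominant (0 dB) resonance is sharper, pinning the spectral peak
        bw = (200.0 + 0.04 * f0) if gain_db >= 0 else (250.0 + 0.10 * f0)
        lo = max(f0 - bw / 2.0, 50.0) / nyq
        hi = min(f0 + bw / 2.0, nyq * 0.999) / nyq
        sos = signal.butter(2, [lo, hi], btype="bandpass", output="sos")
        shaped = signal.sosfilt(sos, white)
        # normalise the band energy so the dB gains control relative levels
        rms = np.sqrt(np.mean(shaped[warmup:] ** 2)) or 1.0
        out = out + (10.0 ** (gain_db / 20.0)) * shaped / rms
    seg = out[warmup:]
    peak = np.max(np.abs(seg)) or 1.0
    return 0.5 * seg / peak


def measure_spectral_peak(
    samples: np.ndarray, fs: int, band_low_hz: float = 2000.0
) -> float:
    """Welch-estimate of the power-spectrum argmax above ``band_low_hz``."""
    nper = min(len(samples), 2048)
    freqs, pxx = signal.welch(samples, fs=fs, nperseg=nper)
    sel = freqs >= band_low_hz
    if not np.any(sel):
        raise ValueError("band is empty")
    return float(freqs[sel][np.argmax(pxx[sel])])


def _ellipse_mask(
    yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, a: float, b: float
) -> np.ndarray:
    """Filled ellipse with semi-axes a (cols) and b (rows)."""
    return ((xx - cx) / max(a, 1e-9)) ** 2 + ((yy - cy) / max(b, 1e-9)) ** 2 <= 1.0


def _render_view(
    shape: Tuple[int, int],
    cy: float,
    cx: float,
    outer: Tuple[float, float],
    inner: Tuple[float, float],
    tongue_area: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    label = np.zeros(shape, dtype=np.uint8)
    m_outer = _ellipse_mask(yy, xx, cy, cx, *outer)
    m_inner = _ellipse_mask(yy, xx, cy, cx, *inner)
    label[m_outer & ~m_inner] = LABEL_LIPS
    label[m_inner] = LABEL_MOUTH_INTERIOR
    # thin upper-teeth band inside the mouth opening (ignored by features)
    teeth = m_inner & (yy < cy - 0.45 * inner[1]) & (yy >= cy - 0.8 * inner[1])
    label[teeth] = LABEL_TEETH
    if tongue_area > 0:
        aspect = 1.5
        a_t = math.sqrt(tongue_area * aspect / math.pi)
        b_t = a_t / aspect
        t_cy = cy + 0.25 * inner[1]
        m_tongue = _ellipse_mask(yy, xx, t_cy, cx, a_t, b_t) & m_inner
        label[m_tongue] = LABEL_TONGUE
    base = np.empty(shape, dtype=float)
    for lab, inten in _BASE_INTENSITY.items():
        base[label == lab] = inten
    gray = base + rng.normal(0.0, noise_sd, size=shape)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return gray, label


def synth_mask_sequence(
    profile: ClassProfile,
    n_frames: int,
    image_size: Tuple[int, int] = (96, 128),
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[MaskFrame, MaskFrame]]:
    """Render a sequence of (left, right) camera mask frames.

    Per frame the tongue is visible with probability
    ``profile.tongue_presence_prob``; when visible, its area is drawn from
    Normal(mean, sd) truncated at 0.  Both camera views render the same
    articulator state with independent position jitter and pixel noise.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = image_size
    a_out = profile.mouth_axes_px[0] / 2.0
    b_out = profile.mouth_axes_px[1] / 2.0
    a_in, b_in = a_out - 6.0, b_out - 6.0
    frames: List[Tuple[MaskFrame, MaskFrame]] = []
    for idx in range(n_frames):
        present = rng.random() < profile.tongue_presence_prob
        area = 0.0
        if present:
            area = max(
                rng.normal(profile.tongue_area_mean_px, profile.tongue_area_sd_px),
                0.0,
            )
        pair = []
        for cam in ("left", "right"):
            cy = h / 2.0 + rng.normal(0.0, 1.0)
            cx = w / 2.0 + rng.normal(0.0, 1.0)
            jit = rng.normal(0.0, 0.5, size=2)
            gray, label = _render_view(
                (h, w),
                cy,
                cx,
                (a_out + jit[0], b_out + jit[1]),
                (a_in + jit[0], b_in + jit[1]),
                area,
                profile.texture_noise_sd,
                rng,
            )
            pair.append(
                MaskFrame(gray_image=gray, label_mask=label, camera=cam, frame_index=idx)
            )
        frames.append((pair[0], pair[1]))
    return frames


def generate_cohort(
    config: CohortConfig,
    out_dir: Optional[Path] = None,
    pipeline_config: Optional[PipelineConfig] = None,
) -> Cohort:
    """Generate a full synthetic cohort.

    Speakers are created per class according to ``config.group_sizes``;
    each speaker produces ``config.words_per_speaker`` segments with
    synchronized audio and dual-camera mask sequences (one video frame per
    33-ms audio frame).  With ``out_dir`` set, the corpus is also written
    to disk (WAV + PNG + manifest.csv) via :mod:`articulab.corpus_io`.

    Reproducibility: speaker ``i``'s segment ``j`` uses the sub-stream
    seeded by ``(master_seed, i, j)``, so any speaker can be regenerated
    in isolation.
    """
    pcfg = pipeline_config or PipelineConfig(fs=config.fs)
    frame_len = pcfg.frame_len
    words = DEFAULT_WORDS[config.sibilant]
    cohort = Cohort(sibilant=config.sibilant)
    lo, hi = config.segment_duration_range_s
    min_dur = frame_len / config.fs
    speaker_idx = 0
    for cls in ALLOWED_CLASSES[config.sibilant]:
        if cls not in config.group_sizes:
            continue
        class_profile = config.profiles[cls].validated_for_fs(config.fs)
        for k in range(config.group_sizes[cls]):
            spk_id = f"{config.sibilant.value}-{cls.value[:5]}-{speaker_idx:03d}"
            speaker = SpeakerData(
                speaker_id=spk_id,
                sibilant=config.sibilant,
                articulation_class=cls,
            )
            spk_rng = _segment_rng(config.seed, speaker_idx)
            profile = sample_speaker_profile(class_profile, spk_rng)
            profile.validated_for_fs(config.fs)
            for j in range(config.words_per_speaker):
                rng = _segment_rng(config.seed, speaker_idx, j)
                dur = max(rng.uniform(lo, hi), min_dur * 1.05)
                samples = synth_fricative_segment(
                    profile, dur, fs=config.fs, rng=rng
                )
                n_video = len(samples) // frame_len
                frames = synth_mask_sequence(
                    profile,
                    n_frames=max(n_video, 1),
                    image_size=config.image_size_px,
                    rng=rng,
                )
                audio = AudioSegment(
                    samples=samples,
                    fs=config.fs,
                    speaker_id=spk_id,
                    word=words[j % len(words)],
                    sibilant=config.sibilant,
                    articulation_class=cls,
                )
                speaker.segments.append(SegmentData(audio=audio, frames=frames))
            cohort.speakers.append(speaker)
            speaker_idx += 1
    if out_dir is not None:
        from . import corpus_io

        corpus_io.write_cohort(cohort, out_dir, pad_s=_SILENCE_PAD_S)
        cohort.root = Path(out_dir)
    return cohort
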
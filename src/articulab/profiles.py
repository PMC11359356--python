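"""Articulation classes and synthetic class profiles.

The study contrasts places of articulation of two Polish sibilants:
/s/ (dental vs. interdental realizations) and /ʂ/ (alveolar, dental and
postalveolar realizations).  A :class:`ClassProfile` collects the knobs the
synthetic-corpus generator uses to give each articulation class its own
acoustic and visual signature: the centre of the frication-noise band, a
stack of noise-formant resonances, how often (and how large) the tongue is
visible between the lips, the mouth-opening geometry and the image noise
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Mapping, Tuple


class Sibilant(str, Enum):
    """The two sibilants under study (ASCII identifiers for file paths)."""

    S = "s"      # /s/
    SH = "sh"    # /ʂ/

    @property
    def ipa(self) -> str:
        return {"s": "/s/", "sh": "/ʂ/"}[self.value]


class ArticulationClass(str, Enum):
    DENTAL = "dental"
    INTERDENTAL = "interdental"
    ALVEOLAR = "alveolar"
    POSTALVEOLAR = "postalveolar"


#: Classes retained per sibilant after the small groups were dropped,
#: in the 1/2/3 order used for post hoc pair labels.
ALLOWED_CLASSES: Dict[Sibilant, Tuple[ArticulationClass, ...]] = {
    Sibilant.S: (ArticulationClass.DENTAL, ArticulationClass.INTERDENTAL),
    Sibilant.SH: (
        ArticulationClass.ALVEOLAR,
        ArticulationClass.DENTAL,
        ArticulationClass.POSTALVEOLAR,
    ),
}

#: Observation counts per group in the study design.
DEFAULT_GROUP_SIZES: Dict[Sibilant, Dict[ArticulationClass, int]] = {
    Sibilant.S: {
        ArticulationClass.DENTAL: 113,
        ArticulationClass.INTERDENTAL: 31,
    },
    Sibilant.SH: {
        ArticulationClass.ALVEOLAR: 106,
        ArticulationClass.DENTAL: 27,
        ArticulationClass.POSTALVEOLAR: 29,
    },
}

#: Carrier words per sibilant (ASCII-folded subset of the recording list).
DEFAULT_WORDS: Dict[Sibilant, Tuple[str, ...]] = {
    Sibilant.S: ("sa", "pies", "las", "parasol", "samolot"),
    Sibilant.SH: ("sza", "szafa", "kasza", "koszyk", "szalik"),
}


def coerce_sibilant(value) -> Sibilant:
    if isinstance(value, Sibilant):
        return value
    try:
        return Sibilant(str(value))
    except ValueError:
        raise ValueError(
            f"unknown sibilant {value!r}; expected one of "
            f"{[s.value for s in Sibilant]}"
        ) from None


def coerce_class(value) -> ArticulationClass:
    if isinstance(value, ArticulationClass):
        return value
    try:
        return ArticulationClass(str(value))
    except ValueError:
        raise ValueError(
            f"unknown articulation class {value!r}; expected one of "
            f"{[c.value for c in ArticulationClass]}"
        ) from None


def check_class_allowed(sibilant, articulation_class) -> None:
    sib = coerce_sibilant(sibilant)
    cls = coerce_class(articulation_class)
    if cls not in ALLOWED_CLASSES[sib]:
        raise ValueError(
            f"articulation class {cls.value!r} is not analysed for {sib.ipa}; "
            f"allowed: {[c.value for c in ALLOWED_CLASSES[sib]]}"
        )


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters of one articulation class.

    Parameters
    ----------
    noise_peak_hz
        Centre of the dominant frication-noise resonance; the spectral
        argmax of generated segments above the noise-band cutoff.
    formant_freqs_hz, formant_gains_db
        Four noise-formant centre frequencies (strictly increasing, below
        Nyquist) and their relative levels in dB.  The 0 dB formant is the
        dominant one.
    tongue_presence_prob
        Per-frame probability that the tongue is visible in the mouth
        opening.
    tongue_area_mean_px, tongue_area_sd_px
        Normal(mean, sd) law (truncated at 0) for the visible tongue area.
    mouth_axes_px
        Full major/minor axis lengths of the outer lip ellipse.
    texture_noise_sd
        Gaussian gray-level noise added to the rendered frames.
    """

    noise_peak_hz: float
    formant_freqs_hz: Tuple[float, float, float, float]
    formant_gains_db: Tuple[float, float, float, float]
    tongue_presence_prob: float
    tongue_area_mean_px: float
    tongue_area_sd_px: float
    mouth_axes_px: Tuple[float, float] = (72.0, 44.0)
    texture_noise_sd: float = 8.0
    # between-speaker variability around the class profile
    speaker_peak_sd_hz: float = 350.0
    speaker_logit_sd: float = 0.8
    speaker_axes_sd_px: float = 2.5

    def __post_init__(self):
        if not 0.0 <= self.tongue_presence_prob <= 1.0:
            raise ValueError("tongue_presence_prob must be in [0, 1]")
        if self.tongue_area_mean_px < 0:
            raise ValueError("tongue_area_mean_px must be >= 0")
        freqs = tuple(self.formant_freqs_hz)
        if len(freqs) != 4 or any(
            f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])
        ):
            raise ValueError("formant_freqs_hz must be 4 strictly increasing values")

    def validated_for_fs(self, fs: float) -> "ClassProfile":
        if max(self.formant_freqs_hz) >= fs / 2:
            raise ValueError(
                f"formant frequency {max(self.formant_freqs_hz)} Hz is at or "
                f"above Nyquist ({fs / 2} Hz)"
            )
        return self


def _formant_stack(peak_hz: float) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Dominant resonance at the noise peak plus three weaker ones above it."""
    freqs = tuple(round(peak_hz * r) for r in (1.0, 1.45, 1.9, 2.4))
    gains = (0.0, -10.0, -14.0, -18.0)
    return freqs, gains


def make_default_profiles(sibilant) -> Dict[ArticulationClass, ClassProfile]:
    """Shipped per-class generator profiles.

    The qualitative structure mirrors the study's findings: for /s/ the
    interdental realization shows the tongue far more often and with a
    larger visible area than the dental one (with only a small noise-band
    shift), while the three /ʂ/ realizations differ mainly by the position
    of the frication-noise band.  Individual speakers vary around their
    class profile (noise peak sd 350 Hz, tongue-visibility logit sd 0.8),
    emulating inter-child variability.
    """
    sib = coerce_sibilant(sibilant)
    profiles: Dict[ArticulationClass, ClassProfile] = {}
    if sib is Sibilant.S:
        # dental: tongue mostly hidden, its occasional visibility erratic
        # (high speaker-level spread); interdental: consistent protrusion.
        f, g = _formant_stack(5100.0)
        profiles[ArticulationClass.DENTAL] = ClassProfile(
            noise_peak_hz=5100.0,
            formant_freqs_hz=f,
            formant_gains_db=g,
            tongue_presence_prob=0.15,
            tongue_area_mean_px=300.0,
            tongue_area_sd_px=110.0,
            speaker_logit_sd=1.7,
        )
        f, g = _formant_stack(4800.0)
        profiles[ArticulationClass.INTERDENTAL] = ClassProfile(
            noise_peak_hz=4800.0,
            formant_freqs_hz=f,
            formant_gains_db=g,
            tongue_presence_prob=0.75,
            tongue_area_mean_px=900.0,
            tongue_area_sd_px=70.0,
            speaker_logit_sd=0.5,
        )
    else:
        # tongue-tip contact with teeth/gums in all three classes: similar,
        # moderate tongue visibility; the classes separate acoustically.
        peaks = {
            ArticulationClass.ALVEOLAR: 3200.0,
            ArticulationClass.DENTAL: 4800.0,
            ArticulationClass.POSTALVEOLAR: 2600.0,
        }
        for cls, peak in peaks.items():
            f, g = _formant_stack(peak)
            profiles[cls] = ClassProfile(
                noise_peak_hz=peak,
                formant_freqs_hz=f,
                formant_gains_db=g,
                tongue_presence_prob=0.35,
                tongue_area_mean_px=450.0,
                tongue_area_sd_px=120.0,
            )
    return profiles


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort (one sibilant)."""

    sibilant: Sibilant = Sibilant.S
    group_sizes: Dict[ArticulationClass, int] = field(default_factory=dict)
    words_per_speaker: int = 2
    segment_duration_range_s: Tuple[float, float] = (0.12, 0.30)
    image_size_px: Tuple[int, int] = (96, 128)
    fs: int = 44100
    seed: int = 0
    profiles: Dict[ArticulationClass, ClassProfile] = field(default_factory=dict)

    def __post_init__(self):
        self.sibilant = coerce_sibilant(self.sibilant)
        if not self.group_sizes:
            self.group_sizes = dict(DEFAULT_GROUP_SIZES[self.sibilant])
        else:
            self.group_sizes = {
                coerce_class(k): int(v) for k, v in self.group_sizes.items()
            }
        for cls, n in self.group_sizes.items():
            check_class_allowed(self.sibilant, cls)
            if n <= 0:
                raise ValueError(f"group size for {cls.value} must be > 0")
        if self.words_per_speaker <= 0:
            raise ValueError("words_per_speaker must be > 0")
        lo, hi = self.segment_duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("segment_duration_range_s must be positive")
        if not self.profiles:
            self.profiles = make_default_profiles(self.sibilant)
        else:
            self.profiles = {coerce_class(k): v for k, v in self.profiles.items()}
        missing = set(self.group_sizes) - set(self.profiles)
        if missing:
            raise ValueError(
                f"no profile for classes {[c.value for c in missing]}"
            )

    def with_profiles(self, profiles) -> "CohortConfig":
        cfg = replace(self)
        cfg.profiles = {coerce_class(k): v for k, v in profiles.items()}
        return cfg
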
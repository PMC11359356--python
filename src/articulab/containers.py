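"""Core in-memory containers shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .profiles import ArticulationClass, Sibilant, check_class_allowed

VALID_MASK_LABELS = frozenset({0, 1, 2, 3, 4})

#: Label values in the articulator masks.
LABEL_BACKGROUND = 0
LABEL_LIPS = 1
LABEL_TEETH = 2
LABEL_TONGUE = 3
LABEL_MOUTH_INTERIOR = 4


@dataclass
class AudioSegment:
    """One sibilant realization: samples plus identifying labels."""

    samples: np.ndarray
    fs: int
    speaker_id: str
    word: str
    sibilant: Sibilant
    articulation_class: ArticulationClass

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment samples must be mono (1-D)")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class MaskFrame:
    """One camera frame: grayscale image plus articulator label mask."""

    gray_image: np.ndarray
    label_mask: np.ndarray
    camera: str  # "left" | "right"
    frame_index: int

    def __post_init__(self):
        self.gray_image = np.asarray(self.gray_image)
        self.label_mask = np.asarray(self.label_mask)
        if self.gray_image.shape != self.label_mask.shape:
            raise ValueError(
                f"gray image shape {self.gray_image.shape} != mask shape "
                f"{self.label_mask.shape}"
            )
        if self.camera not in ("left", "right"):
            raise ValueError(f"camera must be 'left' or 'right', got {self.camera!r}")
        labels = set(np.unique(self.label_mask).tolist())
        bad = labels - VALID_MASK_LABELS
        if bad:
            raise ValueError(f"mask contains invalid labels {sorted(bad)}")


@dataclass
class SegmentRecord:
    """Manifest row locating one annotated sibilant segment on disk."""

    speaker_id: str
    word: str
    sibilant: Sibilant
    articulation_class: ArticulationClass
    wav_path: Path
    t_start_s: float
    t_end_s: float

    def __post_init__(self):
        self.wav_path = Path(self.wav_path)
        if self.t_end_s <= self.t_start_s:
            raise ValueError(
                f"t_end_s ({self.t_end_s}) must exceed t_start_s ({self.t_start_s})"
            )
        check_class_allowed(self.sibilant, self.articulation_class)


@dataclass
class SegmentData:
    """A fully loaded segment: audio plus synchronized dual-camera frames."""

    audio: AudioSegment
    frames: List[Tuple[MaskFrame, MaskFrame]]  # (left, right) per video frame


@dataclass
class SpeakerData:
    speaker_id: str
    sibilant: Sibilant
    articulation_class: ArticulationClass
    segments: List[SegmentData] = field(default_factory=list)


@dataclass
class Cohort:
    """A set of speakers with articulation-class labels."""

    sibilant: Sibilant
    speakers: List[SpeakerData] = field(default_factory=list)
    root: Optional[Path] = None

    def group_sizes(self) -> Dict[ArticulationClass, int]:
        sizes: Dict[ArticulationClass, int] = {}
        for spk in self.speakers:
            sizes[spk.articulation_class] = sizes.get(spk.articulation_class, 0) + 1
        return sizes


@dataclass
class PipelineConfig:
    """Shared processing constants.

    Defaults follow the study protocol: 44.1 kHz audio cut into 33-ms
    non-overlapping Hamming frames (to match the video frame rate), 32
    gray levels for texture analysis, 25% frame cropping at each end of a
    segment, alpha = 0.05 and the [0.1, 10] variance-ratio screen.
    """

    fs: int = 44100
    frame_ms: float = 33.0
    window: str = "hamming"
    overlap: float = 0.0
    noise_band_low_hz: float = 2000.0
    gray_levels: int = 32
    crop_fraction: float = 0.25
    alpha: float = 0.05
    variance_ratio_bounds: Tuple[float, float] = (0.1, 10.0)
    skew_threshold: float = 2.0
    # estimator details
    n_mel_filters: int = 26
    n_noise_filters: int = 20
    formant_smooth_bins: int = 9
    pitch_range_hz: Tuple[float, float] = (50.0, 500.0)
    voicing_threshold: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.crop_fraction < 0.5:
            raise ValueError("crop_fraction must be in [0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.overlap != 0.0:
            raise ValueError("only non-overlapping frames are supported")
        lo, hi = self.variance_ratio_bounds
        if not (0 < lo < 1 < hi):
            raise ValueError("variance_ratio_bounds must straddle 1")

    @property
    def frame_len(self) -> int:
        """Frame length in samples (1455 at the default 33 ms / 44.1 kHz)."""
        return int(round(self.frame_ms * self.fs / 1000.0))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variance_ratio_bounds", "pitch_range_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
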
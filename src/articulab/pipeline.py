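"""End-to-end feature extraction: cohort -> one 250-feature row per speaker.

The hybrid vector concatenates 76 acoustic features with the 87 visual
features of each camera (suffixes ``_L`` / ``_R``), 250 columns in total.
Visual features are computed only for the frames retained by the 25%
end-cropping (per-frame features are independent, so cropping first is
equivalent to extracting everything and cropping afterwards); acoustic
features are computed for all frames (spectral flux needs the previous
frame) and cropped at aggregation time.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import acoustic, visual
from .aggregate import crop_frames
from .containers import Cohort, PipelineConfig, SegmentData, SpeakerData
from .corpus_io import load_cohort, rows_to_table

log = logging.getLogger("articulab")

HYBRID_FEATURE_NAMES = (
    list(acoustic.ACOUSTIC_FEATURE_NAMES)
    + [f"{n}_L" for n in visual.VISUAL_FEATURE_NAMES]
    + [f"{n}_R" for n in visual.VISUAL_FEATURE_NAMES]
)
assert len(HYBRID_FEATURE_NAMES) == 250

ID_COLUMNS = ["speaker_id", "sibilant", "articulation_class"]


def classify_feature_name(name: str) -> Dict[str, str]:
    """Metadata for a hybrid feature column: data kind (A/V), category and
    camera."""
    if name in acoustic.ACOUSTIC_CATEGORY:
        return {
            "data_kind": "A",
            "category": acoustic.ACOUSTIC_CATEGORY[name],
            "camera": "none",
        }
    for suffix, camera in (("_L", "left"), ("_R", "right")):
        if name.endswith(suffix):
            base = name[: -len(suffix)]
            if base in visual.VISUAL_CATEGORY:
                return {
                    "data_kind": "V",
                    "category": visual.VISUAL_CATEGORY[base],
                    "camera": camera,
                }
    raise KeyError(f"unknown feature name {name!r}")


def extract_segment_matrices(
    segment: SegmentData,
    cfg: PipelineConfig,
    modalities: Tuple[str, ...] = ("audio", "video"),
    precrop_video: bool = True,
) -> pd.DataFrame:
    """Per-frame feature matrix of one segment (frames x selected columns).

    With ``precrop_video`` the visual features of frames outside the
    retained crop window are left as NaN and skipped at aggregation.
    """
    parts: List[pd.DataFrame] = []
    n_frames = None
    if "audio" in modalities:
        am = acoustic.extract_acoustic(segment.audio, cfg)
        n_frames = len(am)
        parts.append(am)
    if "video" in modalities:
        n_video = len(segment.frames)
        if n_frames is not None and n_video != n_frames:
            raise ValueError(
                f"segment {segment.audio.speaker_id}/{segment.audio.word}: "
                f"{n_video} video frames but {n_frames} audio frames"
            )
        keep = crop_frames(n_video, cfg.crop_fraction) if precrop_video else range(n_video)
        vrows = np.full((n_video, 2 * len(visual.VISUAL_FEATURE_NAMES)), np.nan)
        for idx in keep:
            left, right = segment.frames[idx]
            fl = visual.extract_visual(left, cfg.gray_levels)
            fr = visual.extract_visual(right, cfg.gray_levels)
            vrows[idx] = list(fl.values()) + list(fr.values())
        vcols = [f"{n}_L" for n in visual.VISUAL_FEATURE_NAMES] + [
            f"{n}_R" for n in visual.VISUAL_FEATURE_NAMES
        ]
        parts.append(pd.DataFrame(vrows, columns=vcols))
    if not parts:
        raise ValueError("no modalities selected")
    return pd.concat(parts, axis=1)


def speaker_vector(
    speaker: SpeakerData,
    cfg: PipelineConfig,
    modalities: Tuple[str, ...] = ("audio", "video"),
) -> Dict[str, float]:
    """One aggregated hybrid feature row for a speaker."""
    if not speaker.segments:
        raise ValueError(f"speaker {speaker.speaker_id} has no segments")
    blocks: List[np.ndarray] = []
    columns = None
    for seg in speaker.segments:
        m = extract_segment_matrices(seg, cfg, modalities)
        columns = list(m.columns)
        keep = crop_frames(len(m), cfg.crop_fraction)
        blocks.append(m.to_numpy()[keep.start : keep.stop])
    pooled = np.vstack(blocks)
    means = np.nanmean(pooled, axis=0)
    row: Dict[str, float] = {
        "speaker_id": speaker.speaker_id,
        "sibilant": speaker.sibilant.value,
        "articulation_class": speaker.articulation_class.value,
    }
    row.update(zip(columns, means))
    return row


def extract_speaker_table(
    cohort,
    cfg: Optional[PipelineConfig] = None,
    modalities: Tuple[str, ...] = ("audio", "video"),
) -> pd.DataFrame:
    """Speaker-level feature table for a cohort (in memory or on disk).

    Returns one row per speaker with id columns plus the selected feature
    columns (250 for the full hybrid set).
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(cohort, Cohort):
        cohort = load_cohort(Path(cohort), cfg)
    t0 = time.perf_counter()
    rows = [speaker_vector(spk, cfg, modalities) for spk in cohort.speakers]
    log.info(
        "extracted %d speaker vectors in %.1f s",
        len(rows),
        time.perf_counter() - t0,
    )
    return rows_to_table(rows)
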
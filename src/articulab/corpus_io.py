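"""On-disk corpus formats: WAV segments, PNG mask frames, manifests and
feature tables.

Corpus layout::

    corpus/<speaker>/<word>__<k>.wav
    corpus/<speaker>/<word>__<k>/<frame>_{L,R}_img.png
    corpus/<speaker>/<word>__<k>/<frame>_{L,R}_mask.png
    corpus/manifest.csv

Manifest columns: speaker_id, word, sibilant, class, wav_path, t_start_s,
t_end_s.  Mask PNGs are 8-bit single channel with label values 0
background, 1 lips, 2 teeth, 3 tongue, 4 mouth interior.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .containers import (
    AudioSegment,
    Cohort,
    MaskFrame,
    PipelineConfig,
    SegmentData,
    SegmentRecord,
    SpeakerData,
    VALID_MASK_LABELS,
)
from .profiles import coerce_class, coerce_sibilant

log = logging.getLogger("articulab")

_CAM_SUFFIX = {"left": "L", "right": "R"}


# ---------------------------------------------------------------------------
# audio

def write_wav(path: Path, samples: np.ndarray, fs: int) -> None:
    """Write mono float samples as 16-bit PCM."""
    peak = float(np.max(np.abs(samples))) or 1.0
    scaled = np.clip(samples / peak * 0.9, -1.0, 1.0)
    wavfile.write(path, fs, (scaled * 32767).astype(np.int16))


def load_segment(record: SegmentRecord, config: Optional[PipelineConfig] = None) -> AudioSegment:
    """Load the annotated slice ``[t_start_s, t_end_s)`` of a mono WAV.

    The file must be mono and match the configured sampling rate; the
    slice covers sample indices ``round(t*fs)`` half-open.
    """
    cfg = config or PipelineConfig()
    if not record.wav_path.exists():
        raise FileNotFoundError(f"missing WAV file: {record.wav_path}")
    fs, data = wavfile.read(record.wav_path)
    if data.ndim != 1:
        raise ValueError(f"{record.wav_path}: expected mono audio, got shape {data.shape}")
    if fs != cfg.fs:
        raise ValueError(
            f"{record.wav_path}: sampling rate {fs} Hz does not match configured {cfg.fs} Hz"
        )
    i0 = int(round(record.t_start_s * fs))
    i1 = int(round(record.t_end_s * fs))
    if i1 > len(data):
        raise ValueError(
            f"{record.wav_path}: segment end {record.t_end_s}s beyond file length"
        )
    samples = data[i0:i1]
    if np.issubdtype(samples.dtype, np.integer):
        samples = samples.astype(float) / 32768.0
    return AudioSegment(
        samples=samples,
        fs=fs,
        speaker_id=record.speaker_id,
        word=record.word,
        sibilant=record.sibilant,
        articulation_class=record.articulation_class,
    )


# ---------------------------------------------------------------------------
# masks

def _frame_dir(record: SegmentRecord) -> Path:
    return record.wav_path.with_suffix("")


def load_mask_frames(
    record: SegmentRecord, config: Optional[PipelineConfig] = None
) -> List[Tuple[MaskFrame, MaskFrame]]:
    """Load the dual-camera mask frames synchronized with a segment.

    The number of stored video frames must equal the segment's audio frame
    count on the 33-ms grid (``floor(n_samples / frame_len)``).
    """
    cfg = config or PipelineConfig()
    fdir = _frame_dir(record)
    if not fdir.is_dir():
        raise FileNotFoundError(f"missing frame directory: {fdir}")
    n_samples = int(round(record.t_end_s * cfg.fs)) - int(round(record.t_start_s * cfg.fs))
    n_expected = max(n_samples // cfg.frame_len, 1)
    frames: List[Tuple[MaskFrame, MaskFrame]] = []
    for idx in range(n_expected):
        pair = []
        for cam in ("left", "right"):
            suf = _CAM_SUFFIX[cam]
            img_path = fdir / f"{idx:03d}_{suf}_img.png"
            mask_path = fdir / f"{idx:03d}_{suf}_mask.png"
            for p in (img_path, mask_path):
                if not p.exists():
                    raise FileNotFoundError(f"missing frame file: {p}")
            gray = iio.imread(img_path)
            mask = iio.imread(mask_path)
            labels = set(np.unique(mask).tolist())
            if labels - VALID_MASK_LABELS:
                raise ValueError(
                    f"{mask_path}: invalid label values {sorted(labels - VALID_MASK_LABELS)}"
                )
            pair.append(
                MaskFrame(gray_image=gray, label_mask=mask, camera=cam, frame_index=idx)
            )
        frames.append((pair[0], pair[1]))
    return frames


# ---------------------------------------------------------------------------
# manifest

def write_cohort(cohort: Cohort, out_dir: Path, pad_s: float = 0.05) -> Path:
    """Write a cohort to disk and return the manifest path.

    Audio is embedded in a WAV with ``pad_s`` of silence on both sides,
    with the manifest carrying the segment annotation times.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spk in cohort.speakers:
        spk_dir = out_dir / spk.speaker_id
        spk_dir.mkdir(exist_ok=True)
        word_count: dict = {}
        for seg in spk.segments:
            k = word_count.get(seg.audio.word, 0)
            word_count[seg.audio.word] = k + 1
            stem = f"{seg.audio.word}__{k}"
            wav_path = spk_dir / f"{stem}.wav"
            fs = seg.audio.fs
            pad = np.zeros(int(round(pad_s * fs)))
            write_wav(wav_path, np.concatenate([pad, seg.audio.samples, pad]), fs)
            fdir = spk_dir / stem
            fdir.mkdir(exist_ok=True)
            for idx, (left, right) in enumerate(seg.frames):
                for fr in (left, right):
                    suf = _CAM_SUFFIX[fr.camera]
                    iio.imwrite(fdir / f"{idx:03d}_{suf}_img.png", fr.gray_image.astype(np.uint8))
                    iio.imwrite(fdir / f"{idx:03d}_{suf}_mask.png", fr.label_mask.astype(np.uint8))
            rows.append(
                dict(
                    speaker_id=spk.speaker_id,
                    word=seg.audio.word,
                    sibilant=spk.sibilant.value,
                    **{"class": spk.articulation_class.value},
                    wav_path=str(wav_path.relative_to(out_dir)),
                    t_start_s=round(pad_s, 6),
                    t_end_s=round(pad_s + len(seg.audio.samples) / fs, 6),
                )
            )
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    log.info("wrote corpus with %d segments to %s", len(rows), out_dir)
    return manifest_path


def read_manifest(corpus_dir: Path) -> List[SegmentRecord]:
    corpus_dir = Path(corpus_dir)
    manifest_path = corpus_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    df = pd.read_csv(manifest_path)
    records = []
    for _, row in df.iterrows():
        records.append(
            SegmentRecord(
                speaker_id=str(row["speaker_id"]),
                word=str(row["word"]),
                sibilant=coerce_sibilant(row["sibilant"]),
                articulation_class=coerce_class(row["class"]),
                wav_path=corpus_dir / row["wav_path"],
                t_start_s=float(row["t_start_s"]),
                t_end_s=float(row["t_end_s"]),
            )
        )
    return records


def load_cohort(corpus_dir: Path, config: Optional[PipelineConfig] = None) -> Cohort:
    """Reload a written corpus into memory, grouped by speaker."""
    records = read_manifest(corpus_dir)
    cfg = config or PipelineConfig()
    speakers: dict = {}
    sibilant = None
    for rec in records:
        sibilant = rec.sibilant
        spk = speakers.get(rec.speaker_id)
        if spk is None:
            spk = SpeakerData(
                speaker_id=rec.speaker_id,
                sibilant=rec.sibilant,
                articulation_class=rec.articulation_class,
            )
            speakers[rec.speaker_id] = spk
        audio = load_segment(rec, cfg)
        frames = load_mask_frames(rec, cfg)
        spk.segments.append(SegmentData(audio=audio, frames=frames))
    return Cohort(sibilant=sibilant, speakers=list(speakers.values()), root=Path(corpus_dir))


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(df: pd.DataFrame, path: Path) -> None:
    """Write a feature table as CSV with stable column order.

    Floats are written with 12 significant digits so a read/write round
    trip is lossless to that precision.
    """
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def rows_to_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Stack per-speaker feature dicts, enforcing a common feature set."""
    if not rows:
        return pd.DataFrame()
    ref_cols = list(rows[0].keys())
    for i, row in enumerate(rows[1:], start=1):
        if list(row.keys()) != ref_cols:
            raise ValueError(f"row {i} has an inconsistent feature set")
    return pd.DataFrame(list(rows), columns=ref_cols)
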
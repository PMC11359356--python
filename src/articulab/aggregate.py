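"""Per-speaker aggregation of frame-level feature matrices.

Each segment's frame sequence is cropped by 25% at both ends (to remove
neighbouring sounds, silence or background noise at the annotation
boundaries) and the retained frames of all of a speaker's segments are
averaged column-wise into a single hybrid feature vector per speaker and
sibilant, which keeps the downstream statistics on independent
observations.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd


def crop_frames(n_frames: int, fraction: float = 0.25) -> range:
    """Retained frame index range after dropping ``floor(fraction*n)``
    frames at each end; at least one frame is always retained."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    k = int(np.floor(fraction * n_frames))
    if n_frames - 2 * k < 1:  # unreachable for fraction < 0.5; kept as a guard
        mid = n_frames // 2
        return range(mid, mid + 1)
    return range(k, n_frames - k)


def aggregate_speaker(
    matrices: Sequence[pd.DataFrame], crop_fraction: float = 0.25
) -> pd.Series:
    """Average the cropped frames of all segments of one speaker.

    All retained frames are pooled with equal weight per frame (not per
    segment); the result is one feature vector.
    """
    if len(matrices) == 0:
        raise ValueError("aggregate_speaker needs at least one segment matrix")
    columns = list(matrices[0].columns)
    blocks: List[np.ndarray] = []
    for m in matrices:
        if list(m.columns) != columns:
            raise ValueError("segment matrices have inconsistent columns")
        keep = crop_frames(len(m), crop_fraction)
        blocks.append(m.to_numpy()[keep.start : keep.stop])
    pooled = np.vstack(blocks)
    return pd.Series(pooled.mean(axis=0), index=columns)
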
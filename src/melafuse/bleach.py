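"""Photobleaching feature extraction from autofluorescence frame sequences.

Given the time-ordered fluorescence frames of a lesion and its
segmentation masks, this module produces the tabular photobleaching
feature vector: the mean lesion-region pixel intensity of each frame
(nominally 10 frames at 1-s intervals). Skin-background means can be
computed on request but are never part of the feature vector — only
lesion intensities carry diagnostically useful bleaching dynamics.

Sequences shorter than the nominal length are padded by repeating the
last observed value, with per-frame validity flags exposing which
entries are real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class PhotobleachCurve:
    """Mean lesion intensity per frame with per-frame validity flags."""

    values: np.ndarray
    valid: np.ndarray
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid flags must have equal length")
        if not self.valid.any():
            raise ValueError("a curve needs at least one valid frame")
        if not np.isfinite(self.values[self.valid]).all():
            raise ValueError("valid curve entries must be finite")

    def __len__(self) -> int:
        return len(self.values)


def derive_background_mask(lesion_mask: np.ndarray, marker_mask: np.ndarray) -> np.ndarray:
    """Skin-background mask: complement of the lesion/marker union."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    marker_mask = np.asarray(marker_mask, dtype=bool)
    if lesion_mask.shape != marker_mask.shape:
        raise ValueError(
            f"mask shapes differ: {lesion_mask.shape} vs {marker_mask.shape}"
        )
    return ~(lesion_mask | marker_mask)


def mean_intensity(frame: np.ndarray, mask: np.ndarray, frame_index: int | None = None) -> float:
    """Arithmetic mean of the frame's pixels under the mask."""
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError(f"frame/mask shapes differ: {frame.shape} vs {mask.shape}")
    if not mask.any():
        where = "" if frame_index is None else f" at frame {frame_index}"
        raise ValueError(f"empty mask{where}: mean intensity undefined")
    return float(frame[mask].mean())


def extract_curve(
    frames: Sequence[np.ndarray] | np.ndarray,
    lesion_mask: np.ndarray | Sequence[np.ndarray],
    expected_len: int = 10,
    lesion_id: str = "",
    normalize_i0: bool = False,
) -> PhotobleachCurve:
    """Build the photobleaching feature vector from a frame sequence.

    ``lesion_mask`` is either a single mask applied to every frame (the
    default contract: the first frame's segmentation) or one mask per
    frame. If fewer than ``expected_len`` frames are available the curve
    is padded with the last observed mean, flagged invalid.

    With ``normalize_i0`` the curve is divided by its first valid value,
    turning it into a relative-decay profile.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("cannot extract a curve from zero frames")

    masks: list[np.ndarray]
    first = np.asarray(lesion_mask)
    if first.ndim == 2 and first.dtype != object:
        masks = [first] * len(frames)
    else:
        masks = [np.asarray(m) for m in lesion_mask]  # type: ignore[union-attr]
        if len(masks) != len(frames):
            raise ValueError("per-frame masks must match the number of frames")

    n = min(len(frames), expected_len)
    values = np.empty(expected_len)
    valid = np.zeros(expected_len, dtype=bool)
    for t in range(n):
        values[t] = mean_intensity(frames[t], masks[t], frame_index=t)
        valid[t] = True
    values[n:] = values[n - 1]  # pad by repeating the last measurement

    if normalize_i0:
        values = values / values[0]
    return PhotobleachCurve(values=values, valid=valid, lesion_id=lesion_id)


def curves_to_matrix(curves: Sequence[PhotobleachCurve]) -> np.ndarray:
    """Stack curves into an (n_lesions, n_frames) feature matrix."""
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise ValueError(f"curves have mixed lengths: {sorted(lengths)}")
    return np.stack([c.values for c in curves])
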
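"""Synthetic multispectral lesions with autofluorescence photobleaching.

Emulates the acquisition geometry of a multispectral skin-lesion study:
each record carries a C-channel reflectance/fluorescence image stack of a
compact lesion blob, a lesion segmentation mask, a reference-marker mask,
and a time-ordered sequence of single-channel autofluorescence frames in
which the lesion signal decays exponentially under sustained excitation
(``I(t) = I0 * exp(-lambda_c * t)`` plus i.i.d. Gaussian noise, with a
class-specific decay constant ``lambda_c``).

Class identity is injected in two places so every downstream stage sees a
learnable signal: per-class, per-channel additive offsets in the image
stack, and per-class decay rates in the fluorescence sequence. A
``signal_frames`` mode restricts the class-dependent decay to the first k
frames — frames at t >= k carry a shared constant plus noise — which is
the regime used to exercise purity-guided frame selection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from melafuse.losses import CLASS_NAMES, ClassLabel


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Parameters
    ----------
    n_per_class:
        Records generated per class.
    image_size:
        Side length of the square image stack, in pixels.
    n_channels:
        Channels in the multispectral stack (12 mimics 4 spectral
        modalities x 3 camera channels; 3 mimics plain RGB).
    n_frames:
        Frames per photobleaching sequence, acquired at unit intervals.
    decay_rates:
        Per-class decay constant lambda_c in 1/frame, ordered as
        ``CLASS_NAMES``.
    spectral_offsets:
        Per-class additive channel offset; scalar per class (applied with
        alternating channel signs) or a full (n_classes, n_channels) array.
    i0:
        Initial lesion fluorescence intensity, common to all classes.
    noise_sd:
        Standard deviation of additive i.i.d. Gaussian noise on image and
        frame pixels; the lesion-mean noise scales as noise_sd/sqrt(area).
    decay_jitter:
        Per-record standard deviation of the decay constant around its
        class value (inter-patient photobleaching variability); 0 gives
        every record its class's exact lambda_c.
    signal_frames:
        If set, class-specific decay acts only on frames t < signal_frames;
        later frames share a class-independent level (pure noise regime).
    seed:
        RNG seed; identical config + seed => bit-identical dataset.
    """

    n_per_class: int = 50
    image_size: int = 32
    n_channels: int = 12
    n_frames: int = 10
    decay_rates: tuple[float, ...] = (0.5, 0.25, 0.05)
    spectral_offsets: tuple[float, ...] = (0.30, 0.0, -0.30)
    i0: float = 1.0
    noise_sd: float = 0.05
    decay_jitter: float = 0.0
    signal_frames: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(r < 0 for r in self.decay_rates):
            raise ValueError("decay_rates must be >= 0")
        if self.decay_jitter < 0:
            raise ValueError("decay_jitter must be >= 0")
        if len(self.decay_rates) != len(CLASS_NAMES):
            raise ValueError(f"need one decay rate per class ({len(CLASS_NAMES)})")


@dataclass
class SyntheticRecord:
    """One simulated lesion: image stack, masks, frame sequence, label."""

    record_id: str
    image: np.ndarray  # (C, H, W) in [0, 1]
    lesion_mask: np.ndarray  # (H, W) bool
    marker_mask: np.ndarray  # (H, W) bool
    frames: np.ndarray  # (T, H, W)
    label: ClassLabel

    def __post_init__(self) -> None:
        if self.lesion_mask.shape != self.marker_mask.shape:
            raise ValueError("lesion and marker masks must share spatial dims")
        if self.image.shape[1:] != self.lesion_mask.shape:
            raise ValueError("masks must share the image spatial dims")
        if np.any(self.lesion_mask & self.marker_mask):
            raise ValueError("lesion and marker masks must be disjoint")
        if not self.lesion_mask.any():
            raise ValueError("lesion mask must be nonempty")


def _lesion_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """A random filled ellipse, kept away from the marker corner."""
    cy = rng.uniform(0.35, 0.65) * size
    cx = rng.uniform(0.35, 0.65) * size
    ry = rng.uniform(0.12, 0.22) * size
    rx = rng.uniform(0.12, 0.22) * size
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _marker_mask(size: int) -> np.ndarray:
    """Small reference-marker square in the top-left corner."""
    mask = np.zeros((size, size), dtype=bool)
    m = max(2, size // 10)
    mask[1 : 1 + m, 1 : 1 + m] = True
    return mask


def _channel_offsets(config: SynthConfig, class_idx: int) -> np.ndarray:
    offsets = np.asarray(config.spectral_offsets, dtype=float)
    if offsets.ndim == 1:
        # scalar per class, alternated in sign across channels so no two
        # classes differ by a single global brightness shift only
        signs = np.where(np.arange(config.n_channels) % 2 == 0, 1.0, -1.0)
        return offsets[class_idx] * signs
    return offsets[class_idx]


def _decay_curve(config: SynthConfig, lam: float) -> np.ndarray:
    """Noise-free lesion mean per frame for a record's decay constant."""
    t = np.arange(config.n_frames, dtype=float)
    curve = config.i0 * np.exp(-lam * t)
    if config.signal_frames is not None:
        k = config.signal_frames
        # beyond frame k the bleaching has saturated identically for all
        # classes: a shared plateau carrying no class information
        plateau = config.i0 * np.exp(-float(np.mean(config.decay_rates)) * k)
        curve[t >= k] = plateau
    return curve


def generate_dataset(config: SynthConfig) -> list[SyntheticRecord]:
    """Generate ``n_per_class`` records for each of the three classes.

    The lesion-region mean of frame t equals the record's decay curve at
    t plus zero-mean sampling noise (exact when noise_sd=0).
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    marker = _marker_mask(size)
    records: list[SyntheticRecord] = []
    for class_idx, class_name in enumerate(CLASS_NAMES):
        offsets = _channel_offsets(config, class_idx)
        for i in range(config.n_per_class):
            lam = config.decay_rates[class_idx]
            if config.decay_jitter > 0:
                lam = max(0.0, lam + rng.normal(0.0, config.decay_jitter))
            curve = _decay_curve(config, lam)
            lesion = _lesion_mask(size, rng)
            lesion &= ~marker
            base = rng.uniform(0.35, 0.45)
            image = np.full((config.n_channels, size, size), base)
            image += offsets[:, None, None] * lesion[None, :, :] * 0.5
            image += offsets[:, None, None] * 0.5
            if config.noise_sd > 0:
                image += rng.normal(0.0, config.noise_sd, image.shape)
            image = np.clip(image, 0.0, 1.0)

            frames = np.empty((config.n_frames, size, size))
            for t in range(config.n_frames):
                frame = np.full((size, size), 0.05)
                frame[lesion] = curve[t]
                if config.noise_sd > 0:
                    frame += rng.normal(0.0, config.noise_sd, (size, size))
                frames[t] = frame

            records.append(
                SyntheticRecord(
                    record_id=f"{class_name.lower()}-{i:04d}",
                    image=image,
                    lesion_mask=lesion,
                    marker_mask=marker.copy(),
                    frames=frames,
                    label=ClassLabel(class_name),
                )
            )
    return records


def threshold_segment(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask true exactly where ``frame > threshold``.

    A stand-in for a learned lesion segmenter, adequate for synthetic
    blobs on a dark background. An all-false result is legal; callers
    decide whether an empty mask is an error.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("threshold_segment expects a single-channel 2-D frame")
    return frame > threshold


def dataset_digest(records: Sequence[SyntheticRecord]) -> str:
    """SHA-256 digest over all arrays and labels; for determinism checks."""
    h = hashlib.sha256()
    for rec in records:
        h.update(rec.record_id.encode())
        h.update(rec.label.name.encode())
        for arr in (rec.image, rec.lesion_mask, rec.marker_mask, rec.frames):
            h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()
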
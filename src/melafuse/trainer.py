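"""Experimental protocol: splits, preprocessing, augmentation, training.

The protocol mirrors a small-data medical-imaging study: several fixed
random cross-validation splits into 80/10/10% train/validation/test
folds (stratified by class to protect the smallest category), per-image
min-max normalization to [0, 1] and bilinear resizing, light training
augmentation (gamma, contrast and Gaussian noise on images; Gaussian
noise only on the tabular photobleaching vector), Nadam optimization
with reduce-on-plateau learning-rate scheduling, and selection of the
checkpoint with the lowest validation loss for test evaluation.
Training is repeated several times per split; the resulting per-run
metric table feeds the significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from melafuse.bleach import PhotobleachCurve
from melafuse.losses import LossWeights, hard_target, soft_target
from melafuse.metrics import RunMetrics, accuracy, weighted_auc_pr_from_scores
from melafuse.net import ModelConfig, MultiHeadModel
from melafuse.nn import Nadam
from melafuse.simgen import SyntheticRecord


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation/test index sets for one split."""

    split_id: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split folds must be disjoint")


@dataclass(frozen=True)
class AugmentParams:
    """Augmentation strengths; degenerate ranges give the identity."""

    gamma_range: tuple[float, float] = (0.8, 1.25)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    image_noise_sd: float = 0.01
    tabular_noise_sd: float = 0.01
    p_apply: float = 0.5  # per-sample, per-transform enable probability


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the full-scale protocol."""

    max_epochs: int = 50
    batch_size: int = 4
    optimizer: str = "nadam"
    lr: float = 2e-4
    weight_decay: float = 1e-4
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    image_size: int = 448
    n_splits: int = 5
    repeats: int = 3
    seed: int = 0
    augment: AugmentParams = AugmentParams()

    def __post_init__(self) -> None:
        if self.max_epochs < 0 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("max_epochs >= 0, batch_size >= 1, lr > 0 required")
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ValueError("scheduler factor must lie in (0, 1)")


# --------------------------------------------------------------------- splits


def make_splits(
    n: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_splits: int = 5,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> list[SplitPlan]:
    """Seeded random splits into train/val/test by the given ratios.

    Validation and test sizes are floored; the remainder goes to train
    (so n=100 gives exactly 80/10/10 and n=103 gives 83/10/10). When
    ``labels`` are supplied the folds are stratified: per-class fold
    quotas are assigned by largest remainder so the global fold sizes
    are exact.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    if n < 10:
        raise ValueError("need at least 10 samples to split 80/10/10")
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))

    plans = []
    for split_id in range(n_splits):
        rng = np.random.default_rng([seed, split_id])
        if labels is None:
            perm = rng.permutation(n)
            test, val, train = perm[:n_test], perm[n_test : n_test + n_val], perm[n_test + n_val :]
        else:
            label_arr = np.asarray(labels)
            classes = np.unique(label_arr)
            per_class = {c: rng.permutation(np.flatnonzero(label_arr == c)) for c in classes}
            counts = np.array([len(per_class[c]) for c in classes], dtype=float)
            test_q = _largest_remainder(counts * ratios[2] / 1.0, n_test)
            val_q = _largest_remainder(counts * ratios[1] / 1.0, n_val)
            test_parts, val_parts, train_parts = [], [], []
            for ci, c in enumerate(classes):
                idx = per_class[c]
                t, v = test_q[ci], val_q[ci]
                test_parts.append(idx[:t])
                val_parts.append(idx[t : t + v])
                train_parts.append(idx[t + v :])
            test = np.concatenate(test_parts)
            val = np.concatenate(val_parts)
            train = np.concatenate(train_parts)
        plans.append(
            SplitPlan(split_id=split_id, train=np.sort(train), val=np.sort(val),
                      test=np.sort(test))
        )
    return plans


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    if remainder > 0:
        frac = quotas - base
        # ties broken by ascending class index via stable sort
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
    return base


# -------------------------------------------------------------- preprocessing


def normalize_and_resize(
    image: np.ndarray, size: int, per_channel: bool = False
) -> np.ndarray:
    """Min-max normalize a (C, H, W) stack to [0, 1], then bilinearly
    resize each channel to size x size. Constant images map to zeros."""
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if image.ndim == 2:
        image = image[None]
    if per_channel:
        lo = image.min(axis=(1, 2), keepdims=True)
        hi = image.max(axis=(1, 2), keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        image = np.where(hi > lo, (image - lo) / span, 0.0)
    else:
        lo, hi = image.min(), image.max()
        image = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    if image.shape[1:] == (size, size):
        return image
    return np.stack(
        [
            _sk_resize(ch, (size, size), order=1, preserve_range=True,
                       anti_aliasing=False)
            for ch in image
        ]
    )


def apply_gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    """Pixelwise power transform x**gamma on a [0, 1] image."""
    return np.clip(np.asarray(image, dtype=float), 0.0, 1.0) ** gamma


def apply_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """Mean-anchored contrast scaling: m + factor * (x - m)."""
    image = np.asarray(image, dtype=float)
    mean = image.mean()
    return mean + factor * (image - mean)


def augment_image(
    image: np.ndarray, rng: np.random.Generator, params: AugmentParams = AugmentParams()
) -> np.ndarray:
    """Gamma, mean-anchored contrast, and additive Gaussian noise, each
    independently enabled per sample; output clamped to [0, 1]."""
    out = np.asarray(image, dtype=float)
    if rng.random() < params.p_apply:
        out = apply_gamma(out, rng.uniform(*params.gamma_range))
    if rng.random() < params.p_apply:
        out = apply_contrast(out, rng.uniform(*params.contrast_range))
    if params.image_noise_sd > 0 and rng.random() < params.p_apply:
        out = out + rng.normal(0.0, params.image_noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0)


def augment_tabular(
    vector: np.ndarray,
    rng: np.random.Generator,
    sigma: float,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Additive Gaussian noise on the photobleaching vector; entries
    flagged invalid (padding) are left untouched."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    vector = np.asarray(vector, dtype=float)
    noise = rng.normal(0.0, sigma, vector.shape) if sigma > 0 else np.zeros_like(vector)
    if valid is not None:
        noise = np.where(np.asarray(valid, dtype=bool), noise, 0.0)
    return vector + noise


# ------------------------------------------------------------------ scheduler


class PlateauScheduler:
    """Reduce-on-plateau: after ``patience`` consecutive epochs without a
    strict improvement of the monitored loss, multiply the learning rate
    by ``factor``. The rate never increases."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 5) -> None:
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        if not np.isfinite(val_loss):
            raise ValueError("validation loss must be finite")
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
        return self.lr


# ------------------------------------------------------------------- training


@dataclass
class TrainingData:
    """Arrays consumed by the training loop."""

    images: np.ndarray  # (N, C, H, W), already normalized to [0, 1]
    tabular: np.ndarray | None  # (N, T) or None in image-only mode
    tabular_valid: np.ndarray | None  # (N, T) bool, padding flags
    labels: np.ndarray  # (N,) int class indices
    hard: np.ndarray  # (N, C) one-hot
    soft: np.ndarray  # (N, C) soft labels

    def __len__(self) -> int:
        return len(self.labels)


def build_training_data(
    records: Sequence[SyntheticRecord],
    curves: Sequence[PhotobleachCurve] | None = None,
    frame_subset: Sequence[int] | None = None,
    image_size: int | None = None,
) -> TrainingData:
    """Assemble normalized arrays from simulated records and their curves.

    ``frame_subset`` restricts the tabular vector to the selected frame
    indices (the purity-guided choice); ``curves=None`` yields the
    image-only mode.
    """
    size = image_size or records[0].image.shape[-1]
    images = np.stack([normalize_and_resize(r.image, size) for r in records])
    labels = np.array([r.label.index for r in records])
    hard = np.stack([hard_target(r.label) for r in records])
    soft = np.stack([soft_target(r.label) for r in records])
    tabular = valid = None
    if curves is not None:
        if len(curves) != len(records):
            raise ValueError("one curve per record required")
        tabular = np.stack([c.values for c in curves])
        valid = np.stack([c.valid for c in curves])
        if frame_subset is not None:
            subset = list(frame_subset)
            tabular = tabular[:, subset]
            valid = valid[:, subset]
    return TrainingData(images=images, tabular=tabular, tabular_valid=valid,
                        labels=labels, hard=hard, soft=soft)


@dataclass
class TrainResult:
    model: MultiHeadModel
    metrics: RunMetrics
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _batched_eval_loss(model, data: TrainingData, idx: np.ndarray,
                       weights: LossWeights, batch_size: int = 64) -> float:
    total, count = 0.0, 0
    for start in range(0, len(idx), batch_size):
        b = idx[start : start + batch_size]
        tab = None if data.tabular is None else data.tabular[b]
        total += model.eval_loss(data.images[b], tab, data.hard[b], data.soft[b],
                                 weights) * len(b)
        count += len(b)
    return total / count


def evaluate_model(model: MultiHeadModel, data: TrainingData, idx: np.ndarray
                   ) -> tuple[float, float, np.ndarray]:
    """Accuracy, weighted AUC-PR and the averaged probabilities on a fold."""
    probs = []
    for start in range(0, len(idx), 64):
        b = idx[start : start + 64]
        tab = None if data.tabular is None else data.tabular[b]
        probs.append(model.predict_proba(data.images[b], tab))
    probs = np.concatenate(probs)
    truth = data.labels[idx]
    predicted = probs.argmax(axis=1)
    return (
        accuracy(predicted, truth),
        weighted_auc_pr_from_scores(probs, truth),
        probs,
    )


def train_model(
    model: MultiHeadModel,
    data: TrainingData,
    split: SplitPlan,
    config: TrainConfig,
    weights: LossWeights = LossWeights(),
    repeat_id: int = 0,
) -> TrainResult:
    """Optimize the total loss on the train fold, track validation loss,
    restore the minimum-validation-loss checkpoint, and score the test
    fold. Fully deterministic given ``config.seed``.

    With ``max_epochs=0`` the initialized model is evaluated as-is.
    """
    rng = np.random.default_rng([config.seed, split.split_id, repeat_id])
    opt = Nadam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    sched = PlateauScheduler(config.lr, config.scheduler_factor, config.scheduler_patience)

    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = 0
    rows = []
    use_tab = data.tabular is not None and model.config.use_tabular
    aug = config.augment

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(split.train)
        epoch_losses = []
        for start in range(0, len(perm), config.batch_size):
            b = perm[start : start + config.batch_size]
            images = np.stack([augment_image(data.images[i], rng, aug) for i in b])
            tab = None
            if use_tab:
                tab = np.stack(
                    [
                        augment_tabular(
                            data.tabular[i], rng, aug.tabular_noise_sd,
                            None if data.tabular_valid is None else data.tabular_valid[i],
                        )
                        for i in b
                    ]
                )
            losses = model.loss_and_grad_step(images, tab, data.hard[b], data.soft[b], weights)
            if np.isnan(losses["total"]):
                raise FloatingPointError(
                    f"training diverged (NaN loss) at epoch {epoch}"
                )
            opt.step()
            epoch_losses.append(losses["total"])

        val_loss = _batched_eval_loss(model, data, split.val, weights)
        lr = sched.step(val_loss)
        opt.lr = lr
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state_dict()
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss, "lr": lr}
        )

    if config.max_epochs == 0:
        best_val = _batched_eval_loss(model, data, split.val, weights)
    model.load_state_dict(best_state)
    acc, wauc, _ = evaluate_model(model, data, split.test)
    metrics = RunMetrics(split_id=split.split_id, repeat_id=repeat_id,
                         accuracy=acc, weighted_auc_pr=wauc)
    history = pd.DataFrame(rows)
    return TrainResult(model=model, metrics=metrics, history=history,
                       best_epoch=best_epoch, best_val_loss=float(best_val))


def run_repeated(
    data: TrainingData,
    splits: Sequence[SplitPlan],
    config: TrainConfig,
    model_config: ModelConfig,
    mode: str = "multi",
    weights: LossWeights = LossWeights(),
) -> list[RunMetrics]:
    """Train ``repeats`` seeded runs on every split (the 5x3 protocol at
    full scale) and collect the per-run metric table.

    The single-head ablation (``mode="single"``) reuses the exact same
    splits and per-run seeds, so comparisons are paired by design.
    """
    results = []
    for split in splits:
        for repeat in range(config.repeats):
            model_seed = (config.seed * 1000003 + split.split_id * 101 + repeat) % (2**31)
            input_channels = data.images.shape[1]
            model = MultiHeadModel(model_config, input_channels=input_channels,
                                   mode=mode, seed=model_seed)
            result = train_model(model, data, split, config, weights, repeat_id=repeat)
            results.append(result.metrics)
    return results
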
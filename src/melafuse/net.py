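"""The two-head classifier: shared encoder, fusion head, hard-target head.

A shared convolutional backbone maps the multispectral stack to a feature
vector. Two MLP heads consume it:

* **Head 1** (soft targets) sees the visual features concatenated with the
  tabular photobleaching vector (when enabled) and is trained with binary
  cross-entropy per output plus KL divergence toward the soft label.
* **Head 2** (hard targets) sees the visual features alone and is trained
  with categorical cross-entropy against the one-hot label.

At inference the per-head probability vectors are combined by simple
elementwise averaging, which keeps the final prediction on the simplex.

Backbones are pluggable: any object exposing ``feature_dim``,
``forward(images) -> features`` and ``backward(grad)`` satisfies the
contract. The bundled :class:`TinyConvBackbone` (strided conv blocks +
global average pooling) is adequate for the synthetic-scale experiments;
large pretrained encoders can be plugged in behind the same contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from melafuse.losses import EPS, ClassLabel, LossWeights
from melafuse.nn import Conv2d, GlobalAvgPool, Linear, ReLU, Sequential


@dataclass(frozen=True)
class ModelConfig:
    """Architecture settings for the two-head model.

    ``use_tabular`` toggles concatenation of the photobleaching vector
    into Head 1 (off reproduces the image-only RGB mode). ``head1_sigmoid``
    switches Head 1 from a single softmax to per-logit sigmoids; the
    softmax default keeps every head output on the simplex so the
    averaged prediction is itself a distribution.
    """

    n_classes: int = 3
    use_tabular: bool = True
    tabular_dim: int = 10
    mlp_hidden: tuple[int, ...] = (256,)
    backbone_channels: tuple[int, ...] = (16, 32, 32, 32)
    head1_sigmoid: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.use_tabular and self.tabular_dim < 1:
            raise ValueError("tabular_dim must be >= 1 when use_tabular")


@dataclass(frozen=True)
class HeadOutput:
    """One head's class-probability vector."""

    head_id: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.head_id not in (1, 2):
            raise ValueError("head_id must be 1 or 2")
        probs = np.asarray(self.probs, dtype=float)
        if np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("head output must lie on the probability simplex")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TinyConvBackbone:
    """Small strided conv encoder: conv(3x3, stride 2)+ReLU blocks, then
    global average pooling. ``feature_dim`` equals the last block width."""

    def __init__(
        self,
        input_channels: int,
        channels: Sequence[int] = (16, 32, 32, 32),
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        layers: list = []
        prev = input_channels
        for width in channels:
            layers.append(Conv2d(prev, width, kernel_size=3, stride=2, padding=1, rng=rng))
            layers.append(ReLU())
            prev = width
        layers.append(GlobalAvgPool())
        self.net = Sequential(*layers)
        self.input_channels = input_channels
        self.feature_dim = prev

    def forward(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 4 or images.shape[1] != self.input_channels:
            raise ValueError(
                f"expected (N, {self.input_channels}, H, W) images, got {images.shape}"
            )
        return self.net.forward(images)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def parameters(self) -> list[tuple[object, str]]:
        return self.net.parameters()


class _MLPHead:
    """MLP -> logits; the final layer is zero-initialized so an untrained
    head emits the uniform distribution."""

    def __init__(self, in_dim: int, hidden: Sequence[int], n_classes: int,
                 rng: np.random.Generator) -> None:
        layers: list = []
        prev = in_dim
        for width in hidden:
            layers.append(Linear(prev, width, rng=rng))
            layers.append(ReLU())
            prev = width
        layers.append(Linear(prev, n_classes, rng=rng, zero_init=True))
        self.net = Sequential(*layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def parameters(self) -> list[tuple[object, str]]:
        return self.net.parameters()


class MultiHeadModel:
    """Shared backbone + the two classification heads.

    ``mode`` selects the trained configuration: ``"multi"`` runs both
    heads (predictions averaged); ``"single"`` runs Head 2 only — the
    single-head ablation — with every enabled loss applied to its output.
    """

    def __init__(
        self,
        config: ModelConfig = ModelConfig(),
        backbone: TinyConvBackbone | None = None,
        input_channels: int = 12,
        mode: str = "multi",
        seed: int = 0,
    ) -> None:
        if mode not in ("multi", "single"):
            raise ValueError("mode must be 'multi' or 'single'")
        rng = np.random.default_rng(seed)
        self.config = config
        self.mode = mode
        self.backbone = backbone or TinyConvBackbone(
            input_channels, config.backbone_channels, rng=rng
        )
        head1_in = self.backbone.feature_dim + (
            config.tabular_dim if config.use_tabular else 0
        )
        self.head1 = _MLPHead(head1_in, config.mlp_hidden, config.n_classes, rng)
        self.head2 = _MLPHead(
            self.backbone.feature_dim, config.mlp_hidden, config.n_classes, rng
        )
        self._cache: dict | None = None

    # ---------------------------------------------------------------- forward

    def head1_forward(self, features: np.ndarray, tabular: np.ndarray | None) -> np.ndarray:
        if self.config.use_tabular:
            if tabular is None:
                raise ValueError("tabular input required when use_tabular=True")
            if tabular.shape[1] != self.config.tabular_dim:
                raise ValueError(
                    f"tabular dim {tabular.shape[1]} != configured {self.config.tabular_dim}"
                )
            x = np.concatenate([features, tabular], axis=1)
        else:
            x = features
        logits = self.head1.forward(x)
        if self.config.head1_sigmoid:
            probs = 1.0 / (1.0 + np.exp(-logits))
            return probs / np.maximum(probs.sum(axis=1, keepdims=True), EPS)
        return softmax(logits)

    def head2_forward(self, features: np.ndarray) -> np.ndarray:
        return softmax(self.head2.forward(features))

    def forward(self, images: np.ndarray, tabular: np.ndarray | None = None
                ) -> tuple[np.ndarray | None, np.ndarray]:
        """Return (head1 probs or None, head2 probs) for a batch."""
        features = self.backbone.forward(images)
        p2 = self.head2_forward(features)
        p1 = self.head1_forward(features, tabular) if self.mode == "multi" else None
        self._cache = {"p1": p1, "p2": p2, "features": features}
        return p1, p2

    def predict_proba(self, images: np.ndarray, tabular: np.ndarray | None = None
                      ) -> np.ndarray:
        """Final (averaged) class probabilities for a batch."""
        p1, p2 = self.forward(images, tabular)
        heads = [p2] if p1 is None else [p1, p2]
        return np.mean(heads, axis=0)

    # --------------------------------------------------------------- training

    def loss_and_grad_step(
        self,
        images: np.ndarray,
        tabular: np.ndarray | None,
        hard: np.ndarray,
        soft: np.ndarray,
        weights: LossWeights = LossWeights(),
    ) -> dict[str, float]:
        """Forward + backward for one batch; leaves gradients in the layers.

        In multi-head mode CE acts on Head 2 and BCE+KL on Head 1; in the
        single-head ablation all enabled terms act on Head 2's output.
        Returns the batch-mean loss terms.
        """
        p1, p2 = self.forward(images, tabular)
        n = images.shape[0]
        p2c = np.clip(p2, EPS, 1.0 - EPS)

        l_ce = float(-(hard * np.log(p2c)).sum(axis=1).mean())
        if self.mode == "multi":
            assert p1 is not None
            p1c = np.clip(p1, EPS, 1.0 - EPS)
            target_p, pc = p1, p1c
        else:
            target_p, pc = p2, p2c
        c = pc.shape[1]
        l_bce = float(
            -(soft * np.log(pc) + (1 - soft) * np.log(1 - pc)).mean(axis=1).sum() / n
        )
        mask = soft > 0
        l_kl = float(
            np.where(mask, soft * np.log(np.maximum(soft, EPS) / pc), 0.0).sum(axis=1).mean()
        )

        # gradients w.r.t. the soft-target head's probabilities
        g_bce = (weights.beta / c) * (-soft / pc + (1 - soft) / (1 - pc))
        g_kl = weights.gamma * (-soft / pc)
        g_soft_p = (g_bce + g_kl) / n

        def softmax_vjp(p: np.ndarray, g: np.ndarray) -> np.ndarray:
            return p * (g - (g * p).sum(axis=1, keepdims=True))

        grad_features = np.zeros_like(self._cache["features"])  # type: ignore[index]
        # CE through Head 2's softmax has the closed-form logit gradient
        gz2 = weights.alpha * (p2 - hard) / n
        if self.mode == "single":
            gz2 = gz2 + softmax_vjp(p2, g_soft_p)
        grad_features += self.head2.backward(gz2)

        if self.mode == "multi":
            gz1 = softmax_vjp(p1, g_soft_p)
            gx1 = self.head1.backward(gz1)
            grad_features += gx1[:, : self.backbone.feature_dim]

        self.backbone.backward(grad_features)
        total = weights.alpha * l_ce + weights.beta * l_bce + weights.gamma * l_kl
        return {"ce": l_ce, "bce": l_bce, "kl": l_kl, "total": total}

    def eval_loss(
        self,
        images: np.ndarray,
        tabular: np.ndarray | None,
        hard: np.ndarray,
        soft: np.ndarray,
        weights: LossWeights = LossWeights(),
    ) -> float:
        """Batch-mean total loss without touching gradients."""
        p1, p2 = self.forward(images, tabular)
        p2c = np.clip(p2, EPS, 1.0 - EPS)
        l_ce = float(-(hard * np.log(p2c)).sum(axis=1).mean())
        pc = p2c if p1 is None else np.clip(p1, EPS, 1.0 - EPS)
        l_bce = float(-(soft * np.log(pc) + (1 - soft) * np.log(1 - pc)).mean(axis=1).mean())
        mask = soft > 0
        l_kl = float(
            np.where(mask, soft * np.log(np.maximum(soft, EPS) / pc), 0.0).sum(axis=1).mean()
        )
        return weights.alpha * l_ce + weights.beta * l_bce + weights.gamma * l_kl

    def parameters(self) -> list[tuple[object, str]]:
        params = self.backbone.parameters() + self.head2.parameters()
        if self.mode == "multi":
            params += self.head1.parameters()
        return params

    # ------------------------------------------------------------- state dict

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for scope, obj in (("backbone", self.backbone), ("head1", self.head1),
                           ("head2", self.head2)):
            for i, (layer, name) in enumerate(obj.parameters()):
                state[f"{scope}.{i}.{name}"] = layer.params[name].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for scope, obj in (("backbone", self.backbone), ("head1", self.head1),
                           ("head2", self.head2)):
            for i, (layer, name) in enumerate(obj.parameters()):
                layer.params[name][...] = state[f"{scope}.{i}.{name}"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "mode": self.mode,
            "input_channels": self.backbone.input_channels,
            "config": {
                "n_classes": self.config.n_classes,
                "use_tabular": self.config.use_tabular,
                "tabular_dim": self.config.tabular_dim,
                "mlp_hidden": list(self.config.mlp_hidden),
                "backbone_channels": list(self.config.backbone_channels),
                "head1_sigmoid": self.config.head1_sigmoid,
            },
        }
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "MultiHeadModel":
        data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path)
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        model = cls(
            ModelConfig(
                n_classes=cfg["n_classes"],
                use_tabular=cfg["use_tabular"],
                tabular_dim=cfg["tabular_dim"],
                mlp_hidden=tuple(cfg["mlp_hidden"]),
                backbone_channels=tuple(cfg["backbone_channels"]),
                head1_sigmoid=cfg["head1_sigmoid"],
            ),
            input_channels=meta["input_channels"],
            mode=meta["mode"],
        )
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


def aggregate_predictions(outputs: Sequence[HeadOutput | np.ndarray]) -> np.ndarray:
    """Elementwise mean of the head probability vectors (Eq. of simple
    averaging); the result stays on the simplex."""
    if len(outputs) == 0:
        raise ValueError("cannot aggregate zero head outputs")
    vectors = [
        np.asarray(o.probs if isinstance(o, HeadOutput) else o, dtype=float)
        for o in outputs
    ]
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise ValueError("head outputs must have equal length")
    return np.mean(vectors, axis=0)


def predict_class(final: np.ndarray) -> ClassLabel:
    """Argmax class of the final probability vector; ties go to the lowest
    index."""
    final = np.asarray(final, dtype=float)
    if final.size == 0:
        raise ValueError("empty probability vector")
    if np.isnan(final).any():
        raise ValueError("probability vector contains NaN")
    return ClassLabel.from_index(int(np.argmax(final)))
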
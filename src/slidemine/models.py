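"""Backbone descriptors, partial fine-tuning masks, and the numpy tile CNN.

Partial fine-tuning freezes a pretrained backbone except for the affine
(scale/offset) parameters of every batch-normalisation layer and the final
classification layer. Two things are needed to reason about that scheme:

* a *structural descriptor* of a backbone (:class:`BackboneSpec`) — layer
  kinds and parameter shapes, sufficient to compute the trainable-parameter
  mask and count for any architecture, including EfficientNetB1; and
* an actually trainable tile scorer. The package ships a deliberately small
  convolutional network (:class:`TileCNN`) written directly on numpy:
  frozen random convolution filters, trainable batch-norm affine parameters
  and a single-unit sigmoid head, with manual backpropagation. Only the
  gradients the fine-tuning scheme needs are ever computed.

The classification head has one output unit trained with binary
cross-entropy: with a two-label task the categorical formulation reduces to
this, and a 1-unit head is what the published trainable-parameter count of
EfficientNetB1 (63,329 = 2 x 31,024 batch-norm channels + 1280 weights + 1
bias) implies.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParamSpec",
    "LayerSpec",
    "BackboneSpec",
    "trainable_mask",
    "count_trainable",
    "efficientnet_b1",
    "toy_backbone_spec",
    "TileCNN",
    "Adam",
]


# ---------------------------------------------------------------------------
# structural descriptors
# ---------------------------------------------------------------------------

LAYER_KINDS = {"conv", "batch_norm", "dense", "activation", "pool", "other"}


@dataclass(frozen=True)
class ParamSpec:
    """One named parameter tensor of a layer."""

    name: str
    shape: tuple[int, ...]

    @property
    def count(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a backbone: a kind plus its parameter tensors."""

    name: str
    kind: str
    params: tuple[ParamSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "batch_norm":
            affine = [p for p in self.params if p.name in ("scale", "offset")]
            if len(affine) != 2 or affine[0].shape != affine[1].shape:
                raise ValueError(
                    f"batch_norm layer {self.name!r} must expose scale/offset "
                    "vectors of equal length"
                )


@dataclass
class BackboneSpec:
    """Ordered layers plus a distinguished final classification head."""

    layers: list[LayerSpec]
    head: LayerSpec

    def __post_init__(self) -> None:
        if self.head.kind != "dense":
            raise ValueError("classification head must be a dense layer")

    def all_layers(self) -> list[LayerSpec]:
        return [*self.layers, self.head]

    def param_ids(self) -> list[str]:
        return [
            f"{layer.name}/{p.name}"
            for layer in self.all_layers()
            for p in layer.params
        ]

    def total_parameters(self) -> int:
        return sum(p.count for layer in self.all_layers() for p in layer.params)


def trainable_mask(backbone: BackboneSpec) -> set[str]:
    """Parameter ids trained under partial fine-tuning.

    The mask contains the scale/offset vectors of every batch-normalisation
    layer plus all parameters of the final classification layer; everything
    else stays frozen at its pretrained value.
    """
    if backbone.head is None:  # pragma: no cover - dataclass forbids None
        raise ValueError("backbone has no final classification layer")
    mask: set[str] = set()
    for layer in backbone.layers:
        if layer.kind == "batch_norm":
            for p in layer.params:
                if p.name in ("scale", "offset"):
                    mask.add(f"{layer.name}/{p.name}")
    for p in backbone.head.params:
        mask.add(f"{backbone.head.name}/{p.name}")
    return mask


def count_trainable(backbone: BackboneSpec, mask: set[str] | None = None) -> int:
    """Exact number of scalar parameters selected by ``mask``."""
    if mask is None:
        mask = trainable_mask(backbone)
    total = 0
    for layer in backbone.all_layers():
        for p in layer.params:
            if f"{layer.name}/{p.name}" in mask:
                total += p.count
    return total


# ---------------------------------------------------------------------------
# EfficientNetB1 structural descriptor
# ---------------------------------------------------------------------------

# (expand_ratio, kernel, stride, base output channels, base repeats)
_EFFNET_BASE_STAGES = [
    (1, 3, 1, 16, 1),
    (6, 3, 2, 24, 2),
    (6, 5, 2, 40, 2),
    (6, 3, 2, 80, 3),
    (6, 5, 1, 112, 3),
    (6, 5, 2, 192, 4),
    (6, 3, 2, 320, 1),
]
_EFFNET_STEM_CHANNELS = 32
_EFFNET_TOP_CHANNELS = 1280


def _round_filters(filters: int, width: float, divisor: int = 8) -> int:
    """EfficientNet channel rounding under a width multiplier."""
    filters *= width
    new = max(divisor, int(filters + divisor / 2) // divisor * divisor)
    if new < 0.9 * filters:
        new += divisor
    return int(new)


def _round_repeats(repeats: int, depth: float) -> int:
    return int(math.ceil(depth * repeats))


def _bn(name: str, channels: int) -> LayerSpec:
    return LayerSpec(
        name,
        "batch_norm",
        (ParamSpec("scale", (channels,)), ParamSpec("offset", (channels,))),
    )


def efficientnet_b1(n_outputs: int = 1) -> BackboneSpec:
    """Structural descriptor of EfficientNetB1 with an ``n_outputs``-unit head.

    Built from the compound-scaling recipe (B1: width 1.0, depth 1.1) at the
    granularity the fine-tuning mask needs: every convolution, batch-norm and
    squeeze-excitation layer with its parameter shapes. Weights are not
    materialised; the descriptor exists for mask/count computations and
    checkpoints of the real network remain pluggable.
    """
    width, depth = 1.0, 1.1
    layers: list[LayerSpec] = []
    stem = _round_filters(_EFFNET_STEM_CHANNELS, width)
    layers.append(
        LayerSpec("stem_conv", "conv", (ParamSpec("kernel", (3, 3, 3, stem)),))
    )
    layers.append(_bn("stem_bn", stem))
    in_ch = stem
    block = 0
    for expand, kernel, _stride, base_out, base_rep in _EFFNET_BASE_STAGES:
        out_ch = _round_filters(base_out, width)
        for _ in range(_round_repeats(base_rep, depth)):
            prefix = f"block{block}"
            mid = in_ch * expand
            if expand != 1:
                layers.append(
                    LayerSpec(
                        f"{prefix}_expand_conv",
                        "conv",
                        (ParamSpec("kernel", (1, 1, in_ch, mid)),),
                    )
                )
                layers.append(_bn(f"{prefix}_expand_bn", mid))
            layers.append(
                LayerSpec(
                    f"{prefix}_dwconv",
                    "conv",
                    (ParamSpec("kernel", (kernel, kernel, mid, 1)),),
                )
            )
            layers.append(_bn(f"{prefix}_dw_bn", mid))
            # squeeze-excitation: two 1x1 convs, no batch norm
            se = max(1, in_ch // 4)
            layers.append(
                LayerSpec(
                    f"{prefix}_se_reduce",
                    "conv",
                    (ParamSpec("kernel", (1, 1, mid, se)), ParamSpec("bias", (se,))),
                )
            )
            layers.append(
                LayerSpec(
                    f"{prefix}_se_expand",
                    "conv",
                    (ParamSpec("kernel", (1, 1, se, mid)), ParamSpec("bias", (mid,))),
                )
            )
            layers.append(
                LayerSpec(
                    f"{prefix}_project_conv",
                    "conv",
                    (ParamSpec("kernel", (1, 1, mid, out_ch)),),
                )
            )
            layers.append(_bn(f"{prefix}_project_bn", out_ch))
            in_ch = out_ch
            block += 1
    top = _round_filters(_EFFNET_TOP_CHANNELS, width)
    layers.append(
        LayerSpec("top_conv", "conv", (ParamSpec("kernel", (1, 1, in_ch, top)),))
    )
    layers.append(_bn("top_bn", top))
    layers.append(LayerSpec("avg_pool", "pool"))
    head = LayerSpec(
        "head",
        "dense",
        (ParamSpec("weights", (top, n_outputs)), ParamSpec("bias", (n_outputs,))),
    )
    return BackboneSpec(layers, head)


def toy_backbone_spec(channels: tuple[int, ...] = (8, 16, 32)) -> BackboneSpec:
    """Descriptor of the package's small trainable CNN (see :class:`TileCNN`)."""
    layers: list[LayerSpec] = []
    in_ch = 3
    for i, ch in enumerate(channels):
        layers.append(
            LayerSpec(
                f"block{i}_conv", "conv", (ParamSpec("kernel", (3, 3, in_ch, ch)),)
            )
        )
        layers.append(_bn(f"block{i}_bn", ch))
        layers.append(LayerSpec(f"block{i}_relu", "activation"))
        layers.append(LayerSpec(f"block{i}_pool", "pool"))
        in_ch = ch
    layers.append(LayerSpec("gap", "pool"))
    head = LayerSpec(
        "head", "dense", (ParamSpec("weights", (in_ch, 1)), ParamSpec("bias", (1,)))
    )
    return BackboneSpec(layers, head)


# ---------------------------------------------------------------------------
# numpy tile CNN
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding sliding windows of (B, H, W, C) -> (B, H, W, C, 3, 3)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    return np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))


class TileCNN:
    """Small convolutional tile scorer trained by partial fine-tuning.

    Architecture: ``channels``-wide 3x3 conv + batch norm + ReLU + 2x2 average
    pool blocks, global average pooling, and a single-unit sigmoid head.
    Convolution filters are frozen at their random initial values (the
    stand-in for pretrained weights); only batch-norm scale/offset vectors
    and the head are trainable, exactly the partial fine-tuning mask.

    Inputs are RGB uint8 tiles; internally pixels are scaled to [0, 1] and
    centred. Batch statistics are used while training, exponential running
    statistics at inference.
    """

    BN_MOMENTUM = 0.9
    BN_EPS = 1e-5

    def __init__(
        self,
        tile_size: int,
        channels: tuple[int, ...] = (8, 16, 32),
        seed: int = 0,
    ) -> None:
        if tile_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"tile_size {tile_size} must be divisible by {2 ** len(channels)}"
            )
        self.tile_size = int(tile_size)
        self.channels = tuple(int(c) for c in channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        in_ch = 3
        for i, ch in enumerate(self.channels):
            fan_in = 9 * in_ch
            self.params[f"block{i}_conv/kernel"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(3, 3, in_ch, ch)
            ).astype(np.float32)
            self.params[f"block{i}_bn/scale"] = np.ones(ch, dtype=np.float32)
            self.params[f"block{i}_bn/offset"] = np.zeros(ch, dtype=np.float32)
            self.buffers[f"block{i}_bn/mean"] = np.zeros(ch, dtype=np.float32)
            self.buffers[f"block{i}_bn/var"] = np.ones(ch, dtype=np.float32)
            in_ch = ch
        self.params["head/weights"] = rng.normal(
            0.0, 1.0 / np.sqrt(in_ch), size=(in_ch, 1)
        ).astype(np.float32)
        self.params["head/bias"] = np.zeros(1, dtype=np.float32)

    # -- descriptor interface -------------------------------------------

    def spec(self) -> BackboneSpec:
        return toy_backbone_spec(self.channels)

    def trainable_ids(self) -> set[str]:
        return trainable_mask(self.spec())

    # -- state ----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param:{k}": v.copy() for k, v in self.params.items()}
        out.update({f"buffer:{k}": v.copy() for k, v in self.buffers.items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            kind, name = key.split(":", 1)
            target = self.params if kind == "param" else self.buffers
            target[name] = value.copy()

    def snapshot(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())

    # -- forward / backward ---------------------------------------------

    @staticmethod
    def _prepare(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        return x.astype(np.float32) - 0.5

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, dict]:
        """Probabilities for a (B, H, W, 3) batch; cache retained for backward."""
        a = self._prepare(x)
        cache: dict = {"inputs": [], "bn": [], "relu": [], "pool_in": []}
        for i in range(len(self.channels)):
            cols = _im2col(a)
            b, hh, ww = cols.shape[:3]
            kernel = self.params[f"block{i}_conv/kernel"]
            cout = kernel.shape[3]
            # flatten windows as (ki, kj, c) on both sides of the matmul
            flat = cols.transpose(0, 1, 2, 4, 5, 3).reshape(b, hh, ww, -1)
            kmat = kernel.reshape(-1, cout)
            z = flat @ kmat
            cache["inputs"].append(a)
            # batch norm
            scale = self.params[f"block{i}_bn/scale"]
            offset = self.params[f"block{i}_bn/offset"]
            if training:
                mean = z.mean(axis=(0, 1, 2))
                var = z.var(axis=(0, 1, 2))
                m = self.BN_MOMENTUM
                self.buffers[f"block{i}_bn/mean"] = (
                    m * self.buffers[f"block{i}_bn/mean"] + (1 - m) * mean
                ).astype(np.float32)
                self.buffers[f"block{i}_bn/var"] = (
                    m * self.buffers[f"block{i}_bn/var"] + (1 - m) * var
                ).astype(np.float32)
            else:
                mean = self.buffers[f"block{i}_bn/mean"]
                var = self.buffers[f"block{i}_bn/var"]
            inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
            xhat = (z - mean) * inv_std
            bn_out = xhat * scale + offset
            cache["bn"].append((xhat, inv_std, scale, training))
            # relu
            relu_out = np.maximum(bn_out, 0.0)
            cache["relu"].append(bn_out > 0)
            # 2x2 average pool
            b2, hh2, ww2, cc = relu_out.shape
            pooled = relu_out.reshape(b2, hh2 // 2, 2, ww2 // 2, 2, cc).mean(axis=(2, 4))
            cache["pool_in"].append(relu_out.shape)
            a = pooled
        # global average pool
        cache["gap_in"] = a.shape
        feats = a.mean(axis=(1, 2))
        cache["feats"] = feats
        logits = feats @ self.params["head/weights"] + self.params["head/bias"]
        probs = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        cache["probs"] = probs
        return probs, cache

    def backward(self, cache: dict, labels: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy w.r.t. trainable parameters."""
        probs = cache["probs"]
        b = probs.shape[0]
        dlogits = ((probs - labels.astype(np.float32)) / b)[:, None]
        grads: dict[str, np.ndarray] = {}
        grads["head/weights"] = cache["feats"].T @ dlogits
        grads["head/bias"] = dlogits.sum(axis=0)
        da = dlogits @ self.params["head/weights"].T  # (B, C)
        bsz, gh, gw, gc = cache["gap_in"]
        da = np.broadcast_to(da[:, None, None, :], (bsz, gh, gw, gc)) / (gh * gw)
        for i in reversed(range(len(self.channels))):
            # un-pool (average): spread gradient uniformly over each 2x2 block
            ps = cache["pool_in"][i]
            d = np.repeat(np.repeat(da, 2, axis=1), 2, axis=2) / 4.0
            d = d[:, : ps[1], : ps[2], :]
            # relu
            d = d * cache["relu"][i]
            # batch norm backward
            xhat, inv_std, scale, was_training = cache["bn"][i]
            grads[f"block{i}_bn/scale"] = (d * xhat).sum(axis=(0, 1, 2))
            grads[f"block{i}_bn/offset"] = d.sum(axis=(0, 1, 2))
            if was_training:
                dxhat = d * scale
                dz = (
                    dxhat
                    - dxhat.mean(axis=(0, 1, 2))
                    - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
                ) * inv_std
            else:
                dz = d * scale * inv_std
            if i == 0:
                break  # conv0 input gradient is never needed
            # conv backward to the previous activation (frozen kernel)
            kernel = self.params[f"block{i}_conv/kernel"]
            cin = kernel.shape[2]
            kmat = kernel.reshape(-1, kernel.shape[3])
            dflat = dz @ kmat.T  # (B, H, W, 9*cin)
            bb, hh, ww = dz.shape[:3]
            dcols = dflat.reshape(bb, hh, ww, 3, 3, cin)
            dxp = np.zeros((bb, hh + 2, ww + 2, cin), dtype=np.float32)
            for ki in range(3):
                for kj in range(3):
                    dxp[:, ki : ki + hh, kj : kj + ww, :] += dcols[:, :, :, ki, kj, :]
            da = dxp[:, 1:-1, 1:-1, :]
        return grads

    # -- inference -------------------------------------------------------

    def predict_proba(self, tiles: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Probabilities for a stack of tiles using running BN statistics."""
        tiles = np.asarray(tiles)
        out = np.empty(tiles.shape[0], dtype=np.float64)
        for start in range(0, tiles.shape[0], batch_size):
            probs, _ = self.forward(tiles[start : start + batch_size], training=False)
            out[start : start + probs.shape[0]] = probs
        return out


class Adam:
    """Adam optimizer restricted to the trainable-parameter mask."""

    def __init__(
        self,
        model: TileCNN,
        trainable: set[str] | None = None,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.trainable = set(trainable) if trainable is not None else model.trainable_ids()
        missing = self.trainable - set(model.params)
        if missing:
            raise ValueError(f"unknown trainable parameters: {sorted(missing)}")
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(model.params[k]) for k in self.trainable}
        self.v = {k: np.zeros_like(model.params[k]) for k in self.trainable}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in self.trainable:
            g = grads[k].reshape(self.model.params[k].shape).astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.model.params[k] = (
                self.model.params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(np.float32)


def bce_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of predicted probabilities."""
    p = np.clip(np.asarray(probs, dtype=np.float64), eps, 1 - eps)
    y = np.asarray(labels, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
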
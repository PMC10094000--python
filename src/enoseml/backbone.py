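"""The 18-layer residual convolutional backbone and its training loop.

Architecture (ResNet-18, adapted to 10-channel 10x10 inputs):

* **stem** — 7x7 convolution, stride 2, padding 3, 64 filters; batch norm;
  ReLU; 3x3 max pool, stride 2, padding 1.
* **four stages** of two residual blocks each, with widths 64, 128, 256,
  512. The first block of stages 2-4 downsamples: its first 3x3 convolution
  and its 1x1 projection shortcut use stride 2. All other blocks keep the
  identity shortcut. Each block computes ``relu(bn(conv(relu(bn(conv(x)))))
  + shortcut(x))``.
* **head** — global average pooling to a 512-vector, then a linear C-way
  classifier used for training (and for the backbone-alone ablation arm).

The 1x1 projection shortcut uses padding 0: with any positive padding a 1x1
stride-2 kernel would produce a larger map than the main path, so the shapes
of the two branches could never match (see :func:`conv_out_size`).

After training, :func:`extract_features` discards the head and returns the
512-dimensional pooled activations with batch-norm statistics frozen, so
feature extraction is a deterministic function of the input.

For a 10x10 input the spatial trace is 5 (stem conv), 3 (stem pool), 3, 2,
1, 1 through the four stages; for a 224x224 RGB-style input it is the
classical 112, 56, 56, 28, 14, 7.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from enoseml._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    softmax_cross_entropy,
)

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "Backbone",
    "conv_out_size",
    "shape_trace",
    "build_backbone",
    "train_backbone",
    "extract_features",
    "predict_backbone",
    "save_backbone",
    "load_backbone",
]

STAGE_WIDTHS = (64, 128, 256, 512)
FEATURE_DIM = 512


def conv_out_size(n: int, k: int, s: int, p: int) -> int:
    """Spatial output size of a convolution/pooling layer.

    ``floor((n + 2p - k) / s) + 1``; raises if the input is too small for
    the layer.
    """
    if n < 1 or k < 1 or s < 1 or p < 0:
        raise ValueError(f"invalid layer geometry n={n}, k={k}, s={s}, p={p}")
    out = (n + 2 * p - k) // s + 1
    if out < 1:
        raise ValueError(
            f"input of size {n} too small for kernel {k}, stride {s}, padding {p}"
        )
    return out


@dataclass(frozen=True)
class BackboneConfig:
    """Geometry of the backbone; defaults match the 10-channel adaptation."""

    in_channels: int = 10
    stage_widths: tuple[int, ...] = STAGE_WIDTHS
    feature_dim: int = FEATURE_DIM
    num_classes: int = 9


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol for the backbone's classification head.

    Adam with cross-entropy; the seed fixes initialization and batch order.
    """

    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


def shape_trace(input_size: int) -> list[int]:
    """Spatial sizes after stem conv, stem pool and each of the four stages.

    Raises (naming the stage) if the input underflows anywhere.
    """
    sizes = []
    try:
        n = conv_out_size(input_size, 7, 2, 3)  # stem conv
    except ValueError as e:
        raise ValueError(f"stem conv: {e}") from None
    sizes.append(n)
    n = conv_out_size(n, 3, 2, 1)  # stem pool
    sizes.append(n)
    sizes.append(n)  # stage 1: stride-1 blocks preserve size
    for stage in (2, 3, 4):
        try:
            n = conv_out_size(n, 3, 2, 1)  # downsampling block
        except ValueError as e:
            raise ValueError(f"stage {stage}: {e}") from None
        sizes.append(n)
    return sizes


class _BasicBlock:
    """Residual block; identity shortcut, or 1x1 stride-2 projection when
    downsampling."""

    def __init__(
        self, in_ch: int, out_ch: int, downsample: bool, rng: np.random.Generator
    ) -> None:
        stride = 2 if downsample else 1
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        self.downsample = downsample
        if downsample:
            # 1x1 stride-2 projection, padding 0: any positive padding would
            # make the shortcut map larger than the main path.
            self.proj = Conv2d(in_ch, out_ch, 1, 2, 0, rng)
            self.bn_proj = BatchNorm2d(out_ch)

    def layers(self) -> list:
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.downsample:
            out += [self.proj, self.bn_proj]
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        if self.downsample:
            shortcut = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            shortcut = x
        return self.relu_out.forward(h + shortcut, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dh = self.bn2.backward(dsum)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.downsample:
            dshort = self.proj.backward(self.bn_proj.backward(dsum))
        else:
            dshort = dsum
        return dx + dshort


class _ResNet:
    """The assembled network: stem, four residual stages, pooled head."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        w1 = cfg.stage_widths[0]
        self.stem_conv = Conv2d(cfg.in_channels, w1, 7, 2, 3, rng)
        self.stem_bn = BatchNorm2d(w1)
        self.stem_relu = ReLU()
        self.stem_pool = MaxPool2d(3, 2, 1)
        self.blocks: list[_BasicBlock] = []
        in_ch = w1
        for stage, width in enumerate(cfg.stage_widths):
            for b in range(2):
                downsample = stage > 0 and b == 0
                self.blocks.append(_BasicBlock(in_ch, width, downsample, rng))
                in_ch = width
        self.pool = GlobalAvgPool()
        self.fc = Linear(cfg.stage_widths[-1], cfg.num_classes, rng)

    def layers(self) -> list:
        out = [self.stem_conv, self.stem_bn, self.stem_relu, self.stem_pool]
        for b in self.blocks:
            out += b.layers()
        out += [self.pool, self.fc]
        return out

    def forward(
        self, x: np.ndarray, train: bool = True, features_only: bool = False
    ) -> np.ndarray:
        h = self.stem_conv.forward(x, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        h = self.stem_pool.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train)
        feats = self.pool.forward(h, train)
        if features_only:
            return feats
        return self.fc.forward(feats, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.pool.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        d = self.stem_pool.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem_conv.backward(d)

    def n_parameters(self) -> int:
        return sum(v.size for l in self.layers() for v in l.params.values())


@dataclass
class Backbone:
    """Trained (or untrained) backbone plus its C-way linear head."""

    net: _ResNet
    config: BackboneConfig
    classes: list[str] = field(default_factory=list)
    train_config: TrainConfig | None = None
    history: list[dict] = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def parameter_checksum(self) -> float:
        """Sum of all parameters — a cheap determinism fingerprint."""
        return float(
            sum(v.astype(np.float64).sum() for l in self.net.layers() for v in l.params.values())
        )


def build_backbone(cfg: BackboneConfig | None = None, seed: int = 0) -> Backbone:
    """Build an untrained backbone; validates the 10x10 shape trace."""
    cfg = cfg or BackboneConfig()
    rng = np.random.default_rng(seed)
    net = _ResNet(cfg, rng)
    return Backbone(net=net, config=cfg)


def _encode_labels(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in labels], dtype=np.int64), classes


def train_backbone(
    X: np.ndarray,
    labels: list[str],
    cfg: TrainConfig | None = None,
    backbone_cfg: BackboneConfig | None = None,
) -> Backbone:
    """Train the backbone end-to-end with its linear head.

    ``X`` is (n, channels, 10, 10); labels are class strings. Training is
    deterministic given ``cfg.seed`` (initialization and batch order both
    derive from it). Returns the trained backbone with a per-epoch loss and
    accuracy history.
    """
    cfg = cfg or TrainConfig()
    y, classes = _encode_labels(list(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    X = np.asarray(X, dtype=np.float32)
    bcfg = backbone_cfg or BackboneConfig(
        in_channels=X.shape[1], num_classes=len(classes)
    )
    if bcfg.num_classes != len(classes):
        bcfg = BackboneConfig(
            in_channels=bcfg.in_channels,
            stage_widths=bcfg.stage_widths,
            feature_dim=bcfg.feature_dim,
            num_classes=len(classes),
        )
    shape_trace(X.shape[2])  # fail early on underflow
    backbone = build_backbone(bcfg, seed=cfg.seed)
    backbone.classes = classes
    backbone.train_config = cfg
    net = backbone.net
    opt = Adam(net.layers(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        backbone.history.append(
            {"epoch": epoch + 1, "loss": sum(losses) / n, "accuracy": correct / n}
        )
    _recalibrate_batchnorm(net, X, cfg.batch_size)
    return backbone


def _recalibrate_batchnorm(net: _ResNet, X: np.ndarray, batch_size: int) -> None:
    """Replace batch-norm running statistics with exact population statistics
    of the final parameters over the training set.

    The momentum-averaged statistics accumulated *during* optimization lag
    behind the parameters (few update steps, fast-moving activations), which
    can make frozen-statistics inference much worse than training-mode
    inference. One deterministic pass in stat-collection mode fixes that.
    """
    bns = [l for l in net.layers() if isinstance(l, BatchNorm2d)]
    for bn in bns:
        bn.start_stat_collection()
    for start in range(0, len(X), batch_size):
        net.forward(X[start : start + batch_size], train=True)
    for bn in bns:
        bn.finalize_stat_collection()


def _batched_forward(
    backbone: Backbone, X: np.ndarray, features_only: bool, batch: int = 256
) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    outs = []
    for start in range(0, len(X), batch):
        outs.append(
            backbone.net.forward(
                X[start : start + batch], train=False, features_only=features_only
            )
        )
    return np.concatenate(outs, axis=0)


def extract_features(backbone: Backbone, X: np.ndarray) -> np.ndarray:
    """Pooled 512-dim embeddings, head removed, batch-norm stats frozen."""
    if X.shape[1] != backbone.config.in_channels:
        raise ValueError(
            f"input has {X.shape[1]} channels; backbone expects "
            f"{backbone.config.in_channels}"
        )
    feats = _batched_forward(backbone, X, features_only=True)
    return feats.astype(np.float64)


def predict_backbone(backbone: Backbone, X: np.ndarray) -> np.ndarray:
    """Class predictions from the backbone's own linear head."""
    if not backbone.classes:
        raise ValueError("backbone has not been trained")
    logits = _batched_forward(backbone, X, features_only=False)
    return np.array(backbone.classes, dtype=object)[logits.argmax(axis=1)]


# ---------------------------------------------------------------------------
# Checkpointing: flat npz of parameters and running stats + JSON config echo
# ---------------------------------------------------------------------------


def _state_arrays(net: _ResNet) -> dict[str, np.ndarray]:
    state = {}
    for i, layer in enumerate(net.layers()):
        for key, val in layer.params.items():
            state[f"layer{i}.{key}"] = val
        if isinstance(layer, BatchNorm2d):
            state[f"layer{i}.running_mean"] = layer.running_mean
            state[f"layer{i}.running_var"] = layer.running_var
    return state


def save_backbone(backbone: Backbone, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "config": {
            "in_channels": backbone.config.in_channels,
            "stage_widths": list(backbone.config.stage_widths),
            "feature_dim": backbone.config.feature_dim,
            "num_classes": backbone.config.num_classes,
        },
        "classes": backbone.classes,
    }
    np.savez(
        path,
        _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **_state_arrays(backbone.net),
    )


def load_backbone(path: str | Path) -> Backbone:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = BackboneConfig(
            in_channels=meta["config"]["in_channels"],
            stage_widths=tuple(meta["config"]["stage_widths"]),
            feature_dim=meta["config"]["feature_dim"],
            num_classes=meta["config"]["num_classes"],
        )
        backbone = build_backbone(cfg, seed=0)
        backbone.classes = list(meta["classes"])
        for i, layer in enumerate(backbone.net.layers()):
            for key in layer.params:
                layer.params[key][...] = data[f"layer{i}.{key}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = data[f"layer{i}.running_mean"]
                layer.running_var[...] = data[f"layer{i}.running_var"]
    return backbone
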
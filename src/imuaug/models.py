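"""Window classifiers: a plain temporal CNN and an InceptionTime network.

Both take ``(N, W, C)`` window batches and emit per-class probabilities.

**Conv1D** — four valid (unpadded) temporal convolutions with stride 2 and
ReLU, flattened and fed to three dense layers (reference widths 800 / 200 /
n_classes) with ReLU and dropout after the first two.  The 200-unit
activation is the penultimate feature used for embedding exports.

**InceptionTime** — a stack of Inception modules: a 1-kernel bottleneck,
three parallel same-padded convolutions with kernels of different sizes
(reference 10/20/40), a max-pool branch followed by a 1-kernel convolution,
channel concatenation, batch normalization and ReLU; residual shortcuts
join the stack every ``residual_every`` modules; a global average pool over
time feeds the softmax head.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm,
    Conv1D,
    Dropout,
    Flatten,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPoolSame,
    ReLU,
    Sequential,
    conv_out_len,
    softmax,
)


@dataclass(frozen=True)
class Conv1DConfig:
    conv_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 5
    stride: int = 2
    dense_units: tuple[int, ...] = (800, 200, 52)
    dropout_p: float = 0.7
    input_len: int = 740
    input_channels: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if len(self.dense_units) < 1:
            raise ValueError("need at least the output dense layer")

    @property
    def n_classes(self) -> int:
        return self.dense_units[-1]

    def conv_lengths(self) -> list[int]:
        """Temporal length after each convolution (shape-propagation rule)."""
        lengths = []
        L = self.input_len
        for _ in self.conv_channels:
            L = conv_out_len(L, self.kernel_size, self.stride)
            lengths.append(L)
        return lengths

    def min_input_len(self) -> int:
        """Smallest input length for which every conv output is non-empty."""
        L = 1
        for _ in self.conv_channels:
            L = (L - 1) * self.stride + self.kernel_size
        return L

    @property
    def flatten_dim(self) -> int:
        return self.conv_lengths()[-1] * self.conv_channels[-1]


@dataclass(frozen=True)
class InceptionConfig:
    n_modules: int = 6
    n_filters: int = 32
    kernel_sizes: tuple[int, ...] = (10, 20, 40)
    bottleneck_channels: int = 32
    use_residual: bool = True
    residual_every: int = 3
    n_classes: int = 52
    input_channels: int = 30

    def __post_init__(self) -> None:
        if not self.kernel_sizes:
            raise ValueError("kernel_sizes must be nonempty")
        if min(self.n_modules, self.n_filters, self.bottleneck_channels, self.n_classes) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def module_out_channels(self) -> int:
        return (len(self.kernel_sizes) + 1) * self.n_filters


class InceptionModule(Layer):
    """Bottleneck + parallel convs + max-pool branch + BN + ReLU."""

    def __init__(self, in_ch: int, cfg: InceptionConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.bottleneck = Conv1D(in_ch, cfg.bottleneck_channels, 1, bias=False, rng=rng)
        self.branches = [
            Conv1D(cfg.bottleneck_channels, cfg.n_filters, k, padding="same", bias=False, rng=rng)
            for k in cfg.kernel_sizes
        ]
        self.pool = MaxPoolSame(3)
        self.pool_conv = Conv1D(in_ch, cfg.n_filters, 1, bias=False, rng=rng)
        self.bn = BatchNorm(cfg.module_out_channels)
        self.relu = ReLU()

    def forward(self, x, train=False, rng=None):
        b = self.bottleneck.forward(x, train, rng)
        ys = [br.forward(b, train, rng) for br in self.branches]
        ys.append(self.pool_conv.forward(self.pool.forward(x, train, rng), train, rng))
        self._split = np.cumsum([y.shape[-1] for y in ys])[:-1]
        cat = np.concatenate(ys, axis=-1)
        return self.relu.forward(self.bn.forward(cat, train, rng), train, rng)

    def backward(self, dy):
        dcat = self.bn.backward(self.relu.backward(dy))
        parts = np.split(dcat, self._split, axis=-1)
        db = sum(br.backward(d) for br, d in zip(self.branches, parts[:-1]))
        dx = self.bottleneck.backward(db)
        dx += self.pool.backward(self.pool_conv.backward(parts[-1]))
        return dx

    def sublayers(self):
        return (
            self.bottleneck.sublayers()
            + [l for br in self.branches for l in br.sublayers()]
            + self.pool_conv.sublayers()
            + self.bn.sublayers()
        )


class InceptionBody(Layer):
    """Stacked Inception modules with periodic residual shortcuts."""

    def __init__(self, cfg: InceptionConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        ch = cfg.input_channels
        self.modules_: list[InceptionModule] = []
        self.shortcuts: dict[int, tuple[Conv1D, BatchNorm]] = {}
        for i in range(cfg.n_modules):
            self.modules_.append(InceptionModule(ch, cfg, rng))
            ch = cfg.module_out_channels
            if cfg.use_residual and (i + 1) % cfg.residual_every == 0:
                in_ch = cfg.input_channels if i + 1 == cfg.residual_every else ch
                self.shortcuts[i] = (
                    Conv1D(in_ch, ch, 1, bias=False, rng=rng),
                    BatchNorm(ch),
                )
        self.out_channels = ch
        self._relu_masks: dict[int, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):
        res_input = x
        for i, mod in enumerate(self.modules_):
            x = mod.forward(x, train, rng)
            if i in self.shortcuts:
                conv, bn = self.shortcuts[i]
                sc = bn.forward(conv.forward(res_input, train, rng), train, rng)
                x = x + sc
                self._relu_masks[i] = x > 0
                x = x * self._relu_masks[i]
                res_input = x
        return x

    def backward(self, dy):
        joins = sorted(self.shortcuts)
        last_join = joins[-1] if joins else -1
        # trailing modules after the last residual join are a plain chain
        for i in range(len(self.modules_) - 1, last_join, -1):
            dy = self.modules_[i].backward(dy)
        # then walk the residual segments in reverse; at each join the
        # gradient splits into the module chain and the shortcut and the two
        # contributions are summed at the segment input
        for seg_end in reversed(joins):
            dy = dy * self._relu_masks[seg_end]
            conv, bn = self.shortcuts[seg_end]
            d_sc = conv.backward(bn.backward(dy))
            seg_start = seg_end - self.cfg.residual_every + 1
            d_main = dy
            for i in range(seg_end, seg_start - 1, -1):
                d_main = self.modules_[i].backward(d_main)
            dy = d_main + d_sc
        return dy

    def sublayers(self):
        out = []
        for mod in self.modules_:
            out.extend(mod.sublayers())
        for conv, bn in self.shortcuts.values():
            out.extend(conv.sublayers())
            out.extend(bn.sublayers())
        return out


@dataclass
class ClassifierHandle:
    """A built classifier: feature extractor + softmax head.

    ``features`` maps a window batch to penultimate features (dropout off
    at inference); ``head`` maps features to logits.  Probabilities are the
    softmax of the logits.
    """

    features: Layer
    head: Layer
    final_linear: Linear
    n_classes: int
    penultimate_dim: int
    name: str
    config: object

    def logits(self, X: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        return self.head.forward(self.features.forward(X, train, rng), train, rng)

    def backward(self, dlogits: np.ndarray) -> None:
        self.features.backward(self.head.backward(dlogits))

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = [softmax(self.logits(X[i : i + batch])) for i in range(0, len(X), batch)]
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        return self.predict_proba(X, batch).argmax(axis=1)

    def penultimate(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = [self.features.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
        return np.concatenate(out, axis=0)

    def sublayers(self) -> list[Layer]:
        return self.features.sublayers() + self.head.sublayers()

    def clone(self) -> "ClassifierHandle":
        return copy.deepcopy(self)

    def state_snapshot(self) -> list[np.ndarray]:
        out = []
        for sub in self.sublayers():
            for name in sorted(sub.params):
                out.append(sub.params[name].copy())
        return out


def build_conv1d(config: Conv1DConfig = Conv1DConfig(), seed: int = 0) -> ClassifierHandle:
    """Build the temporal CNN; raises if the input is too short for the stack."""
    if config.conv_lengths()[-1] < 1:
        raise ValueError(
            f"input length {config.input_len} too short for the conv stack; "
            f"minimum is {config.min_input_len()}"
        )
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    ch = config.input_channels
    for out_ch in config.conv_channels:
        layers.append(Conv1D(ch, out_ch, config.kernel_size, config.stride, rng=rng))
        layers.append(ReLU())
        ch = out_ch
    layers.append(Flatten())
    dim = config.flatten_dim
    for units in config.dense_units[:-1]:
        layers.append(Linear(dim, units, rng=rng))
        layers.append(ReLU())
        layers.append(Dropout(config.dropout_p))
        dim = units
    # penultimate feature = activation of the last hidden dense layer; the
    # trailing dropout belongs to the head so inference features skip it
    *feature_layers, last_dropout = layers
    final = Linear(dim, config.n_classes, rng=rng)
    return ClassifierHandle(
        features=Sequential(feature_layers),
        head=Sequential([last_dropout, final]),
        final_linear=final,
        n_classes=config.n_classes,
        penultimate_dim=dim,
        name="conv1d",
        config=config,
    )


def build_inceptiontime(
    config: InceptionConfig = InceptionConfig(), seed: int = 0
) -> ClassifierHandle:
    rng = np.random.default_rng(seed)
    body = InceptionBody(config, rng)
    final = Linear(body.out_channels, config.n_classes, rng=rng)
    return ClassifierHandle(
        features=Sequential([body, GlobalAvgPool()]),
        head=final,
        final_linear=final,
        n_classes=config.n_classes,
        penultimate_dim=body.out_channels,
        name="inceptiontime",
        config=config,
    )


def save_checkpoint(handle: ClassifierHandle, path) -> None:
    """Weights (and batch-norm running stats) to ``.npz``; config to YAML.

    The YAML file sits next to the array container so a checkpoint is
    self-describing and can be rebuilt without the original code path.
    """
    import dataclasses
    from pathlib import Path

    import yaml

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, sub in enumerate(handle.sublayers()):
        for name in sorted(sub.params):
            arrays[f"{i}:{name}"] = sub.params[name]
        if hasattr(sub, "running_mean"):
            arrays[f"{i}:running_mean"] = sub.running_mean
            arrays[f"{i}:running_var"] = sub.running_var
    np.savez(path, **arrays)
    meta = {
        "name": handle.name,
        "n_classes": handle.n_classes,
        "config": dataclasses.asdict(handle.config),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_checkpoint(path) -> ClassifierHandle:
    """Rebuild a classifier from :func:`save_checkpoint` output."""
    from pathlib import Path

    import yaml

    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    cfg = meta["config"]
    for key in ("conv_channels", "dense_units", "kernel_sizes"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    if meta["name"] == "conv1d":
        handle = build_conv1d(Conv1DConfig(**cfg))
    else:
        handle = build_inceptiontime(InceptionConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        subs = handle.sublayers()
        for key in data.files:
            idx, name = key.split(":", 1)
            sub = subs[int(idx)]
            if name == "running_mean":
                sub.running_mean = data[key]
            elif name == "running_var":
                sub.running_var = data[key]
            else:
                sub.params[name] = data[key]
    return handle


def reinit_final_dense(handle: ClassifierHandle, seed: int = 0) -> ClassifierHandle:
    """Re-instantiate the final pre-softmax dense layer in place.

    All other parameters are untouched and stay trainable — the transfer-
    learning head reset.
    """
    handle.final_linear.reinit(np.random.default_rng(seed))
    return handle
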
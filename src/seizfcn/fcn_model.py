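"""Lightweight fully convolutional seizure detector over imaged-EEG.

Architecture (base configuration, N input EEG channels):

    [conv1d(N->128, k=8) + BatchNorm + ReLU + maxpool4] + dropout(0.1)
    [conv1d(128->128, k=8) + BatchNorm + ReLU + maxpool4] + dropout(0.1)
    [conv1d(128->128, k=8) + BatchNorm + ReLU + maxpool4] + dropout(0.3)
    conv1d(128->128, k=1) -> conv1d(128->2, k=1) -> softmax over classes

Convolutions are one-dimensional along time with EEG channels as input
features and length-preserving padding; each max-pool truncates the
remainder, so three 4x pools give exactly floor(L/64) output positions —
one (interictal, ictal) probability pair per 64 input samples, for inputs
of arbitrary length. At N=23 the default configuration has 303,618
trainable parameters.

The network, its backward pass and the Adam optimizer are implemented
directly on NumPy arrays (float32), which keeps training reproducible on a
single CPU thread: same seed and data, same final weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .core import ConfigError, Recording, TrainingError
from .representation import WindowImage

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    n_input_channels: int = 23
    n_blocks: int = 3
    filters_per_block: int = 128
    temporal_kernel: int = 8
    pool_factor: int = 4
    head_filters: int = 128
    n_classes: int = 2
    dropout_early: float = 0.1
    dropout_late: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_input_channels < 1:
            raise ConfigError("n_input_channels must be >= 1")
        if self.n_classes != 2:
            raise ConfigError("n_classes must be 2 (interictal vs ictal)")
        if self.pool_factor**self.n_blocks != 64:
            raise ConfigError(
                "pool factors must multiply to the 64-sample prediction stride "
                f"(got {self.pool_factor}^{self.n_blocks})"
            )
        for name in ("filters_per_block", "temporal_kernel", "head_filters"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("dropout_early", "dropout_late"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must lie in [0, 1)")

    @property
    def stride(self) -> int:
        return self.pool_factor**self.n_blocks


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 30
    val_fraction: float = 0.1
    patience: int = 3
    seed: int = 0


@dataclass
class PredictionTrack:
    """Dense ictal probabilities, one per 64 input samples."""

    recording_id: str
    probabilities: np.ndarray  # (floor(L/64),) ictal-class probability
    stride: int = 64
    sampling_rate: float = 256.0

    def __len__(self) -> int:
        return len(self.probabilities)

    def bin_times(self) -> np.ndarray:
        """Start time (s) of each prediction bin."""
        return np.arange(len(self.probabilities)) * self.stride / self.sampling_rate


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal trainable layer: params/grads dicts plus forward/backward."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(_Layer):
    """Same-padded 1-D convolution over (batch, channels, length)."""

    def __init__(self, name, c_in, c_out, kernel, rng):
        super().__init__(name)
        scale = math.sqrt(2.0 / (c_in * kernel))  # He initialisation
        self.params["W"] = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(_DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=_DTYPE)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self._cols = None
        self._in_shape = None

    def forward(self, x, training):
        k = self.kernel
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        b, c, lp = xp.shape
        L = x.shape[2]
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(b * L, c * k)
        w = self.params["W"].reshape(self.c_out, c * k)
        y = cols @ w.T + self.params["b"]
        if training:
            self._cols = cols
            self._in_shape = x.shape
        else:
            self._cols = None
        return y.reshape(b, L, self.c_out).transpose(0, 2, 1)

    def backward(self, dy):
        b, _, L = dy.shape
        k = self.kernel
        pl = (k - 1) // 2
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * L, self.c_out)
        w = self.params["W"].reshape(self.c_out, self.c_in * k)
        self.grads["W"] = (dyf.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ w).reshape(b, L, self.c_in, k)
        dxp = np.zeros((b, self.c_in, L + k - 1), dtype=_DTYPE)
        for j in range(k):  # scatter-add each kernel tap
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pl : pl + L]


class BatchNorm1d(_Layer):
    """Per-feature-channel normalisation over (batch, length)."""

    def __init__(self, name, c, momentum=0.1, eps=1e-5):
        super().__init__(name)
        self.params["gamma"] = np.ones(c, dtype=_DTYPE)
        self.params["beta"] = np.zeros(c, dtype=_DTYPE)
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, training):
        if training and not self.frozen:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if training:
            self._cache = (xhat.astype(_DTYPE), inv.astype(_DTYPE))
        return (self.params["gamma"][None, :, None] * xhat
                + self.params["beta"][None, :, None]).astype(_DTYPE)

    def backward(self, dy):
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None]
        if self.frozen:
            dx = dy * g * inv[None, :, None]
        else:
            # standard batch-norm backward
            dx = (g * inv[None, :, None] / n) * (
                n * dy
                - dy.sum(axis=(0, 2))[None, :, None]
                - xhat * (dy * xhat).sum(axis=(0, 2))[None, :, None]
            )
        self._cache = None
        return dx.astype(_DTYPE)


class ReLU(_Layer):
    def __init__(self, name):
        super().__init__(name)
        self._mask = None

    def forward(self, x, training):
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(_Layer):
    """Factor-f max-pool that truncates the remainder (floor semantics)."""

    def __init__(self, name, factor):
        super().__init__(name)
        self.factor = factor
        self._cache = None

    def forward(self, x, training):
        f = self.factor
        b, c, L = x.shape
        lo = L // f
        xv = x[:, :, : lo * f].reshape(b, c, lo, f)
        idx = xv.argmax(axis=3)
        if training:
            self._cache = (idx, x.shape)
        return np.take_along_axis(xv, idx[..., None], axis=3)[..., 0]

    def backward(self, dy):
        idx, shape = self._cache
        b, c, L = shape
        f = self.factor
        lo = L // f
        dxv = np.zeros((b, c, lo, f), dtype=_DTYPE)
        np.put_along_axis(dxv, idx[..., None], dy[..., None], axis=3)
        dx = np.zeros(shape, dtype=_DTYPE)
        dx[:, :, : lo * f] = dxv.reshape(b, c, lo * f)
        self._cache = None
        return dx


class Dropout(_Layer):
    def __init__(self, name, p):
        super().__init__(name)
        self.p = p
        self.rng = np.random.default_rng(0)  # reseeded by the trainer
        self._mask = None

    def forward(self, x, training):
        if not training or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(_DTYPE) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class FCNDetector:
    """The 3-block FCN; build with :func:`build_model`."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.adapter: Conv1d | None = None
        rng = np.random.default_rng(config.seed)
        f, k = config.filters_per_block, config.temporal_kernel
        layers: list[_Layer] = []
        c_in = config.n_input_channels
        for i in range(1, config.n_blocks + 1):
            p_drop = config.dropout_late if i == config.n_blocks else config.dropout_early
            layers += [
                Conv1d(f"block{i}.conv", c_in, f, k, rng),
                BatchNorm1d(f"block{i}.bn", f),
                ReLU(f"block{i}.relu"),
                MaxPool1d(f"block{i}.pool", config.pool_factor),
                Dropout(f"block{i}.dropout", p_drop),
            ]
            c_in = f
        layers += [
            Conv1d("head.fc1", f, config.head_filters, 1, rng),
            ReLU("head.relu"),
            Conv1d("head.fc2", config.head_filters, config.n_classes, 1, rng),
        ]
        self.layers = layers

    # -- inference ---------------------------------------------------------

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if self.adapter is not None:
            x = self.adapter.forward(x, training)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(B, n_classes, floor(L/64)) softmax probabilities."""
        z = self.logits(x, training=False)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_input_channels(self) -> int:
        if self.adapter is not None:
            return self.adapter.c_in
        return self.config.n_input_channels

    def trainable_layers(self) -> list[_Layer]:
        out = [self.adapter] if self.adapter is not None else []
        return out + self.layers

    def parameter_count(self) -> int:
        return sum(
            p.size for layer in self.trainable_layers() for p in layer.params.values()
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for layer in self.trainable_layers():
            for key, val in layer.params.items():
                state[f"{layer.name}.{key}"] = val.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.trainable_layers():
            for key in layer.params:
                layer.params[key] = np.asarray(state[f"{layer.name}.{key}"], dtype=_DTYPE)
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.asarray(state[f"{layer.name}.running_mean"], dtype=_DTYPE)
                layer.running_var = np.asarray(state[f"{layer.name}.running_var"], dtype=_DTYPE)

    def save(self, path) -> None:
        meta = {"config": asdict(self.config),
                "adapter_channels": None if self.adapter is None else self.adapter.c_in}
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path) -> "FCNDetector":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(ModelConfig(**meta["config"]))
            if meta["adapter_channels"] is not None:
                add_channel_adapter(model, meta["adapter_channels"])
            model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


def build_model(config: ModelConfig) -> FCNDetector:
    """Construct the FCN with seeded, deterministic initial weights."""
    return FCNDetector(config)


def add_channel_adapter(model: FCNDetector, n_new_channels: int) -> FCNDetector:
    """Prepend a 1x1 convolution mapping ``n_new_channels`` inputs onto the
    pretrained model's channel width; all other weights are untouched.

    When the widths already match, the adapter is identity-initialised so
    predictions are bit-unchanged until finetuning moves it.
    """
    if n_new_channels < 1:
        raise ConfigError("n_new_channels must be >= 1")
    c = model.config.n_input_channels
    rng = np.random.default_rng(model.config.seed + 1)
    adapter = Conv1d("adapter.conv", n_new_channels, c, 1, rng)
    if n_new_channels == c:
        adapter.params["W"] = np.eye(c, dtype=_DTYPE)[:, :, None]
        adapter.params["b"] = np.zeros(c, dtype=_DTYPE)
    model.adapter = adapter
    return model


# ---------------------------------------------------------------------------
# Dense inference
# ---------------------------------------------------------------------------

_CHUNK = 1 << 16   # samples per inference chunk (memory bound)
_MARGIN = 256      # context samples kept on each side; multiple of the stride


def dense_predict(
    model: FCNDetector,
    data: Recording | WindowImage | np.ndarray,
    recording_id: str | None = None,
    sampling_rate: float = 256.0,
) -> PredictionTrack:
    """Run the FCN densely over a full-length input.

    Long inputs are processed in stride-aligned chunks with overlapping
    context margins wider than the receptive field, so the result matches a
    single full-length pass; dropout is off and batch norm uses running
    statistics.
    """
    if isinstance(data, Recording):
        x = data.signal
        recording_id = recording_id or data.recording_id
        sampling_rate = data.sampling_rate
    elif isinstance(data, WindowImage):
        x = data.matrix
        recording_id = recording_id or data.recording_id
    else:
        x = np.asarray(data)
    if x.ndim != 2:
        raise ConfigError("dense_predict expects a channels x samples matrix")
    if x.shape[0] != model.n_input_channels:
        raise ConfigError(
            f"channel mismatch: model expects {model.n_input_channels}, got {x.shape[0]}"
        )
    stride = model.config.stride
    L = x.shape[1]
    if L < stride:
        raise ConfigError(f"input length {L} shorter than one {stride}-sample stride")

    n_bins = L // stride
    probs = np.empty(n_bins, dtype=np.float64)
    pos = 0
    while pos < n_bins * stride:
        c1 = min(pos + _CHUNK, n_bins * stride)
        a0 = max(pos - _MARGIN, 0)
        b1 = min(c1 + _MARGIN, L)
        p = model.predict_proba(x[None, :, a0:b1])[0, 1]
        probs[pos // stride : c1 // stride] = p[(pos - a0) // stride : (c1 - a0) // stride]
        pos = c1
    return PredictionTrack(
        recording_id=recording_id or "",
        probabilities=probs,
        stride=stride,
        sampling_rate=sampling_rate,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, layers, lr, weight_decay):
        self.layers = layers
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self):
        self.t += 1
        for layer in self.layers:
            if layer.frozen:
                continue
            for key, p in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                g = g.astype(np.float64)
                if key == "W" and self.wd:
                    g = g + self.wd * p  # L2 penalty on weights only
                slot = (layer.name, key)
                m = self.m.get(slot, 0.0) * self.b1 + (1 - self.b1) * g
                v = self.v.get(slot, 0.0) * self.b2 + (1 - self.b2) * g * g
                self.m[slot], self.v[slot] = m, v
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                layer.params[key] = (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DTYPE)


def _xy_from_windows(windows: list[WindowImage]):
    x = np.stack([w.matrix for w in windows]).astype(_DTYPE)
    y = np.array([1 if w.label == "ictal" else 0 for w in windows], dtype=np.int64)
    return x, y


def _loss_and_grad(model: FCNDetector, x, y, training=True):
    """Per-bin cross-entropy averaged over bins and batch.

    One label per window, applied to every output bin of that window.
    """
    z = model.logits(x, training=training)  # (B, 2, T)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    b, _, t = p.shape
    logp = np.log(np.maximum(p[np.arange(b), y, :], 1e-12))
    loss = -logp.mean()
    onehot = np.zeros_like(p)
    onehot[np.arange(b), y, :] = 1.0
    dz = ((p - onehot) / (b * t)).astype(_DTYPE)
    return loss, dz


def train(
    model: FCNDetector,
    train_windows: list[WindowImage],
    hyper: TrainConfig | None = None,
) -> tuple[FCNDetector, list[float]]:
    """Mini-batch Adam training with L2 weight decay and early stopping.

    A held-out slice of the training windows (``val_fraction``) monitors
    generalisation; training stops after ``patience`` epochs without
    improvement or at ``max_epochs``. Returns the model (best-validation
    weights restored) and the per-epoch training-loss curve.
    """
    hyper = hyper or TrainConfig()
    if not train_windows:
        raise TrainingError("empty train set")
    labels = {w.label for w in train_windows}
    if labels != {"ictal", "interictal"}:
        raise TrainingError(f"train set must contain both classes, got {sorted(labels)}")

    x, y = _xy_from_windows(train_windows)
    rng = np.random.default_rng([hyper.seed, 7])
    for li, layer in enumerate(model.trainable_layers()):
        if isinstance(layer, Dropout):
            layer.rng = np.random.default_rng([hyper.seed, 11, li])

    n = len(x)
    order = rng.permutation(n)
    n_val = min(max(int(hyper.val_fraction * n), 2), n - 2) if n >= 8 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]

    opt = _Adam(model.trainable_layers(), hyper.learning_rate, hyper.weight_decay)
    losses: list[float] = []
    best_val = np.inf
    best_state = None
    stale = 0
    for _epoch in range(hyper.max_epochs):
        perm = rng.permutation(len(tr_idx))
        n_batches = 0
        for s in range(0, len(tr_idx), hyper.batch_size):
            idx = tr_idx[perm[s : s + hyper.batch_size]]
            loss, dz = _loss_and_grad(model, x[idx], y[idx], training=True)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training diverged (loss={loss}) at epoch {_epoch}, batch {n_batches}"
                )
            grad = dz
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            if model.adapter is not None:
                model.adapter.backward(grad)
            opt.step()
            n_batches += 1
        # epoch-end loss over the training slice in inference mode: a
        # deterministic curve free of dropout/minibatch noise
        epoch_loss = 0.0
        for s in range(0, len(tr_idx), hyper.batch_size):
            idx = tr_idx[s : s + hyper.batch_size]
            loss, _ = _loss_and_grad(model, x[idx], y[idx], training=False)
            epoch_loss += float(loss) * len(idx)
        losses.append(epoch_loss / len(tr_idx))

        if n_val:
            val_loss, _ = _loss_and_grad(model, x[val_idx], y[val_idx], training=False)
            if val_loss < best_val - 1e-5:
                best_val, best_state, stale = val_loss, model.state_dict(), 0
            else:
                stale += 1
                if stale >= hyper.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, losses


def finetune(
    model: FCNDetector,
    train_windows: list[WindowImage],
    hyper: TrainConfig | None = None,
    freeze: tuple[str, ...] = (),
) -> tuple[FCNDetector, list[float]]:
    """Continue training a pretrained model, optionally freezing layers.

    ``freeze`` holds layer-name prefixes (e.g. ``("block1", "block2")``);
    frozen layers keep their weights bit-identical and frozen batch-norm
    layers keep using their running statistics. With no frozen layers this
    is exactly :func:`train` on the pretrained weights.
    """
    all_frozen = True
    for layer in model.trainable_layers():
        layer.frozen = any(layer.name.startswith(p) for p in freeze)
        if layer.params and not layer.frozen:
            all_frozen = False
    if all_frozen:
        import logging

        logging.getLogger(__name__).warning(
            "every trainable layer is frozen; finetuning has nothing to learn"
        )
    return train(model, train_windows, hyper)
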
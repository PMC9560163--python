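"""Fully-convolutional 1D detector for sharp-wave ripples.

Architecture: seven blocks of (Conv1D -> BatchNorm -> LeakyReLU(0.1)) followed
by a per-time-step dense unit with a sigmoid, giving one ripple probability
per non-overlapping input window. Kernel size equals stride in every conv
layer (no pooling), so an input of L samples yields floor(L / S) outputs,
where S is the product of strides: 40 samples (32 ms at 1250 Hz) for the
CNN32 variant (first kernel length 5) and 16 samples (12.8 ms) for CNN12
(first kernel length 2). Kernel counts per block are 4, 2, 8, 4, 16, 8, 32.

The network is small enough (~2.5k parameters) that it is implemented
directly in NumPy: because stride equals kernel size, each convolution is a
block reshape followed by a matrix product, and training (Adam on binary
cross-entropy with soft labels, L2 penalty on conv kernels) runs in seconds
per epoch on a single core. The implementation is exactly reproducible given
a seed, and exposes the input gradients needed for kernel saliency maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EventSet, LfpRecording, TARGET_FS, downsample

__all__ = [
    "ArchitectureConfig", "TrainingConfig", "ProbabilityTrace",
    "DetectionResult", "RippleCnn", "build_model", "bce_loss", "train",
    "predict", "stream_predict", "extract_events", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureConfig:
    """Network hyper-parameters. Kernel size equals stride in every block."""

    variant: str = "CNN32"
    kernel_sizes: tuple = (5, 1, 2, 1, 2, 1, 2)
    n_filters: tuple = (4, 2, 8, 4, 16, 8, 32)
    leaky_relu_alpha: float = 0.1
    l2_lambda: float = 0.0005
    n_input_channels: int = 8

    def __post_init__(self):
        if len(self.kernel_sizes) != 7 or len(self.n_filters) != 7:
            raise ValueError("architecture has exactly 7 conv blocks")
        expected = {"CNN32": 40, "CNN12": 16}
        prod = int(np.prod(self.kernel_sizes))
        if self.variant in expected and prod != expected[self.variant]:
            raise ValueError(
                f"{self.variant} requires stride product {expected[self.variant]}, "
                f"got {prod}")

    @property
    def stride_product(self) -> int:
        return int(np.prod(self.kernel_sizes))

    @property
    def window_s(self) -> float:
        return self.stride_product / TARGET_FS

    @classmethod
    def cnn32(cls) -> "ArchitectureConfig":
        return cls(variant="CNN32", kernel_sizes=(5, 1, 2, 1, 2, 1, 2))

    @classmethod
    def cnn12(cls) -> "ArchitectureConfig":
        return cls(variant="CNN12", kernel_sizes=(2, 1, 2, 1, 2, 1, 2))


@dataclass
class TrainingConfig:
    """Optimizer and schedule (Adam with the library-default moments)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 16          # chunks per batch
    epochs: int = 3000
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ProbabilityTrace:
    """Per-window ripple probabilities.

    Trace value ``i`` corresponds to the time interval
    ``[t0 + i * window_s, t0 + (i + 1) * window_s)``; for the streaming
    (overlapped) trace ``window_s`` is the hop between emissions.
    """

    p: np.ndarray
    window_s: float
    t0: float = 0.0

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64).ravel()
        if self.p.size and (self.p.min() < 0 or self.p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def times(self) -> np.ndarray:
        """Start time of each window's interval."""
        return self.t0 + np.arange(self.p.size) * self.window_s


@dataclass
class DetectionResult:
    """Extracted events plus the trace and threshold provenance."""

    events: EventSet
    trace: ProbabilityTrace
    thresholds: tuple
    detector_id: str = "cnn"
    peak_p: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv:
    """1-D convolution with stride == kernel size (a block matmul)."""

    def __init__(self, k, c_in, c_out, rng):
        limit = np.sqrt(6.0 / (k * c_in + k * c_out))  # Glorot uniform
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.params = {
            "W": rng.uniform(-limit, limit, size=(k * c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {}
        self._cache = None

    def forward(self, x, training=False):
        b, length, c = x.shape
        t = length // self.k
        xr = x[:, : t * self.k].reshape(b, t, self.k * c)
        self._cache = (xr, length)
        return xr @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        xr, length = self._cache
        b, t, _ = xr.shape
        self.grads["W"] = np.einsum("bti,btf->if", xr, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dxr = dy @ self.params["W"].T
        dx = np.zeros((b, length, self.c_in))
        dx[:, : t * self.k] = dxr.reshape(b, t * self.k, self.c_in)
        return dx


class _BatchNorm:
    """Per-feature batch normalization (momentum 0.99, eps 1e-3)."""

    momentum = 0.99
    eps = 1e-3

    def __init__(self, c):
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.grads = {}
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, training, x.shape[0] * x.shape[1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, ivar, training, n = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not training:
            return dy * g * ivar
        dxhat = dy * g
        return (ivar / n) * (
            n * dxhat - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class _LeakyRelu:
    def __init__(self, alpha):
        self.alpha = alpha
        self.params, self.grads = {}, {}
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class _Dense:
    """Per-time-step dense unit; returns logits (sigmoid applied outside)."""

    def __init__(self, c_in, rng):
        limit = np.sqrt(6.0 / (c_in + 1))
        self.params = {"W": rng.uniform(-limit, limit, size=(c_in, 1)),
                       "b": np.zeros(1)}
        self.grads = {}
        self._cache = None

    def forward(self, x, training=False):
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._cache
        self.grads["W"] = np.einsum("bti,btf->if", x, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dy @ self.params["W"].T


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class RippleCnn:
    """The seven-block fully-convolutional detector."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        if cfg.n_input_channels != 8:
            raise ValueError("the detector expects 8 input channels")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = cfg.n_input_channels
        for k, f in zip(cfg.kernel_sizes, cfg.n_filters):
            self.blocks.append(
                (_Conv(k, c_in, f, rng), _BatchNorm(f),
                 _LeakyRelu(cfg.leaky_relu_alpha)))
            c_in = f
        self.dense = _Dense(c_in, rng)

    # -- plumbing ----------------------------------------------------------
    def layers(self):
        for conv, bn, act in self.blocks:
            yield from (conv, bn, act)
        yield self.dense

    def parameters(self):
        """Yield (layer, name, is_conv_kernel) triples of trainable arrays."""
        for conv, bn, _ in self.blocks:
            yield conv, "W", True
            yield conv, "b", False
            yield bn, "gamma", False
            yield bn, "beta", False
        yield self.dense, "W", False
        yield self.dense, "b", False

    # -- forward / backward -------------------------------------------------
    def forward(self, x, training=False, collect=False):
        """Return logits of shape (batch, floor(L/S), 1).

        With ``collect=True`` also return the per-block raw conv outputs and
        post-ReLU outputs (for kernel-activation analyses).
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] != self.cfg.n_input_channels:
            raise ValueError(
                f"expected {self.cfg.n_input_channels} channels, got {x.shape[2]}")
        conv_raw, post_relu = [], []
        for conv, bn, act in self.blocks:
            y = conv.forward(x, training)
            conv_raw.append(y)
            x = act.forward(bn.forward(y, training), training)
            post_relu.append(x)
        logits = self.dense.forward(x, training)
        if collect:
            return logits, conv_raw, post_relu
        return logits

    def predict_proba(self, x, training=False):
        return _sigmoid(self.forward(x, training))

    def backward(self, dlogits):
        """Backpropagate from the logits through the whole stack."""
        dx = self.dense.backward(dlogits)
        for conv, bn, act in reversed(self.blocks):
            dx = conv.backward(bn.backward(act.backward(dx)))
        return dx

    def input_gradient(self, x, block_id, kernel_id):
        """Gradient of the mean kernel activation w.r.t. the input.

        ``block_id`` is 1..7 for a conv block (the raw conv output is the
        kernel activation) or ``"dense"`` for the output unit (pre-sigmoid).
        Returns ``(objective_value, gradient)`` with gradient shaped like x.
        The model is evaluated in inference mode.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if block_id == "dense":
            logits = self.forward(x, training=False)
            t = logits.shape[1]
            obj = float(logits[..., 0].mean())
            dlog = np.full_like(logits, 1.0 / (logits.shape[0] * t))
            grad = self.backward(dlog)
            return obj, grad
        j = int(block_id) - 1
        if not 0 <= j < 7:
            raise ValueError("block_id must be 1..7 or 'dense'")
        _, conv_raw, _ = self.forward(x, training=False, collect=True)
        ka = conv_raw[j]
        if not 0 <= kernel_id < ka.shape[2]:
            raise ValueError(f"kernel_id out of range for block {block_id}")
        obj = float(ka[:, :, kernel_id].mean())
        dy = np.zeros_like(ka)
        dy[:, :, kernel_id] = 1.0 / (ka.shape[0] * ka.shape[1])
        dx = self.blocks[j][0].backward(dy)
        for conv, bn, act in reversed(self.blocks[:j]):
            dx = conv.backward(bn.backward(act.backward(dx)))
        return obj, dx

    def l2_penalty(self):
        return self.cfg.l2_lambda * sum(
            float((layer.params[name] ** 2).sum())
            for layer, name, is_kernel in self.parameters() if is_kernel)


def build_model(cfg: ArchitectureConfig, seed: int = 0) -> RippleCnn:
    """Instantiate the detector with seeded Glorot-uniform weights."""
    return RippleCnn(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Loss and training
# ---------------------------------------------------------------------------

def bce_loss(y, p, eps: float = 1e-7) -> float:
    """Binary cross-entropy with soft labels (natural log).

    ``-(1/N) * sum(y*log p + (1-y)*log(1-p))`` with ``p`` clipped to
    ``(eps, 1-eps)``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class _Adam:
    def __init__(self, model, tcfg):
        self.tcfg = tcfg
        self.state = [
            (layer, name, is_kernel,
             np.zeros_like(layer.params[name]), np.zeros_like(layer.params[name]))
            for layer, name, is_kernel in model.parameters()
        ]
        self.t = 0

    def step(self, l2_lambda):
        c = self.tcfg
        self.t += 1
        for layer, name, is_kernel, m, v in self.state:
            g = layer.grads[name]
            if is_kernel and l2_lambda:
                g = g + 2.0 * l2_lambda * layer.params[name]
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1 ** self.t)
            vhat = v / (1 - c.beta2 ** self.t)
            layer.params[name] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.epsilon)


def train(model: RippleCnn, ds, tcfg: TrainingConfig):
    """Train on a :class:`~ripplekit.io.WindowedDataset`.

    The chunks are split 70/30 into train and development sets by a seeded
    shuffle; batches are whole chunks. Returns ``(model, history)`` where
    history maps ``"train"`` and ``"dev"`` to per-epoch loss lists (the train
    loss includes the L2 penalty). Raises on NaN loss.
    """
    expected_t = ds.X.shape[1] // model.cfg.stride_product
    if ds.Y.shape[1] != expected_t:
        raise ValueError(
            f"dataset has {ds.Y.shape[1]} windows per chunk but the "
            f"{model.cfg.variant} model emits {expected_t}")
    n = ds.n_chunks
    rng = np.random.default_rng(tcfg.seed)
    history = {"train": [], "dev": []}
    if tcfg.epochs == 0:
        return model, history
    if n >= 2:
        perm = rng.permutation(n)
        n_train = max(1, int(round(tcfg.train_fraction * n)))
        n_train = min(n_train, n - 1)
        train_idx, dev_idx = perm[:n_train], perm[n_train:]
    else:
        import warnings
        warnings.warn("single-chunk dataset: training without a dev split",
                      RuntimeWarning, stacklevel=2)
        train_idx, dev_idx = np.arange(n), np.arange(0)
    opt = _Adam(model, tcfg)
    lam = model.cfg.l2_lambda
    for _ in range(tcfg.epochs):
        order = rng.permutation(train_idx.size)
        losses = []
        for start in range(0, order.size, tcfg.batch_size):
            idx = train_idx[order[start:start + tcfg.batch_size]]
            xb = ds.X[idx].astype(np.float64)
            yb = ds.Y[idx].astype(np.float64)
            logits = model.forward(xb, training=True)
            p = _sigmoid(logits)
            loss = bce_loss(yb, p) + model.l2_penalty()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss became non-finite at step {opt.t}; reduce the "
                    "learning rate or inspect the input data")
            model.backward((p - yb) / p.size)
            opt.step(lam)
            losses.append(loss)
        history["train"].append(float(np.mean(losses)))
        if dev_idx.size:
            p_dev = model.predict_proba(ds.X[dev_idx].astype(np.float64))
            history["dev"].append(bce_loss(ds.Y[dev_idx], p_dev))
        else:
            history["dev"].append(float("nan"))
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(model: RippleCnn, rec: LfpRecording) -> ProbabilityTrace:
    """Offline probability trace over non-overlapping windows.

    The recording must be at 1250 Hz, 8 channels, already z-scored.
    """
    if abs(rec.fs - TARGET_FS) > 1e-9:
        raise ValueError(f"predict expects fs={TARGET_FS}")
    p = model.predict_proba(rec.data[None])[0, :, 0]
    return ProbabilityTrace(p=p, window_s=model.cfg.window_s, t0=0.0)


def stream_predict(
    model: RippleCnn, rec: LfpRecording, calibration_s: float = 60.0
) -> ProbabilityTrace:
    """Causal streaming simulation of the online detector (CNN12 only).

    Windows of 12.8 ms are evaluated every 6.4 ms (hop = half a window);
    z-scoring uses the mean/SD of the first ``calibration_s`` only, and each
    probability is emitted at the end of its window, so the output at time t
    depends only on samples at or before t.
    """
    if model.cfg.variant != "CNN12":
        raise ValueError("stream_predict requires the CNN12 variant")
    if rec.fs != TARGET_FS:
        rec = downsample(rec, TARGET_FS)
    n_cal = int(round(calibration_s * rec.fs))
    if n_cal > rec.n_samples:
        raise ValueError("calibration_s longer than the recording")
    mu = rec.data[:n_cal].mean(axis=0)
    sd = rec.data[:n_cal].std(axis=0)
    sd[sd == 0] = 1.0
    x = (rec.data - mu) / sd
    win = model.cfg.stride_product           # 16 samples
    hop = win // 2                           # 8 samples
    n_pos = (x.shape[0] - win) // hop + 1
    if n_pos <= 0:
        raise ValueError("recording shorter than one window")
    windows = np.lib.stride_tricks.sliding_window_view(x, win, axis=0)[::hop]
    windows = np.ascontiguousarray(np.swapaxes(windows, 1, 2))  # (n, win, ch)
    out = np.empty(n_pos)
    step = 65536
    for i in range(0, n_pos, step):
        out[i:i + step] = model.predict_proba(windows[i:i + step])[:, 0, 0]
    hop_s = hop / rec.fs
    return ProbabilityTrace(p=out, window_s=hop_s, t0=(win - hop) / rec.fs)


def extract_events(
    trace: ProbabilityTrace, thr_onset: float, thr_confirm: float,
    detector_id: str = "cnn",
) -> DetectionResult:
    """Dual-threshold event extraction.

    An event is a maximal run of consecutive windows with ``p >= thr_onset``
    that contains at least one window with ``p >= thr_confirm``; its interval
    is the run's time span. Runs without a confirming window are discarded.
    """
    if not 0 <= thr_onset <= thr_confirm <= 1:
        raise ValueError("require 0 <= thr_onset <= thr_confirm <= 1")
    p = trace.p
    above = p >= thr_onset
    intervals, peaks = [], []
    i, n = 0, p.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            seg = p[i:j + 1]
            if seg.max() >= thr_confirm:
                intervals.append([trace.t0 + i * trace.window_s,
                                  trace.t0 + (j + 1) * trace.window_s])
                peaks.append(float(seg.max()))
            i = j + 1
        else:
            i += 1
    events = EventSet(np.array(intervals) if intervals else np.empty((0, 2)),
                      label=detector_id)
    return DetectionResult(events=events, trace=trace,
                           thresholds=(thr_onset, thr_confirm),
                           detector_id=detector_id, peak_p=np.asarray(peaks))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: RippleCnn, path) -> None:
    """Write the architecture manifest (JSON) and weights (npz) to ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = model.cfg
    manifest = {
        "variant": cfg.variant,
        "kernel_sizes": list(cfg.kernel_sizes),
        "n_filters": list(cfg.n_filters),
        "leaky_relu_alpha": cfg.leaky_relu_alpha,
        "l2_lambda": cfg.l2_lambda,
        "n_input_channels": cfg.n_input_channels,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {}
    for i, (conv, bn, _) in enumerate(model.blocks):
        arrays[f"conv{i}_W"] = conv.params["W"]
        arrays[f"conv{i}_b"] = conv.params["b"]
        arrays[f"bn{i}_gamma"] = bn.params["gamma"]
        arrays[f"bn{i}_beta"] = bn.params["beta"]
        arrays[f"bn{i}_rmean"] = bn.running_mean
        arrays[f"bn{i}_rvar"] = bn.running_var
    arrays["dense_W"] = model.dense.params["W"]
    arrays["dense_b"] = model.dense.params["b"]
    np.savez(path / "weights.npz", **arrays)


def load_model(path) -> RippleCnn:
    """Rebuild a model saved by :func:`save_model` (bit-identical outputs)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg = ArchitectureConfig(
        variant=manifest["variant"],
        kernel_sizes=tuple(manifest["kernel_sizes"]),
        n_filters=tuple(manifest["n_filters"]),
        leaky_relu_alpha=manifest["leaky_relu_alpha"],
        l2_lambda=manifest["l2_lambda"],
        n_input_channels=manifest["n_input_channels"],
    )
    model = RippleCnn(cfg)
    with np.load(path / "weights.npz") as z:
        try:
            for i, (conv, bn, _) in enumerate(model.blocks):
                _load_into(conv.params, "W", z[f"conv{i}_W"])
                _load_into(conv.params, "b", z[f"conv{i}_b"])
                _load_into(bn.params, "gamma", z[f"bn{i}_gamma"])
                _load_into(bn.params, "beta", z[f"bn{i}_beta"])
                bn.running_mean = z[f"bn{i}_rmean"].copy()
                bn.running_var = z[f"bn{i}_rvar"].copy()
            _load_into(model.dense.params, "W", z["dense_W"])
            _load_into(model.dense.params, "b", z["dense_b"])
        except KeyError as exc:
            raise ValueError(f"weights file does not match manifest: {exc}")
    return model


def _load_into(params, name, arr):
    if params[name].shape != arr.shape:
        raise ValueError(
            f"shape mismatch for {name}: manifest {params[name].shape} "
            f"vs weights {arr.shape}")
    params[name] = arr.copy()
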
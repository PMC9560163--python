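"""Interpretability of the trained detector.

* Kernel saliency maps: the input patch that maximally activates a given
  kernel, found by gradient ascent in input space from a small random
  initialization (N(0, 0.01)), with SGD at learning rate 0.1 and momentum
  0.1, stopping when the mean squared change of the input falls below 1e-9
  or after 2000 iterations. The best input seen so far is tracked and
  returned, so the recorded activation history (the accepted steps) is
  monotone even though individual SGD steps may cross activation kinks.
* Feature maps: the concatenation of every conv block's kernel activations
  (fixed block -> kernel -> time order, post-ReLU by default) plus optionally
  the dense output, a fingerprint of one input window.
* Template matching: unnormalized sliding cross-correlation of a saliency
  map against an LFP window.
* 2-D embedding of feature maps with UMAP (default neighborhood parameters)
  for TP/FP/FN/TN overlays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .cnn import RippleCnn
from .io import LfpRecording
from .features import _band_envelope

__all__ = ["SaliencyMap", "FeatureMap", "saliency", "feature_map",
           "expected_feature_length", "template_match", "event_window",
           "embed"]


@dataclass
class SaliencyMap:
    layer_id: object            # 1..7 or "dense"
    kernel_id: int
    patch: np.ndarray           # channels x samples
    activation: float
    iterations: int
    converged: bool
    activation_history: np.ndarray


@dataclass
class FeatureMap:
    vector: np.ndarray
    layout: list                # (block, n_kernels, n_timesteps) per entry
    includes_dense: bool
    source_id: object = None


def saliency(model: RippleCnn, layer_id, kernel_id: int, seed: int = 0,
             lr: float = 0.1, momentum: float = 0.1, tol: float = 1e-9,
             max_iter: int = 2000) -> SaliencyMap:
    """Gradient-ascent preferred-input patch for one kernel.

    The input is an 8 x S patch (S = the stride product); the objective is
    the kernel activation averaged over its output time steps (the raw conv
    output; the pre-sigmoid unit for ``layer_id="dense"``). The returned
    patch is the best input encountered, so the activation history is
    non-decreasing. Vanishing gradients return a flagged, non-converged map.
    """
    rng = np.random.default_rng(seed)
    s = model.cfg.stride_product
    c = model.cfg.n_input_channels
    x = rng.normal(0.0, 0.01, size=(1, s, c))
    vel = np.zeros_like(x)
    obj, grad = model.input_gradient(x, layer_id, kernel_id)
    best_obj, best_x = obj, x.copy()
    history = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < 1e-12:
            break                         # vanishing gradient: flagged return
        vel = momentum * vel + lr * grad
        x = x + vel
        obj, grad = model.input_gradient(x, layer_id, kernel_id)
        if obj > best_obj:                # accepted step: a new best input
            best_obj, best_x = obj, x.copy()
            history.append(obj)
        if float(np.mean(vel ** 2)) < tol:
            converged = True
            break
    return SaliencyMap(
        layer_id=layer_id, kernel_id=kernel_id, patch=best_x[0].T.copy(),
        activation=float(best_obj), iterations=it, converged=converged,
        activation_history=np.asarray(history))


def expected_feature_length(cfg, n_samples: int, include_dense: bool = True) -> tuple:
    """Per-layer shape walk: ((block, n_kernels, T) entries, total length)."""
    layout = []
    t = n_samples
    for b, (k, f) in enumerate(zip(cfg.kernel_sizes, cfg.n_filters), start=1):
        t = t // k
        layout.append((b, f, t))
    total = sum(f * ti for _, f, ti in layout)
    if include_dense:
        layout.append(("dense", 1, t))
        total += t
    return layout, total


def feature_map(model: RippleCnn, window: np.ndarray,
                include_dense: bool = True, post_relu: bool = True,
                source_id=None) -> FeatureMap:
    """Concatenated kernel activations of one input window.

    ``window`` is channels x samples (or samples x channels); activations
    are flattened in (block, kernel, time) order, post-ReLU by default
    (``post_relu=False`` uses raw conv outputs). The vector length is
    validated against the architecture-derived formula at runtime.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("window must be 2-D")
    if w.shape[0] == model.cfg.n_input_channels and w.shape[1] != model.cfg.n_input_channels:
        w = w.T                                  # to (samples, channels)
    if w.shape[0] < model.cfg.stride_product:
        raise ValueError(
            f"window of {w.shape[0]} samples is shorter than the receptive "
            f"field ({model.cfg.stride_product} samples)")
    logits, conv_raw, post = model.forward(w[None], training=False, collect=True)
    acts = post if post_relu else conv_raw
    pieces, layout = [], []
    for b, a in enumerate(acts, start=1):
        arr = a[0]                               # (T, F)
        layout.append((b, arr.shape[1], arr.shape[0]))
        pieces.append(arr.T.ravel())             # kernel-major, then time
    if include_dense:
        out = logits[0, :, 0]
        layout.append(("dense", 1, out.size))
        pieces.append(out)
    vec = np.concatenate(pieces)
    _, total = expected_feature_length(model.cfg, w.shape[0], include_dense)
    if vec.size != total:
        raise AssertionError(
            f"feature-map length {vec.size} != architecture formula {total}")
    return FeatureMap(vector=vec, layout=layout, includes_dense=include_dense,
                      source_id=source_id)


def template_match(template: np.ndarray, window: np.ndarray):
    """Unnormalized sliding cross-correlation of a template against a window.

    Both arrays are channels x samples; at each lag the similarity is the
    sum over channels and samples of the elementwise product. Returns
    ``(trace, max_value, argmax_lag)`` with ``len(trace) =
    window_len - template_len + 1``.
    """
    t = np.asarray(template, dtype=np.float64)
    w = np.asarray(window, dtype=np.float64)
    if t.ndim != 2 or w.ndim != 2 or t.shape[0] != w.shape[0]:
        raise ValueError("template and window must share the channel axis")
    if t.shape[1] > w.shape[1]:
        raise ValueError("template longer than window")
    trace = _signal.correlate2d(w, t, mode="valid")[0]
    return trace, float(trace.max()), int(np.argmax(trace))


def event_window(rec: LfpRecording, event, channel: int,
                 width_s: float = 0.1, margin_s: float = 0.010):
    """100 ms z-scored window centered for template matching.

    The center is the LFP minimum on the pyramidal channel within
    ``margin_s`` of the ripple-envelope maximum inside the event. Returns
    ``(window, flag)`` with window shaped channels x samples (8 x 125 at
    1250 Hz); boundary truncation zero-pads with a flag.
    """
    s, e = float(event[0]), float(event[1])
    i0, i1 = int(round(s * rec.fs)), int(round(e * rec.fs))
    i0, i1 = max(i0, 0), min(i1, rec.n_samples)
    seg = rec.data[i0:i1, channel]
    if seg.size < 10:
        raise ValueError("event too short for windowing")
    env = _band_envelope(seg, rec.fs)
    peak = i0 + int(np.argmax(env))
    m = int(round(margin_s * rec.fs))
    lo = max(peak - m, 0)
    hi = min(peak + m + 1, rec.n_samples)
    center = lo + int(np.argmin(rec.data[lo:hi, channel]))
    n = int(round(width_s * rec.fs))
    w0 = center - n // 2
    out = np.zeros((n, rec.n_channels))
    lo2, hi2 = max(w0, 0), min(w0 + n, rec.n_samples)
    flag = "" if (lo2 == w0 and hi2 == w0 + n) else "zero-padded"
    out[lo2 - w0:hi2 - w0] = rec.data[lo2:hi2]
    mu = out.mean(axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return ((out - mu) / sd).T, flag


def embed(feature_maps, labels=None, seed: int = 42, n_neighbors: int = 15,
          min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP embedding of feature-map vectors (default parameters).

    ``feature_maps`` is an (n, d) array or a list of :class:`FeatureMap`.
    With fewer vectors than ``n_neighbors`` the neighborhood is reduced with
    a warning. Returns an (n, 2) coordinate array aligned with ``labels``.
    """
    import umap

    if isinstance(feature_maps, (list, tuple)) and feature_maps and \
            isinstance(feature_maps[0], FeatureMap):
        x = np.stack([fm.vector for fm in feature_maps])
    else:
        x = np.asarray(feature_maps, dtype=np.float64)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 vectors to embed")
    if x.shape[0] <= n_neighbors:
        warnings.warn(
            f"n_neighbors reduced from {n_neighbors} to {x.shape[0] - 1}",
            RuntimeWarning, stacklevel=2)
        n_neighbors = x.shape[0] - 1
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")    # umap warns about fixed seeds
        return np.asarray(reducer.fit_transform(x), dtype=np.float64)
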
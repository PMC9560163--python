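"""Butterworth-filter ripple detector (the spectral gold standard).

Offline pipeline on the 1250 Hz pyramidal-layer channel: zero-phase
second-order Butterworth band-pass (100-300 Hz), rectification with a fixed
gain, a fourth-order Savitzky-Golay smoothing pass, then two consecutive
moving averages (2.3 and 6.7 ms) giving the ripple envelope. Detection uses
two thresholds expressed in SD units of the envelope: a run of samples above
the first threshold defines the candidate beginning/end and the candidate is
kept only if it also reaches the second, higher threshold; kept detections
closer than 15 ms are merged. Thresholds are applied to the centered
envelope ((env - mean) / SD), which keeps the SD-unit semantics meaningful
for low multipliers and makes detection invariant to any constant gain.

The 4 x 15 = 60-combination grid search picks the (thr1, thr2) pair with the
best event-level F1 against a ground truth. The online variant thresholds
the causally filtered signal and discards events that co-occur on a veto
channel from outside the ripple band's source region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import EventSet, TARGET_FS
from . import evaluate as _evaluate

__all__ = ["FilterConfig", "bandpass", "envelope", "detect", "grid_search",
           "online_detect"]


@dataclass
class FilterConfig:
    band: tuple = (100.0, 300.0)
    order: int = 2
    zero_phase: bool = True
    gain: float = 2.0
    sg_order: int = 4
    sg_frame_s: float = 0.0088            # 11 samples at 1250 Hz (odd)
    movmean_windows_s: tuple = (0.0023, 0.0067)
    merge_gap_s: float = 0.015
    thr1_sd_candidates: tuple = (1.0, 1.5, 2.0, 2.5)
    thr2_sd_candidates: tuple = tuple(np.arange(3.0, 10.0 + 0.25, 0.5))

    def __post_init__(self):
        if not 0 < self.band[0] < self.band[1] < TARGET_FS / 2:
            raise ValueError("band must lie inside (0, fs/2)")
        if max(self.thr1_sd_candidates) >= min(self.thr2_sd_candidates):
            raise ValueError("all thr2 candidates must exceed all thr1 candidates")


def _sos(cfg: FilterConfig, fs: float):
    return signal.butter(cfg.order, cfg.band, btype="bandpass", fs=fs,
                         output="sos")


def bandpass(x: np.ndarray, fs: float = TARGET_FS,
             cfg: FilterConfig | None = None, causal: bool = False) -> np.ndarray:
    """Band-pass one channel; zero-phase (filtfilt) unless ``causal``."""
    cfg = cfg or FilterConfig()
    x = np.asarray(x, dtype=np.float64)
    sos = _sos(cfg, fs)
    if causal or not cfg.zero_phase:
        return signal.sosfilt(sos, x)
    padlen = 3 * (2 * cfg.order * 2 + 1)
    if x.size <= padlen:
        raise ValueError(
            f"signal of {x.size} samples is shorter than the filter warm-up "
            f"({padlen} samples)")
    return signal.sosfiltfilt(sos, x)


def _movmean(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def envelope(filtered: np.ndarray, fs: float = TARGET_FS,
             cfg: FilterConfig | None = None) -> np.ndarray:
    """Smoothed rectified amplitude of the band-passed signal.

    Rectify and amplify, Savitzky-Golay smooth (order 4), then two moving
    averages (2.3 and 6.7 ms); a final rectification keeps the envelope
    non-negative. Constant gains cancel in SD-unit thresholds.
    """
    cfg = cfg or FilterConfig()
    e = np.abs(np.asarray(filtered, dtype=np.float64)) * cfg.gain
    frame = int(round(cfg.sg_frame_s * fs))
    if frame % 2 == 0:
        frame += 1
    frame = max(frame, cfg.sg_order + 1 + ((cfg.sg_order + 1) % 2 == 0))
    if e.size > frame:
        e = signal.savgol_filter(e, frame, cfg.sg_order)
    for w in cfg.movmean_windows_s:
        e = _movmean(e, max(1, int(round(w * fs))))
    return np.clip(e, 0.0, None)


def _runs(mask: np.ndarray):
    """Start/stop index pairs (half-open) of True runs."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return np.column_stack([starts, stops])


def detect(env: np.ndarray, thr1_sd: float, thr2_sd: float,
           fs: float = TARGET_FS, cfg: FilterConfig | None = None,
           center: float | None = None, sd: float | None = None) -> EventSet:
    """Dual SD-threshold detection on an envelope.

    A candidate is a maximal run with centered envelope >= ``thr1_sd`` SD;
    it is kept iff its maximum reaches ``thr2_sd`` SD. Kept events with gaps
    shorter than 15 ms are merged. ``center``/``sd`` default to the whole
    envelope's mean/SD (pass calibration-prefix statistics for online use).
    """
    if thr1_sd >= thr2_sd:
        raise ValueError("thr1_sd must be smaller than thr2_sd")
    cfg = cfg or FilterConfig()
    env = np.asarray(env, dtype=np.float64)
    mu = env.mean() if center is None else center
    sigma = env.std() if sd is None else sd
    if sigma == 0:
        return EventSet(np.empty((0, 2)), label="filter")
    z = (env - mu) / sigma
    events = []
    for i, j in _runs(z >= thr1_sd):
        if z[i:j].max() >= thr2_sd:
            events.append([i / fs, j / fs])
    return EventSet(_merge_gaps(np.asarray(events).reshape(-1, 2),
                                cfg.merge_gap_s), label="filter")


def _merge_gaps(intervals: np.ndarray, gap_s: float) -> np.ndarray:
    if intervals.shape[0] == 0:
        return intervals
    merged = [intervals[0].copy()]
    for s, e in intervals[1:]:
        if s - merged[-1][1] < gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.asarray(merged)


def grid_search(env: np.ndarray, truth: EventSet, fs: float = TARGET_FS,
                cfg: FilterConfig | None = None, window_s: float = 0.032,
                duration_s: float | None = None):
    """Evaluate all thr1 x thr2 candidate pairs; return the best pair + table.

    The best pair maximizes event-level F1 (IoU >= 0.1 matching); ties break
    toward the higher thr2, then the higher thr1. Returns
    ``((thr1, thr2), table)`` with one row per combination.
    """
    if len(truth) == 0:
        raise ValueError("grid_search requires a non-empty ground truth")
    cfg = cfg or FilterConfig()
    duration = duration_s if duration_s is not None else env.size / fs
    rows = []
    for t1 in cfg.thr1_sd_candidates:
        for t2 in cfg.thr2_sd_candidates:
            pred = detect(env, t1, t2, fs=fs, cfg=cfg)
            counts = _evaluate.match(pred, truth, window_s=window_s,
                                     duration_s=duration)
            m = _evaluate.metrics(counts)
            rows.append({"thr1_sd": t1, "thr2_sd": t2,
                         "precision": m.precision, "recall": m.recall,
                         "f1": m.f1, "n_pred": len(pred)})
    table = pd.DataFrame(rows)
    best = table.sort_values(["f1", "thr2_sd", "thr1_sd"],
                             ascending=[False, False, False]).iloc[0]
    return (float(best["thr1_sd"]), float(best["thr2_sd"])), table


def online_detect(ripple_channel: np.ndarray, veto_channel: np.ndarray,
                  thr_sd: float, fs: float = TARGET_FS,
                  cfg: FilterConfig | None = None,
                  calibration_s: float = 60.0) -> EventSet:
    """Single-threshold causal detection with a veto channel.

    Both channels are causally band-passed; runs where the rectified filtered
    signal exceeds ``thr_sd`` times its calibration-prefix SD are events,
    merged with the 15 ms rule. Any ripple-channel event overlapping a
    same-rule event on the veto channel is discarded (broadband artifacts hit
    both channels; genuine ripples do not).
    """
    cfg = cfg or FilterConfig()
    ripple_channel = np.asarray(ripple_channel, dtype=np.float64)
    veto_channel = np.asarray(veto_channel, dtype=np.float64)
    if ripple_channel.shape != veto_channel.shape:
        raise ValueError("ripple and veto channels must have the same length")
    n_cal = min(int(round(calibration_s * fs)), ripple_channel.size)

    def _single(x):
        f = bandpass(x, fs=fs, cfg=cfg, causal=True)
        sd = f[:n_cal].std()
        if sd == 0:
            return EventSet(np.empty((0, 2)))
        mask = np.abs(f) >= thr_sd * sd
        iv = np.array([[i / fs, j / fs] for i, j in _runs(mask)]).reshape(-1, 2)
        return EventSet(_merge_gaps(iv, cfg.merge_gap_s))

    ripple_ev = _single(ripple_channel)
    veto_ev = _single(veto_channel)
    if len(veto_ev) == 0:
        return EventSet(ripple_ev.intervals, label="filter-online")
    keep = [iv for iv in ripple_ev
            if not np.any(veto_ev.overlaps(iv[0], iv[1]))]
    return EventSet(np.array(keep).reshape(-1, 2), label="filter-online")
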
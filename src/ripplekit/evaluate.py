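"""Event-level scoring of ripple detections.

Predictions and ground truth are interval sets; a prediction matches a truth
event when their intersection-over-union is at least 0.1. Matching is greedy
in descending IoU with each prediction and each truth event used at most
once, so several predictions cannot double-count a single truth event (TP is
counted per matched truth). True negatives are only countable at window
resolution: they are the fixed-length windows overlapping neither set.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = harmonic mean; 0/0 cases
return 0 with an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventSet

__all__ = ["MatchCounts", "DetectionMetrics", "iou", "match", "metrics",
           "sweep_thresholds", "time_to_peak", "agreement"]

IOU_MIN = 0.1


@dataclass
class MatchCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    matched_pairs: list = field(default_factory=list)  # (pred_idx, truth_idx)


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    undefined: bool = False    # flagged when any 0/0 convention was applied


def iou(a, b) -> float:
    """Intersection over union of two half-open intervals.

    Zero-length intervals give 0 by convention.
    """
    a0, a1 = a
    b0, b1 = b
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union if union > 0 else 0.0


def _iou_matrix(pred: EventSet, truth: EventSet) -> np.ndarray:
    if len(pred) == 0 or len(truth) == 0:
        return np.zeros((len(pred), len(truth)))
    ps, pe = pred.starts[:, None], pred.ends[:, None]
    ts, te = truth.starts[None, :], truth.ends[None, :]
    inter = np.clip(np.minimum(pe, te) - np.maximum(ps, ts), 0.0, None)
    union = (pe - ps) + (te - ts) - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(union > 0, inter / union, 0.0)
    return m


def match(pred: EventSet, truth: EventSet, iou_min: float = IOU_MIN,
          window_s: float = 0.032, duration_s: float | None = None) -> MatchCounts:
    """Greedy one-to-one IoU matching of predictions against ground truth.

    Unmatched predictions are FP, unmatched truth events FN. TN is the count
    of ``window_s`` windows over ``[0, duration_s)`` overlapping neither set
    (``duration_s`` defaults to the latest interval end).
    """
    m = _iou_matrix(pred, truth)
    pairs = []
    if m.size:
        cand = np.argwhere(m >= iou_min)
        order = np.argsort(-m[cand[:, 0], cand[:, 1]], kind="stable")
        used_p, used_t = set(), set()
        for pi, ti in cand[order]:
            if pi not in used_p and ti not in used_t:
                pairs.append((int(pi), int(ti)))
                used_p.add(int(pi))
                used_t.add(int(ti))
    tp = len(pairs)
    fp = len(pred) - tp
    fn = len(truth) - tp
    if duration_s is None:
        ends = [iv[1] for s in (pred, truth) for iv in s]
        duration_s = max(ends) if ends else 0.0
    n_windows = int(np.floor(duration_s / window_s))
    edges = np.arange(n_windows + 1) * window_s
    occupied = np.zeros(n_windows, dtype=bool)
    for s in (pred, truth):
        for a, b in s:
            lo = max(0, int(np.floor(a / window_s)))
            hi = min(n_windows, int(np.ceil(b / window_s)))
            occupied[lo:hi] = True
    tn = int(n_windows - occupied.sum())
    return MatchCounts(TP=tp, FP=fp, FN=fn, TN=tn, matched_pairs=pairs)


def metrics(c: MatchCounts) -> DetectionMetrics:
    """Precision, recall and F1 from match counts (0/0 -> 0, flagged)."""
    undefined = False
    if c.TP + c.FP > 0:
        p = c.TP / (c.TP + c.FP)
    else:
        p, undefined = 0.0, True
    if c.TP + c.FN > 0:
        r = c.TP / (c.TP + c.FN)
    else:
        r, undefined = 0.0, True
    if p + r > 0:
        f1 = 2 * p * r / (p + r)
    else:
        f1, undefined = 0.0, True
    return DetectionMetrics(precision=p, recall=r, f1=f1, undefined=undefined)


#: The candidate dual-threshold grid for the CNN (15 onset x 8 confirm).
CNN_ONSET_CANDIDATES = (0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50, 0.45,
                        0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10)
CNN_CONFIRM_CANDIDATES = (0.80, 0.70, 0.60, 0.50, 0.40, 0.30, 0.20, 0.10)


def sweep_thresholds(detect_fn, grid, truth: EventSet,
                     window_s: float = 0.032,
                     duration_s: float | None = None):
    """Score a detector over a threshold grid; return the best entry + table.

    ``detect_fn(thresholds)`` must return an :class:`EventSet` (or an object
    with an ``events`` attribute) for one grid entry; ``grid`` is an iterable
    of threshold tuples (or scalars). Returns ``(best_thresholds, table)``
    where the table carries per-entry P/R/F1 and a normalized-threshold axis
    (entry's last threshold divided by the best entry's) for robustness
    curves. Invalid entries (e.g. onset > confirm) are skipped.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    rows = []
    for thr in grid:
        try:
            result = detect_fn(thr)
        except ValueError:
            continue
        events = getattr(result, "events", result)
        m = metrics(match(events, truth, window_s=window_s,
                          duration_s=duration_s))
        thr_t = thr if isinstance(thr, tuple) else (thr,)
        rows.append({"thresholds": thr_t, "threshold": float(thr_t[-1]),
                     "precision": m.precision, "recall": m.recall, "f1": m.f1})
    if not rows:
        raise ValueError("no valid grid entries")
    table = pd.DataFrame(rows)
    best_i = int(table.sort_values(["f1", "threshold"],
                                   ascending=[False, False]).index[0])
    best_thr = table.loc[best_i, "thresholds"]
    table["normalized_threshold"] = table["threshold"] / table.loc[best_i, "threshold"]
    return best_thr, table


def time_to_peak(det, truth: EventSet, rec, channel: int,
                 iou_min: float = IOU_MIN, window_s: float = 0.032):
    """Per-event latency (ms) between detection onset and the ripple peak.

    For every matched (prediction, truth) pair, latency = detection start
    minus the ripple-envelope peak time of the truth event; negative values
    mean the detector anticipated the peak. Returns ``(latencies_ms,
    (mean, sd))``; unmatched events are skipped.
    """
    from .features import ripple_peak

    events = getattr(det, "events", det)
    counts = match(events, truth, iou_min=iou_min, window_s=window_s,
                   duration_s=rec.duration_s)
    lat = []
    for pi, ti in counts.matched_pairs:
        try:
            peak = ripple_peak(rec, truth[ti], channel=channel)
        except ValueError:
            continue
        lat.append((events[pi][0] - peak) * 1000.0)
    lat = np.asarray(lat)
    if lat.size:
        return lat, (float(lat.mean()), float(lat.std()))
    return lat, (float("nan"), float("nan"))


def agreement(truth_a: EventSet, truth_b: EventSet, iou_min: float = IOU_MIN,
              window_s: float = 0.032, duration_s: float | None = None):
    """Inter-annotator agreement: each set scored against the other.

    Returns ``(metrics_a_vs_b, metrics_b_vs_a)``; with one-to-one matching
    the two F1 values coincide.
    """
    ab = metrics(match(truth_a, truth_b, iou_min=iou_min, window_s=window_s,
                       duration_s=duration_s))
    ba = metrics(match(truth_b, truth_a, iou_min=iou_min, window_s=window_s,
                       duration_s=duration_s))
    return ab, ba
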
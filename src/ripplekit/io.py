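"""Reading, writing and preparation of multichannel LFP data.

Containers
----------
:class:`LfpRecording`
    A samples x channels voltage matrix with its sampling rate and per-channel
    geometry (depth along the probe, optional CA1 layer label).
:class:`EventSet`
    An ordered, disjoint set of half-open time intervals ``[start_s, end_s)``
    (ground-truth ripple annotations or detector output).
:class:`WindowedDataset`
    The chunked training tensors: ``X`` (chunks x samples x channels) and soft
    labels ``Y`` (chunks x windows x 1), where each label is the fraction of the
    window occupied by an annotated event.

On-disk formats: channel-interleaved little-endian int16 with a JSON sidecar,
or an HDF5 dataset ``"lfp"`` carrying the same attributes; events as two-column
CSV in seconds; datasets as HDF5 groups.

Conventions: intervals are half-open ``[start, end)`` in seconds, sample
indexing is 0-based, channels are ordered top (dorsal) to bottom (ventral).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger("ripplekit")

#: Working sampling rate of the whole pipeline (Hz).
TARGET_FS = 1250.0
#: Default chunk length in seconds; divisible by both window lengths.
CHUNK_S = 57.6
#: The two supported detector window lengths (seconds).
WINDOW_32 = 0.032
WINDOW_12 = 0.0128

LAYERS = ("SO", "SP", "SR", "SLM", "other")


# ---------------------------------------------------------------------------
# LfpRecording
# ---------------------------------------------------------------------------

@dataclass
class LfpRecording:
    """Multichannel extracellular recording.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_channels)``; microvolts or z-units.
    fs
        Sampling rate in Hz.
    channel_depths_um
        Per-channel depth along the probe (µm, increasing downward). Optional.
    layer_labels
        Per-channel CA1 layer label (``SO``/``SP``/``SR``/``SLM``/``other``).
    gain_uv_per_bit
        Quantization step used when the recording is written as int16.
    """

    data: np.ndarray
    fs: float
    channel_depths_um: np.ndarray | None = None
    layer_labels: list[str] | None = None
    gain_uv_per_bit: float = 0.195

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples, channels)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.channel_depths_um is not None:
            self.channel_depths_um = np.asarray(self.channel_depths_um, float)
            if self.channel_depths_um.size != self.n_channels:
                raise ValueError("channel_depths_um length mismatch")
        if self.layer_labels is not None and len(self.layer_labels) != self.n_channels:
            raise ValueError("layer_labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select(self, channels: "np.ndarray | list[int]") -> "LfpRecording":
        """Return a new recording restricted to ``channels`` (in given order)."""
        channels = list(channels)
        return LfpRecording(
            data=self.data[:, channels],
            fs=self.fs,
            channel_depths_um=None if self.channel_depths_um is None
            else self.channel_depths_um[channels],
            layer_labels=None if self.layer_labels is None
            else [self.layer_labels[c] for c in channels],
            gain_uv_per_bit=self.gain_uv_per_bit,
        )


# ---------------------------------------------------------------------------
# EventSet
# ---------------------------------------------------------------------------

class EventSet:
    """Ordered, disjoint set of half-open intervals ``[start_s, end_s)``.

    Overlapping or touching input intervals are merged at construction time,
    so an ``EventSet`` is always sorted and pairwise disjoint.
    """

    def __init__(self, intervals, label: str = ""):
        arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
        if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("every interval must satisfy start < end")
        self.intervals = _merge_sorted(arr)
        self.label = label

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"EventSet(n={len(self)}, label={self.label!r})"

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def overlaps(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of events overlapping ``[start, end)``."""
        return (self.starts < end) & (self.ends > start)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.intervals, columns=["start_s", "end_s"])
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "EventSet":
        df = pd.read_csv(path)
        return cls(df[["start_s", "end_s"]].to_numpy(), label=label)


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.array(merged).reshape(-1, 2)


# ---------------------------------------------------------------------------
# WindowedDataset
# ---------------------------------------------------------------------------

@dataclass
class WindowedDataset:
    """Chunked input tensor ``X`` and soft-label tensor ``Y``.

    ``X`` has shape ``(n_chunks, chunk_samples, n_channels)`` and ``Y`` has
    shape ``(n_chunks, windows_per_chunk, 1)`` with values in ``[0, 1]``.
    """

    X: np.ndarray
    Y: np.ndarray
    window_s: float
    chunk_s: float = CHUNK_S
    fs: float = TARGET_FS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.Y = np.asarray(self.Y, dtype=np.float32)
        n_win = self.chunk_s / self.window_s
        if abs(n_win - round(n_win)) > 1e-9:
            raise ValueError("window_s must divide chunk_s exactly")
        if self.X.shape[1] != round(self.chunk_s * self.fs):
            raise ValueError("chunk sample count inconsistent with chunk_s * fs")
        if self.Y.shape[:2] != (self.X.shape[0], round(n_win)):
            raise ValueError("Y shape inconsistent with X and window_s")
        if self.Y.size and (self.Y.min() < 0 or self.Y.max() > 1):
            raise ValueError("labels must lie in [0, 1]")

    @property
    def n_chunks(self) -> int:
        return self.X.shape[0]

    @property
    def windows_per_chunk(self) -> int:
        return self.Y.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("Y", data=self.Y)
            f.attrs["window_s"] = self.window_s
            f.attrs["chunk_s"] = self.chunk_s
            f.attrs["fs"] = self.fs

    @classmethod
    def from_hdf5(cls, path) -> "WindowedDataset":
        with h5py.File(path, "r") as f:
            return cls(
                X=f["X"][...], Y=f["Y"][...],
                window_s=float(f.attrs["window_s"]),
                chunk_s=float(f.attrs["chunk_s"]),
                fs=float(f.attrs["fs"]),
            )


# ---------------------------------------------------------------------------
# Recording file formats
# ---------------------------------------------------------------------------

def write_lfp(rec: LfpRecording, path, format: str = "binary") -> None:
    """Write a recording as int16 binary + JSON sidecar or as HDF5.

    ``binary``: channel-interleaved little-endian int16 at ``path`` plus a
    sidecar ``path + ".json"``. ``hdf5``: dataset ``"lfp"`` with attributes.
    Voltages are quantized by ``rec.gain_uv_per_bit``.
    """
    path = Path(path)
    quant = np.clip(np.round(rec.data / rec.gain_uv_per_bit), -32768, 32767)
    payload = quant.astype("<i2")
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "gain_uV_per_bit": rec.gain_uv_per_bit,
        "spacing_um": _spacing_from_depths(rec.channel_depths_um),
        "depths_um": None if rec.channel_depths_um is None
        else rec.channel_depths_um.tolist(),
        "layer_labels": rec.layer_labels,
    }
    if format == "binary":
        payload.tofile(path)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("lfp", data=payload)
            for k, v in meta.items():
                if v is not None:
                    d.attrs[k] = json.dumps(v) if isinstance(v, (list, dict)) else v
    else:
        raise ValueError(f"unknown format {format!r}")


def read_lfp(path, format: str = "binary") -> LfpRecording:
    """Read a recording written by :func:`write_lfp`.

    Raises a ``ValueError`` naming both counts when the payload size is not a
    multiple of the sidecar's channel count.
    """
    path = Path(path)
    if format == "binary":
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = np.fromfile(path, dtype="<i2")
        n_ch = int(meta["n_channels"])
        if raw.size % n_ch:
            raise ValueError(
                f"payload has {raw.size} values, not divisible by the sidecar's "
                f"{n_ch} channels"
            )
        data = raw.reshape(-1, n_ch).astype(np.float64) * meta["gain_uV_per_bit"]
        depths = meta.get("depths_um")
        return LfpRecording(
            data=data, fs=float(meta["fs"]),
            channel_depths_um=None if depths is None else np.asarray(depths),
            layer_labels=meta.get("layer_labels"),
            gain_uv_per_bit=float(meta["gain_uV_per_bit"]),
        )
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            d = f["lfp"]
            gain = float(d.attrs["gain_uV_per_bit"])
            data = d[...].astype(np.float64) * gain
            depths = d.attrs.get("depths_um")
            labels = d.attrs.get("layer_labels")
            return LfpRecording(
                data=data, fs=float(d.attrs["fs"]),
                channel_depths_um=None if depths is None
                else np.asarray(json.loads(depths)),
                layer_labels=None if labels is None else json.loads(labels),
                gain_uv_per_bit=gain,
            )
    else:
        raise ValueError(f"unknown format {format!r}")


def _spacing_from_depths(depths) -> float | None:
    if depths is None or len(depths) < 2:
        return None
    diffs = np.diff(np.asarray(depths, float))
    return float(diffs[0]) if np.allclose(diffs, diffs[0]) else None


# ---------------------------------------------------------------------------
# Preparation pipeline
# ---------------------------------------------------------------------------

def downsample(rec: LfpRecording, target_fs: float = TARGET_FS) -> LfpRecording:
    """Anti-aliased integer-factor decimation to ``target_fs``.

    A zero-phase 8th-order Butterworth low-pass at ``0.4 * target_fs`` is
    applied before taking every q-th sample. The source rate must be an
    integer multiple of ``target_fs``; resample externally otherwise.
    """
    if rec.fs < target_fs:
        raise ValueError("cannot downsample: fs below target")
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs {rec.fs} is not an integer multiple of {target_fs}; "
            "resample externally before downsampling"
        )
    q = int(round(ratio))
    if q == 1:
        return rec
    sos = signal.butter(8, 0.4 * target_fs, btype="low", fs=rec.fs, output="sos")
    low = signal.sosfiltfilt(sos, rec.data, axis=0)
    return LfpRecording(
        data=low[::q], fs=target_fs,
        channel_depths_um=rec.channel_depths_um,
        layer_labels=rec.layer_labels,
        gain_uv_per_bit=rec.gain_uv_per_bit,
    )


def zscore(rec: LfpRecording) -> LfpRecording:
    """Per-channel z-score over the whole session.

    Constant channels map to all-zeros with a warning.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    mu = rec.data.mean(axis=0)
    sd = rec.data.std(axis=0)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant channel(s) z-scored to zeros",
            RuntimeWarning, stacklevel=2,
        )
    sd_safe = np.where(flat, 1.0, sd)
    return LfpRecording(
        data=(rec.data - mu) / sd_safe, fs=rec.fs,
        channel_depths_um=rec.channel_depths_um,
        layer_labels=rec.layer_labels,
        gain_uv_per_bit=rec.gain_uv_per_bit,
    )


def slice_chunks(rec: LfpRecording, chunk_s: float = CHUNK_S) -> np.ndarray:
    """Slice a 1250 Hz recording into fixed-length chunks.

    Returns an array of shape ``(n_chunks, chunk_samples, n_channels)``.
    The trailing remainder shorter than one chunk is dropped (logged).
    """
    if abs(rec.fs - TARGET_FS) > 1e-9:
        raise ValueError(f"slice_chunks expects fs={TARGET_FS}, got {rec.fs}")
    chunk_samples = round(chunk_s * rec.fs)
    n_chunks = rec.n_samples // chunk_samples
    if n_chunks == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{chunk_s} s chunk; pass a smaller chunk_s for short tests"
        )
    dropped = rec.n_samples - n_chunks * chunk_samples
    if dropped:
        logger.info("slice_chunks: dropped %d trailing samples", dropped)
    used = rec.data[: n_chunks * chunk_samples]
    return used.reshape(n_chunks, chunk_samples, rec.n_channels)


def build_labels(
    n_chunks: int,
    events: EventSet,
    window_s: float,
    chunk_s: float = CHUNK_S,
    fs: float = TARGET_FS,
    session_duration_s: float | None = None,
) -> np.ndarray:
    """Soft labels: fraction of each window covered by annotated events.

    Returns ``Y`` of shape ``(n_chunks, windows_per_chunk, 1)``. Event time
    overlapping window ``w`` of chunk ``c`` is summed over events and divided
    by ``window_s``; values are clipped to 1. Events entirely outside the
    chunked span are ignored with a warning.
    """
    n_win = chunk_s / window_s
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("window_s must divide chunk_s exactly")
    n_win = round(n_win)
    total = n_chunks * n_win
    # window edges over the whole chunked span, in seconds
    edges = np.arange(total + 1) * window_s
    occupancy = np.zeros(total)
    span_end = n_chunks * chunk_s
    outside = 0
    for s, e in events:
        if e <= 0 or s >= span_end:
            outside += 1
            continue
        lo = np.clip(edges[:-1], s, e)
        hi = np.clip(edges[1:], s, e)
        occupancy += hi - lo
    if outside:
        warnings.warn(
            f"{outside} event(s) outside the chunked span ignored",
            RuntimeWarning, stacklevel=2,
        )
    y = np.clip(occupancy / window_s, 0.0, 1.0)
    return y.reshape(n_chunks, n_win, 1)


def prepare_dataset(
    rec: LfpRecording,
    events: EventSet,
    window_s: float = WINDOW_32,
    chunk_s: float = CHUNK_S,
    drop_empty: bool = False,
) -> WindowedDataset:
    """Full preparation: downsample -> z-score -> chunk -> soft labels.

    With ``drop_empty=True`` chunks containing no annotated event time are
    discarded; by default all chunks are retained.
    """
    if rec.fs != TARGET_FS:
        rec = downsample(rec, TARGET_FS)
    rec = zscore(rec)
    chunks = slice_chunks(rec, chunk_s=chunk_s)
    y = build_labels(chunks.shape[0], events, window_s, chunk_s=chunk_s, fs=rec.fs)
    if drop_empty:
        keep = y.sum(axis=(1, 2)) > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("prepare_dataset: dropped %d empty chunk(s)", n_drop)
        chunks, y = chunks[keep], y[keep]
    return WindowedDataset(X=chunks, Y=y, window_s=window_s, chunk_s=chunk_s, fs=rec.fs)


def select_channels(
    rec: LfpRecording, n: int = 8, priority_layer: str = "SP", seed: int | None = 0
) -> list[int]:
    """Choose ``n`` channels, preferring those in ``priority_layer``.

    All channels labelled ``priority_layer`` are included first (truncated in
    depth order if more than ``n``); the remainder is drawn uniformly without
    replacement with the given seed. The result is sorted by depth (or by
    channel index when depths are absent).
    """
    if rec.n_channels < n:
        raise ValueError(f"recording has {rec.n_channels} channels, need {n}")
    labels = rec.layer_labels or ["other"] * rec.n_channels
    depths = (rec.channel_depths_um if rec.channel_depths_um is not None
              else np.arange(rec.n_channels, dtype=float))
    order = np.argsort(depths, kind="stable")
    priority = [int(i) for i in order if labels[i] == priority_layer][:n]
    rest = [int(i) for i in order if int(i) not in priority]
    rng = np.random.default_rng(seed)
    extra = rng.choice(len(rest), size=n - len(priority), replace=False)
    chosen = priority + [rest[i] for i in sorted(extra)]
    return sorted(chosen, key=lambda i: (depths[i], i))
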
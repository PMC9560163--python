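"""Per-event spectral characterization of sharp-wave ripples.

All features are computed on a 100 ms window (125 samples at 1250 Hz)
centered on the event at the pyramidal-layer channel:

* ripple-envelope peak time (70-400 Hz band, third-order Butterworth,
  Savitzky-Golay smoothing plus 3 and 6.5 ms moving averages),
* preferred frequency: argmax of the 70-400 Hz periodogram after subtracting
  a fitted exponential decay ``a * exp(b f)`` (1/f correction),
* <100 Hz contribution: fraction of total (uncorrected) power below 100 Hz,
* spectral entropy: ``-sum p_f log2 p_f`` of the normalized power spectrum.

The periodogram of a 125-sample window has a 10 Hz frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .io import EventSet, LfpRecording, TARGET_FS

__all__ = ["PowerSpectrum", "SwrFeatureSet", "ripple_peak", "spectrum",
           "preferred_frequency", "low_freq_fraction", "spectral_entropy",
           "characterize_events"]

PEAK_BAND = (70.0, 400.0)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False
    flag: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def normalize(self) -> "PowerSpectrum":
        total = self.power.sum()
        if total == 0:
            return PowerSpectrum(self.freqs, self.power, normalized=True,
                                 flag="zero-power")
        return PowerSpectrum(self.freqs, self.power / total, normalized=True,
                             flag=self.flag)


@dataclass
class SwrFeatureSet:
    peak_time_s: float
    preferred_freq_hz: float
    low_freq_fraction: float
    entropy_bits: float
    flags: str = ""


def _band_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """70-400 Hz envelope used for ripple-peak localization."""
    sos = signal.butter(3, PEAK_BAND, btype="bandpass", fs=fs, output="sos")
    f = signal.sosfiltfilt(sos, x)
    e = np.abs(f)
    frame = 11  # odd SG frame covering ~9 ms at 1250 Hz
    if e.size > frame:
        e = signal.savgol_filter(e, frame, 4)
    for w_s in (0.003, 0.0065):
        n = max(1, int(round(w_s * fs)))
        e = np.convolve(e, np.ones(n) / n, mode="same")
    return np.clip(e, 0.0, None)


def ripple_peak(rec: LfpRecording, event, channel: int,
                margin_s: float = 0.010) -> float:
    """Time (s) of the ripple-envelope maximum within ``event`` +- margin.

    Raises ``ValueError`` when the segment carries no ripple-band power
    (e.g. pure DC input). Windows extending past the recording edge are
    truncated with a warning.
    """
    import warnings

    s, e = float(event[0]), float(event[1])
    i0 = int(round((s - margin_s) * rec.fs))
    i1 = int(round((e + margin_s) * rec.fs))
    if i0 < 0 or i1 > rec.n_samples:
        warnings.warn("event at recording edge: window truncated",
                      RuntimeWarning, stacklevel=2)
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
    seg = rec.data[i0:i1, channel]
    if seg.size < 20:
        raise ValueError("event segment too short for peak localization")
    env = _band_envelope(seg, rec.fs)
    if env.max() <= 1e-12:
        raise ValueError("no ripple-band power within the event")
    return (i0 + int(np.argmax(env))) / rec.fs


def spectrum(rec: LfpRecording, event, channel: int,
             window_s: float = 0.1, band: tuple | None = None) -> PowerSpectrum:
    """Periodogram of a ``window_s`` window around the event center.

    With ``band`` set, the segment is band-pass filtered first (used with
    70-400 Hz for the preferred-frequency estimate). Windows that exceed the
    recording bounds are zero-padded and flagged. Power is the unnormalized
    magnitude-squared DFT (Parseval: sum equals window energy).
    """
    center = 0.5 * (float(event[0]) + float(event[1]))
    n = int(round(window_s * rec.fs))
    i0 = int(round(center * rec.fs)) - n // 2
    seg = np.zeros(n)
    lo, hi = max(i0, 0), min(i0 + n, rec.n_samples)
    flag = "" if (lo == i0 and hi == i0 + n) else "zero-padded"
    seg[lo - i0:hi - i0] = rec.data[lo:hi, channel]
    if band is not None:
        sos = signal.butter(3, band, btype="bandpass", fs=rec.fs, output="sos")
        seg = signal.sosfiltfilt(sos, seg)
    spec = np.fft.rfft(seg)
    power = np.abs(spec) ** 2 / n
    # fold negative frequencies so that sum(power) = sum(seg**2) (Parseval)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    if power.sum() == 0:
        flag = (flag + ";" if flag else "") + "zero-power"
    return PowerSpectrum(freqs=freqs, power=power, flag=flag)


def preferred_frequency(ps: PowerSpectrum, band: tuple = PEAK_BAND):
    """Ripple frequency after exponential-decay correction.

    Fits ``a * exp(b f)`` to the in-band power by least squares (log-linear
    start, nonlinear refinement) and returns the frequency of the maximal
    positive residual. Falls back to the raw argmax (flagged) when the fit
    fails or the residual has no positive excursion. Returns ``(freq_hz,
    flag)``.
    """
    mask = (ps.freqs >= band[0]) & (ps.freqs <= band[1])
    f = ps.freqs[mask]
    p = ps.power[mask]
    if f.size == 0 or p.max() == 0:
        return float("nan"), "empty-band"
    raw = float(f[np.argmax(p)])
    pos = p > 0
    if pos.sum() < 3:
        return raw, "fallback-raw"
    try:
        # log-linear initialization on the positive bins
        slope, intercept = np.polyfit(f[pos], np.log(p[pos]), 1)
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * np.exp(b * x), f, p,
            p0=(np.exp(intercept), slope), maxfev=5000)
        fit = popt[0] * np.exp(popt[1] * f)
    except (RuntimeError, TypeError, ValueError):
        return raw, "fallback-raw"
    resid = p - fit
    if resid.max() <= 0:
        return raw, "fallback-raw"
    return float(f[np.argmax(resid)]), ""


def low_freq_fraction(ps: PowerSpectrum, cutoff_hz: float = 100.0):
    """Fraction of total (uncorrected) power below ``cutoff_hz``.

    Returns ``(fraction, flag)``; zero total power gives 0 with a flag.
    """
    total = ps.power.sum()
    if total == 0:
        return 0.0, "zero-power"
    return float(ps.power[ps.freqs < cutoff_hz].sum() / total), ""


def spectral_entropy(ps: PowerSpectrum) -> float:
    """Shannon entropy (bits) of the normalized power spectrum.

    Zero bins contribute 0 by the 0*log(0) = 0 convention.
    """
    p = ps.power if ps.normalized else ps.normalize().power
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def characterize_events(rec: LfpRecording, events: EventSet, channel: int,
                        window_s: float = 0.1) -> list[SwrFeatureSet]:
    """Full feature set for every event on the pyramidal-layer channel."""
    out = []
    for iv in events:
        flags = []
        try:
            peak = ripple_peak(rec, iv, channel=channel)
        except ValueError:
            peak, _ = float("nan"), flags.append("no-peak")
        ps_band = spectrum(rec, iv, channel=channel, window_s=window_s,
                           band=PEAK_BAND)
        pref, fl = preferred_frequency(ps_band)
        if fl:
            flags.append(fl)
        ps_full = spectrum(rec, iv, channel=channel, window_s=window_s)
        frac, fl = low_freq_fraction(ps_full)
        if fl:
            flags.append(fl)
        out.append(SwrFeatureSet(
            peak_time_s=peak, preferred_freq_hz=pref, low_freq_fraction=frac,
            entropy_bits=spectral_entropy(ps_full), flags=";".join(flags)))
    return out
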
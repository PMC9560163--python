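"""Seeded generator of annotated laminar LFP sessions.

The generator emulates an 8-channel linear probe spanning the CA1
somatodendritic axis. Each session consists of

* a per-channel 1/f^beta background (unit SD),
* optional theta epochs (6-10 Hz) alternating with quiet epochs in blocks,
* sharp-wave ripple events: a slow sharp-wave deflection whose polarity flips
  across depth (positive above, negative below, zero crossing one channel
  below the pyramidal-layer channel) plus a ripple burst - a sinusoid at a
  truncated-normal frequency (100-250 Hz) under a Gaussian amplitude envelope,
  maximal at the pyramidal channel and decaying with channel distance,
* optional broadband artifacts present on all channels simultaneously.

Amplitudes are expressed in SD units of the background. Events are annotated
where the ripple amplitude envelope crosses 10% of its event maximum,
mirroring the convention of marking the first and last visible ripple.
A single RNG stream is consumed in a fixed order (background -> theta ->
events -> artifacts) so that identical parameters and seed reproduce the
session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventSet, LfpRecording

#: 10% envelope crossing used for the annotated start/end, in units of the
#: Gaussian envelope sigma: exp(-t^2 / 2 sigma^2) = 0.1 at |t| = 2.1460 sigma.
_ANNOT_SIGMA = float(np.sqrt(2.0 * np.log(10.0)))


@dataclass
class GeneratorParams:
    """Parameters of the synthetic session generator (defaults are the
    standard study conditions used throughout the test-suite)."""

    duration_s: float = 60.0
    fs_raw: float = 30000.0
    n_channels: int = 8
    channel_spacing_um: float = 20.0
    event_rate_hz: float = 0.2
    refractory_s: float = 0.25
    ripple_freq_mean: float = 150.0
    ripple_freq_sd: float = 20.0
    ripple_freq_range: tuple = (100.0, 250.0)
    ripple_dur_mean: float = 0.06
    ripple_dur_sd: float = 0.02
    ripple_dur_range: tuple = (0.03, 0.12)
    sw_amp: float = 4.0
    ripple_amp: float = 3.0
    pyramidal_channel_index: int = 2
    theta_epoch_fraction: float = 0.5
    theta_amp: float = 1.5
    theta_block_s: float = 10.0
    artifact_rate_hz: float = 0.05
    artifact_amp: float = 8.0
    artifact_dur_s: float = 0.05
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate_hz * self.refractory_s >= 1:
            raise ValueError("event_rate_hz * refractory_s must be < 1")
        if not 0 <= self.pyramidal_channel_index < self.n_channels:
            raise ValueError("pyramidal_channel_index out of range")
        for name in ("event_rate_hz", "artifact_rate_hz", "theta_epoch_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.theta_epoch_fraction > 1:
            raise ValueError("theta_epoch_fraction must be <= 1")
        if self.duration_s <= 0 or self.fs_raw <= 0:
            raise ValueError("duration_s and fs_raw must be positive")


@dataclass
class SyntheticSession:
    """A generated session: recording, ground truth, per-event table and
    artifact intervals."""

    recording: LfpRecording
    ground_truth: EventSet
    event_table: pd.DataFrame
    artifact_intervals: EventSet
    params: GeneratorParams = field(repr=False, default=None)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (vector-friendly for small sizes)."""
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out[0] if size is None else out


def _one_over_f(rng, n_samples, n_channels, fs, beta):
    """Unit-SD 1/f^beta noise per channel via FFT shaping."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-beta / 2.0)
    scale[0] = 0.0
    white = rng.standard_normal((n_samples, n_channels))
    spec = np.fft.rfft(white, axis=0) * scale[:, None]
    x = np.fft.irfft(spec, n=n_samples, axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _depth_profiles(params: GeneratorParams):
    """(sharp-wave polarity profile, ripple amplitude decay) across channels.

    The sharp wave follows a linear polarity gradient crossing zero one
    channel below the pyramidal channel (positive above, negative below);
    the ripple decays exponentially with channel distance from the pyramidal
    channel (length constant 1.2 channels).
    """
    ch = np.arange(params.n_channels, dtype=float)
    zero_ch = params.pyramidal_channel_index + 1.0
    sw = zero_ch - ch
    peak = np.abs(sw).max()
    sw = sw / (peak if peak else 1.0)
    ripple = np.exp(-np.abs(ch - params.pyramidal_channel_index) / 1.2)
    return sw, ripple


def generate_event(params: GeneratorParams, rng: np.random.Generator):
    """Draw one sharp-wave ripple waveform.

    Returns ``(waveform, meta)`` where ``waveform`` has shape
    ``(n_channels, n_samples)`` centered on the event, and ``meta`` carries
    the drawn ripple frequency (Hz), duration (s), the annotated half-width
    (s, the 10% envelope crossing) and the waveform's sample offset of the
    event center.
    """
    f = float(_truncated_normal(rng, params.ripple_freq_mean, params.ripple_freq_sd,
                                *params.ripple_freq_range))
    dur = float(_truncated_normal(rng, params.ripple_dur_mean, params.ripple_dur_sd,
                                  *params.ripple_dur_range))
    phase = rng.uniform(0, 2 * np.pi)
    fs = params.fs_raw
    sigma = dur / 4.0                      # ripple envelope; +-2 sigma ~ dur
    sw_rise, sw_fall = dur / 3.0, dur / 2.0  # asymmetric half-Gaussian lobes
    half = 3.5 * max(sigma, sw_fall)
    n_half = int(np.ceil(half * fs))
    t = (np.arange(-n_half, n_half + 1)) / fs
    env = np.exp(-0.5 * (t / sigma) ** 2)
    ripple_1d = env * np.sin(2 * np.pi * f * t + phase)
    sw_sigma = np.where(t < 0, sw_rise, sw_fall)
    sw_1d = np.exp(-0.5 * (t / sw_sigma) ** 2)  # asymmetric deflection shape
    sw_prof, rip_prof = _depth_profiles(params)
    wave = (params.sw_amp * np.outer(sw_prof, sw_1d)
            + params.ripple_amp * np.outer(rip_prof, ripple_1d))
    meta = {
        "freq_hz": f,
        "duration_s": dur,
        "annot_half_s": _ANNOT_SIGMA * sigma,
        "center_index": n_half,
    }
    return wave, meta


def generate_session(params: GeneratorParams) -> SyntheticSession:
    """Generate a fully annotated synthetic session.

    Deterministic given ``params`` (including ``params.seed``). Events are
    placed by a Poisson process thinned to respect the refractory gap, and
    artifacts are thinned against events so no event overlaps an artifact.
    """
    if params.duration_s <= 1:
        raise ValueError("duration_s must exceed 1 s")
    rng = np.random.default_rng(params.seed)
    fs = params.fs_raw
    n = int(round(params.duration_s * fs))
    # 1) background
    data = _one_over_f(rng, n, params.n_channels, fs, params.noise_exponent)
    # 2) theta epochs in alternating blocks
    if params.theta_epoch_fraction > 0:
        t_axis = np.arange(n) / fs
        # theta occupies the first theta_epoch_fraction of every on/off pair
        # of blocks: [k*period, k*period + frac*period), period = 2 blocks
        period = 2 * params.theta_block_s
        frac = params.theta_epoch_fraction
        in_theta = (t_axis % period) < frac * period
        f_theta = rng.uniform(6.0, 10.0)
        phase = rng.uniform(0, 2 * np.pi)
        theta = params.theta_amp * np.sin(2 * np.pi * f_theta * t_axis + phase)
        data += np.where(in_theta, theta, 0.0)[:, None]
    # 3) events: homogeneous Poisson thinned by the refractory gap
    n_draw = rng.poisson(params.event_rate_hz * params.duration_s)
    margin = 0.3  # keep annotated spans inside the session
    centers = np.sort(rng.uniform(margin, params.duration_s - margin, size=n_draw))
    kept = []
    for c in centers:
        if not kept or c - kept[-1] >= params.refractory_s:
            kept.append(c)
    rows = []
    for c in kept:
        wave, meta = generate_event(params, rng)
        ci = int(round(c * fs))
        lo = ci - meta["center_index"]
        hi = lo + wave.shape[1]
        s0, s1 = max(lo, 0), min(hi, n)
        data[s0:s1] += wave[:, s0 - lo:s1 - lo].T
        rows.append({
            "start_s": c - meta["annot_half_s"],
            "end_s": c + meta["annot_half_s"],
            "center_s": c,
            "freq_hz": meta["freq_hz"],
            "duration_s": meta["duration_s"],
            "sw_amp": params.sw_amp,
            "ripple_amp": params.ripple_amp,
        })
    table = pd.DataFrame(
        rows, columns=["start_s", "end_s", "center_s", "freq_hz",
                       "duration_s", "sw_amp", "ripple_amp"])
    truth = EventSet(table[["start_s", "end_s"]].to_numpy() if rows else
                     np.empty((0, 2)), label="ground_truth")
    # 4) artifacts: Poisson, thinned against events
    art_rows = []
    n_art = rng.poisson(params.artifact_rate_hz * params.duration_s)
    art_centers = np.sort(rng.uniform(0.1, params.duration_s - 0.1, size=n_art))
    half_art = params.artifact_dur_s / 2.0
    for c in art_centers:
        a0, a1 = c - half_art, c + half_art
        if len(truth) and np.any(truth.overlaps(a0 - 0.05, a1 + 0.05)):
            continue
        n_samp = int(round(params.artifact_dur_s * fs))
        burst = rng.standard_normal(n_samp)
        taper = np.hanning(n_samp)
        seg = params.artifact_amp * burst * taper
        i0 = int(round(a0 * fs))
        i1 = min(i0 + n_samp, n)
        data[i0:i1] += seg[: i1 - i0, None]  # same on ALL channels
        art_rows.append([a0, a1])
    artifacts = EventSet(np.array(art_rows) if art_rows else np.empty((0, 2)),
                         label="artifact")
    depths = np.arange(params.n_channels) * params.channel_spacing_um
    labels = _default_layer_labels(params)
    # synthetic amplitudes are in SD units; the int16 write gain is chosen
    # so that +-65 units span the integer range with negligible quantization
    rec = LfpRecording(data=data, fs=fs, channel_depths_um=depths,
                       layer_labels=labels, gain_uv_per_bit=0.002)
    return SyntheticSession(recording=rec, ground_truth=truth,
                            event_table=table, artifact_intervals=artifacts,
                            params=params)


def _default_layer_labels(params: GeneratorParams) -> list[str]:
    """SO above the pyramidal channel, SP at it, SR below, SLM at the bottom."""
    labels = []
    pyr = params.pyramidal_channel_index
    for ch in range(params.n_channels):
        if ch < pyr:
            labels.append("SO")
        elif ch == pyr:
            labels.append("SP")
        elif ch == params.n_channels - 1:
            labels.append("SLM")
        else:
            labels.append("SR")
    return labels
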
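"""EMG envelope extraction.

Raw EMG channels are rectified, low-pass filtered with a zero-phase
(forward-reverse) fifth-order Butterworth at 15 Hz — or, equivalently,
smoothed by singular-spectrum analysis (SSA) with a window of 250 samples —
and normalized to their per-channel maximum.  The resulting envelopes live
in [0, 1] and share their shape scale with model-estimated activations,
which is what the lagged-correlation comparison consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, signal

from .exceptions import InvalidArgumentError
from .synthetic_data import EMGSet

__all__ = ["EnvelopeSet", "process_emg", "resample_to_frames", "read_emg_csv"]


@dataclass
class EnvelopeSet:
    """Normalized EMG envelopes: (c, f') values in [0, 1], max per channel = 1."""

    values: np.ndarray
    sample_rate: float
    channel_map: dict[int, str]
    zero_channels: list[int] = field(default_factory=list)  # all-zero inputs, left as zeros

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return (self.values.shape[1] - 1) / self.sample_rate


def _ssa_smooth(x: np.ndarray, window: int, sample_rate: float, cutoff_hz: float) -> np.ndarray:
    """Singular-spectrum-analysis smoothing of one channel.

    Embeds the series in a Hankel trajectory matrix of the given window
    length and reconstructs by diagonal averaging from the eigentriples whose
    left singular vector has its dominant frequency at or below the cutoff —
    the SSA grouping that realizes low-pass smoothing equivalent to the
    Butterworth path.
    """
    n = x.size
    window = min(window, n // 2)
    if window < 2:
        return x.copy()
    k = n - window + 1
    traj = linalg.hankel(x[:window], x[window - 1:])  # (window, k)
    u, s, vt = np.linalg.svd(traj, full_matrices=False)
    freqs = np.fft.rfftfreq(window, d=1.0 / sample_rate)
    dominant = freqs[np.argmax(np.abs(np.fft.rfft(u, axis=0)), axis=0)]
    keep = dominant <= cutoff_hz
    if not keep.any():
        keep[0] = True  # always retain the trend component
    approx = (u[:, keep] * s[keep]) @ vt[keep]
    # diagonal averaging back to a series
    out = np.zeros(n)
    counts = np.zeros(n)
    idx = np.arange(window)[:, None] + np.arange(k)[None, :]
    np.add.at(out, idx, approx)
    np.add.at(counts, idx, 1.0)
    return out / counts


def process_emg(
    raw: EMGSet,
    cutoff_hz: float = 15.0,
    order: int = 5,
    method: str = "butterworth",
    ssa_window: int = 250,
) -> EnvelopeSet:
    """Rectify, smooth, and max-normalize raw EMG channels.

    ``method="butterworth"`` applies a zero-phase forward-reverse low-pass
    Butterworth of the given order (the effective magnitude response is the
    squared one-pass response); ``method="ssa"`` uses singular-spectrum
    smoothing with ``ssa_window`` samples instead.  Negative filter
    undershoot is clipped to zero before normalization.  All-zero channels
    are returned as zeros and flagged in ``zero_channels``.
    """
    if cutoff_hz >= raw.sample_rate / 2:
        raise InvalidArgumentError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({raw.sample_rate / 2} Hz)"
        )
    if method not in ("butterworth", "ssa"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    rect = np.abs(raw.channels)
    if method == "butterworth":
        sos = signal.butter(order, cutoff_hz, fs=raw.sample_rate, output="sos")
        smooth = signal.sosfiltfilt(sos, rect, axis=1)
    else:
        smooth = np.vstack(
            [_ssa_smooth(ch, ssa_window, raw.sample_rate, cutoff_hz) for ch in rect]
        )
    smooth = np.clip(smooth, 0.0, None)
    peaks = smooth.max(axis=1)
    zero_channels = [int(i) for i in np.flatnonzero(peaks == 0)]
    if zero_channels:
        warnings.warn(f"all-zero EMG channels left unnormalized: {zero_channels}")
    safe = np.where(peaks == 0, 1.0, peaks)
    return EnvelopeSet(
        values=smooth / safe[:, None],
        sample_rate=raw.sample_rate,
        channel_map=dict(raw.channel_map),
        zero_channels=zero_channels,
    )


def resample_to_frames(env: EnvelopeSet, f: int, dt: float) -> np.ndarray:
    """Linearly interpolate envelopes onto the motion time base; returns (c, f).

    The recording must cover the trial duration.  Linear interpolation of
    values in [0, 1] stays in [0, 1].
    """
    if f < 1 or dt <= 0:
        raise InvalidArgumentError("require f >= 1 and dt > 0")
    trial_duration = (f - 1) * dt
    if trial_duration > env.duration + 1e-12:
        raise InvalidArgumentError(
            f"trial duration {trial_duration:.6g}s exceeds recording {env.duration:.6g}s"
        )
    t_env = np.arange(env.values.shape[1]) / env.sample_rate
    t_frames = np.arange(f) * dt
    return np.vstack([np.interp(t_frames, t_env, ch) for ch in env.values])


def read_emg_csv(path, sample_rate: float, channel_map: dict[int, str] | None = None) -> EMGSet:
    """Read raw EMG from a CSV with a time column followed by channel columns."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidArgumentError("EMG CSV needs a time column plus channel columns")
    channels = df.iloc[:, 1:].to_numpy(dtype=float).T
    names = list(df.columns[1:])
    c = channels.shape[0]
    return EMGSet(
        sample_rate=float(sample_rate),
        channels=channels,
        channel_map=channel_map or {i: names[i] for i in range(c)},
        delays=np.zeros(c),
        noise_sd=0.0,
        crosstalk=np.eye(c),
    )
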
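"""Windowed ECoG feature extraction.

Two per-channel feature families over non-overlapping windows (20 s default):

``set_t`` — eight time-domain statistics per channel:
    area, normalized decay, line length, mean energy, peak amplitude,
    valley amplitude, normalized peak number, peak variation.
    A *peak* is a change from negative to positive in the signal-derivative
    sign, a *valley* the opposite change.  With 16 channels this yields a
    128-dimensional window vector.

``set_f`` — five band powers per channel (Delta 0-4, Theta 4-8, Alpha 8-12,
    Beta 12-30, Gamma 30-100 Hz): 2nd-order Butterworth band-pass (low-pass
    for Delta), applied forward-backward (zero phase), then the mean of the
    squared filtered signal.  With 16 channels: 80 dimensions.

Feature columns are ordered channel-major (all features of channel 0, then
channel 1, ...); ``both`` concatenates the full set_t block before the full
set_f block.  Extraction is pure: the same window always yields the same
vector, with defined sentinel values (never NaN) for degenerate windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import Recording

TIME_FEATURE_NAMES = (
    "area",
    "decay",
    "line_length",
    "energy",
    "peak_amp",
    "valley_amp",
    "peak_number",
    "peak_variation",
)

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

_NO_PEAK_SENTINEL = -12.0
_EPS = 1e-12


@dataclass
class WindowFeatures:
    """Per-window feature matrix with a fixed, documented column order."""

    X: np.ndarray  # (n_windows, d)
    columns: list[str]
    feature_set: str
    window_length_s: float
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def window_signal(signal: np.ndarray, fs: float, window_length_s: float = 20.0) -> np.ndarray:
    """Split (channels x samples) into non-overlapping windows.

    Returns a view of shape (n_windows, n_channels, samples_per_window) where
    window i covers samples [i*w, (i+1)*w); any trailing remainder is
    discarded.  A window longer than the recording yields zero windows.
    """
    w = window_length_s * fs
    if w != int(w):
        raise ValueError("window_length_s * fs must be an integer sample count")
    w = int(w)
    n_ch, n_samp = signal.shape
    n_win = n_samp // w
    trimmed = signal[:, : n_win * w]
    return trimmed.reshape(n_ch, n_win, w).transpose(1, 0, 2)


def _peak_valley_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    s = np.sign(d)
    peaks = np.flatnonzero((s[:-1] < 0) & (s[1:] > 0)) + 1
    valleys = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0)) + 1
    return peaks, valleys


def _log_mean_square(values: np.ndarray) -> float:
    if values.size == 0:
        return _NO_PEAK_SENTINEL
    ms = float(np.mean(values**2))
    if ms <= 0.0:
        return _NO_PEAK_SENTINEL
    return float(np.log10(ms))


def compute_time_features(x: np.ndarray, fs: float = 400.0) -> np.ndarray:
    """Eight time-domain features of a single-channel window.

    Order matches :data:`TIME_FEATURE_NAMES`.  All values are finite:
    windows without peaks get the log-amplitude sentinel -12, and peak
    variation is 0 when fewer than two extrema exist.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("window must be non-empty")
    n = x.size
    window_s = n / fs
    d = np.diff(x)
    abs_d = np.abs(d)

    area = float(np.mean(np.abs(x)))
    frac_decreasing = float(np.mean(d < 0)) if d.size else 0.5
    decay = float(np.clip((frac_decreasing - 0.5) * 2.0, -1.0, 1.0))
    line_length = float(abs_d.sum())
    energy = float(np.mean(x**2))

    peaks, valleys = _peak_valley_indices(x)
    peak_amp = _log_mean_square(x[peaks])
    valley_amp = _log_mean_square(x[valleys])
    mean_step = float(abs_d.mean()) if d.size else 0.0
    peak_number = peaks.size / (mean_step + _EPS)

    extrema = np.sort(np.concatenate([peaks, valleys]))
    if extrema.size < 2:
        peak_variation = 0.0
    else:
        swings = np.diff(x[extrema])
        peak_variation = float(np.std(swings) / window_s)

    return np.array(
        [area, decay, line_length, energy, peak_amp, valley_amp, peak_number, peak_variation]
    )


def compute_band_powers(x: np.ndarray, fs: float) -> np.ndarray:
    """Five Berger-band powers of a single-channel window.

    Order: delta, theta, alpha, beta, gamma (:data:`BANDS`).  Requires a
    sampling rate able to represent the 30-100 Hz gamma band.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("window must be non-empty")
    nyq = fs / 2.0
    powers = np.empty(len(BANDS))
    for i, (name, (lo, hi)) in enumerate(BANDS.items()):
        if hi >= nyq:
            raise ValueError(
                f"sampling rate {fs} Hz too low for the {name} band ({lo}-{hi} Hz)"
            )
        if lo <= 0.0:
            sos = sps.butter(2, hi, btype="lowpass", fs=fs, output="sos")
        else:
            sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        filtered = sps.sosfiltfilt(sos, x)
        powers[i] = float(np.mean(filtered**2))
    return powers


def _columns(n_channels: int, feature_set: str) -> list[str]:
    cols: list[str] = []
    if feature_set in ("set_t", "both"):
        for ch in range(n_channels):
            cols += [f"ch{ch:02d}_{name}" for name in TIME_FEATURE_NAMES]
    if feature_set in ("set_f", "both"):
        for ch in range(n_channels):
            cols += [f"ch{ch:02d}_{name}" for name in BANDS]
    return cols


def extract_features(
    rec: Recording,
    feature_set: str = "set_t",
    window_length_s: float | None = None,
) -> WindowFeatures:
    """Window a recording and compute per-channel features for every window."""
    if feature_set not in ("set_t", "set_f", "both"):
        raise ValueError(f"unknown feature_set {feature_set!r}")
    w = rec.window_length_s if window_length_s is None else window_length_s
    windows = window_signal(rec.signal, rec.fs, w)
    n_win, n_ch, _ = windows.shape

    blocks = []
    if feature_set in ("set_t", "both"):
        Xt = np.empty((n_win, n_ch * len(TIME_FEATURE_NAMES)))
        for i in range(n_win):
            for ch in range(n_ch):
                Xt[i, ch * 8 : (ch + 1) * 8] = compute_time_features(windows[i, ch], rec.fs)
        blocks.append(Xt)
    if feature_set in ("set_f", "both"):
        nb = len(BANDS)
        Xf = np.empty((n_win, n_ch * nb))
        for i in range(n_win):
            for ch in range(n_ch):
                Xf[i, ch * nb : (ch + 1) * nb] = compute_band_powers(windows[i, ch], rec.fs)
        blocks.append(Xf)

    X = np.hstack(blocks) if blocks else np.empty((n_win, 0))
    return WindowFeatures(
        X=X,
        columns=_columns(n_ch, feature_set),
        feature_set=feature_set,
        window_length_s=w,
        fs=rec.fs,
        meta={"n_channels": n_ch},
    )
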
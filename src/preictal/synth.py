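"""Synthetic annotated ECoG recordings with controllable pre-ictal separability.

The generator emulates the structure of chronic multichannel ECoG used for
seizure prediction: a stationary inter-ictal background per channel, plus
pre-ictal epochs (the interval preceding each lead-seizure onset) carrying
elevated time-domain activity whose strength is controlled by a single
``effect_size`` parameter.  ``effect_size = 0`` makes the two classes
statistically identical; increasing it raises line length and mean energy of
pre-ictal windows monotonically.

Model
-----
* Background: per-channel AR(2) noise with a resonant spectral peak
  (default ~6 Hz), scaled to a microvolt-level standard deviation.
* Pre-ictal signature: additive band-limited oscillatory bursts (10-25 Hz,
  Hann envelopes) and sparse biphasic spikes (derivative-of-Gaussian shape),
  both with amplitude proportional to ``effect_size``.

All randomness flows from one ``numpy.random.Generator`` seeded per
recording, so identical configurations give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps


class PlacementError(ValueError):
    """Requested seizures cannot be placed without overlapping pre-ictal intervals."""


@dataclass
class Recording:
    """A multichannel ECoG segment with seizure annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Microvolt-scale amplitudes.
    fs : float
        Sampling rate in Hz.
    seizure_onsets : list of float
        Onset times in seconds, each strictly inside the recording.
    window_labels : ndarray of {0, 1}
        Per-window class (1 = pre-ictal), aligned to non-overlapping
        windows of ``window_length_s`` starting at t = 0.
    window_length_s : float
        Windowing convention the labels refer to.
    meta : dict
        Subject id, seed and generator parameters.
    """

    signal: np.ndarray
    fs: float
    seizure_onsets: list[float] = field(default_factory=list)
    window_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    window_length_s: float = 20.0
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        n_win = int(self.duration_s // self.window_length_s)
        if len(self.window_labels) != n_win:
            raise ValueError(
                f"window_labels has {len(self.window_labels)} entries, "
                f"expected floor(duration / window_length) = {n_win}"
            )
        for t in self.seizure_onsets:
            if not (0.0 < t < self.duration_s):
                raise ValueError(f"seizure onset {t} s not strictly inside recording")


@dataclass
class SynthConfig:
    """Generator parameters.

    ``duration_h = None`` derives the duration from the requested imbalance:
    each seizure contributes ``preictal_minutes`` of pre-ictal time plus
    ``imbalance_ratio`` times as much inter-ictal time, so the emitted
    window-class ratio matches ``imbalance_ratio`` exactly (up to grid
    rounding of one window).
    """

    duration_h: float | None = None
    fs: float = 400.0
    n_channels: int = 16
    preictal_minutes: float = 60.0
    effect_size: float = 1.0
    imbalance_ratio: float = 10.0
    n_lead_seizures: int = 2
    window_length_s: float = 20.0
    seed: int = 0
    subject: str = "synthetic"
    # background / signature shape parameters
    background_std_uv: float = 50.0
    ar_peak_hz: float = 6.0
    ar_pole_radius: float = 0.97
    burst_rate_hz: float = 0.25
    burst_amp_uv: float = 30.0
    spike_rate_hz: float = 0.5
    spike_amp_uv: float = 60.0

    def validate(self) -> None:
        if self.fs <= 0 or self.n_channels < 1 or self.n_lead_seizures < 1:
            raise ValueError("fs, n_channels and n_lead_seizures must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1 (inter-ictal : pre-ictal)")
        if self.window_length_s * self.fs != int(self.window_length_s * self.fs):
            raise ValueError("window_length_s * fs must be an integer sample count")

    def duration_seconds(self) -> float:
        """Recording length in seconds, derived from imbalance when not given."""
        w = self.window_length_s
        if self.duration_h is not None:
            return float(self.duration_h) * 3600.0
        per_seizure = self.preictal_minutes * 60.0 * (1.0 + self.imbalance_ratio)
        per_seizure = math.ceil(per_seizure / w) * w
        return per_seizure * self.n_lead_seizures


def _place_seizures(cfg: SynthConfig, duration_s: float) -> list[float]:
    """Evenly spaced onsets snapped to the window grid; error if infeasible."""
    w = cfg.window_length_s
    pre_s = cfg.preictal_minutes * 60.0
    seg = duration_s / cfg.n_lead_seizures
    onsets = []
    for i in range(cfg.n_lead_seizures):
        onset = math.floor(((i + 1) * seg - w) / w) * w
        onsets.append(float(onset))
    prev_end = 0.0
    for i, onset in enumerate(onsets):
        if not (0.0 < onset < duration_s):
            raise PlacementError(
                f"seizure {i} onset {onset} s falls outside the {duration_s} s recording"
            )
        if onset - pre_s < prev_end - 1e-9:
            raise PlacementError(
                f"pre-ictal interval [{onset - pre_s}, {onset}) s of seizure {i} "
                f"overlaps earlier material ending at {prev_end} s; "
                "increase duration or reduce preictal_minutes/n_lead_seizures"
            )
        prev_end = onset
    return onsets


def _window_labels(duration_s: float, w: float, onsets: list[float], pre_s: float) -> np.ndarray:
    n_win = int(duration_s // w)
    labels = np.zeros(n_win, dtype=np.int8)
    for onset in onsets:
        lo, hi = onset - pre_s, onset
        for i in range(n_win):
            if i * w >= lo - 1e-9 and (i + 1) * w <= hi + 1e-9:
                labels[i] = 1
    return labels


def _ar2_background(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    r, f0 = cfg.ar_pole_radius, cfg.ar_peak_hz
    phi1 = 2.0 * r * math.cos(2.0 * math.pi * f0 / cfg.fs)
    phi2 = -r * r
    burn = 2000
    white = rng.standard_normal(n + burn)
    x = sps.lfilter([1.0], [1.0, -phi1, -phi2], white)[burn:]
    x *= cfg.background_std_uv / x.std()
    return x


def _biphasic_spike(fs: float, width_s: float = 0.06) -> np.ndarray:
    n = max(int(width_s * fs), 5)
    t = np.linspace(-3, 3, n)
    shape = -t * np.exp(-t * t / 2.0)  # derivative-of-Gaussian
    return shape / np.abs(shape).max()


def _add_preictal_signature(
    rng: np.random.Generator, x: np.ndarray, lo: int, hi: int, cfg: SynthConfig
) -> None:
    """Superimpose bursts and spikes on x[lo:hi] in place, scaled by effect_size."""
    fs, es = cfg.fs, cfg.effect_size
    span = hi - lo
    n_bursts = rng.poisson(cfg.burst_rate_hz * span / fs)
    for _ in range(n_bursts):
        dur = int(rng.uniform(0.5, 1.5) * fs)
        start = lo + int(rng.uniform(0, max(span - dur, 1)))
        freq = rng.uniform(10.0, 25.0)
        amp = es * cfg.burst_amp_uv * rng.uniform(0.5, 1.5)
        t = np.arange(dur) / fs
        burst = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        burst *= np.hanning(dur)
        stop = min(start + dur, hi)
        x[start:stop] += burst[: stop - start]
    n_spikes = rng.poisson(cfg.spike_rate_hz * span / fs)
    shape = _biphasic_spike(fs)
    m = shape.size
    for _ in range(n_spikes):
        start = lo + int(rng.uniform(0, max(span - m, 1)))
        amp = es * cfg.spike_amp_uv * rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        stop = min(start + m, hi)
        x[start:stop] += amp * shape[: stop - start]


def generate_recording(cfg: SynthConfig) -> Recording:
    """Generate a seed-deterministic annotated synthetic ECoG recording."""
    cfg.validate()
    duration_s = cfg.duration_seconds()
    pre_s = cfg.preictal_minutes * 60.0
    if duration_s < cfg.n_lead_seizures * pre_s:
        raise PlacementError(
            f"{cfg.n_lead_seizures} pre-ictal intervals of {pre_s} s do not fit "
            f"in a {duration_s} s recording"
        )
    n = int(round(duration_s * cfg.fs))
    onsets = _place_seizures(cfg, duration_s)
    labels = _window_labels(duration_s, cfg.window_length_s, onsets, pre_s)

    rng = np.random.default_rng(cfg.seed)
    signal = np.empty((cfg.n_channels, n), dtype=np.float32)
    for ch in range(cfg.n_channels):
        signal[ch] = _ar2_background(rng, n, cfg)
    for ch in range(cfg.n_channels):
        for onset in onsets:
            lo = int((onset - pre_s) * cfg.fs)
            hi = int(onset * cfg.fs)
            buf = signal[ch, lo:hi].astype(np.float64)
            _add_preictal_signature(rng, buf, 0, hi - lo, cfg)
            signal[ch, lo:hi] = buf

    meta = {"config": asdict(cfg), "seed": cfg.seed, "subject": cfg.subject}
    rec = Recording(
        signal=signal,
        fs=cfg.fs,
        seizure_onsets=onsets,
        window_labels=labels,
        window_length_s=cfg.window_length_s,
        meta=meta,
    )
    rec.validate()
    return rec
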
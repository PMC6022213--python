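"""Reading and writing recordings: plain EDF signals plus delimited sidecars.

A generated :class:`~preictal.synth.Recording` is persisted as

* ``<base>.edf`` — one EDF signal per channel, physical dimension µV,
  16-bit samples, 1 s data records (plain EDF, no annotation channel);
* ``<base>.windows.csv`` — per-window labels with columns
  ``window_index,start_s,end_s,label`` (UTF-8, header row);
* ``<base>.seizures.csv`` — one ``onset_s`` column;
* ``<base>.meta.json`` — sampling rate, seed and generator parameters.

``read(write(x))`` reproduces the signal within one EDF quantization step
and the annotations exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Recording, SynthConfig

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt8(value: float) -> str:
    """Format a number into at most 8 ASCII characters (EDF header field)."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {value} in 8 characters")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(path: str | Path, signal: np.ndarray, fs: float, labels: list[str] | None = None) -> None:
    """Write a (channels x samples) µV array as a plain EDF file.

    The sample count must be an integer number of seconds at ``fs`` (data
    records are one second long) and ``fs`` must be an integer rate.
    """
    path = Path(path)
    signal = np.asarray(signal, dtype=np.float64)
    n_ch, n_samp = signal.shape
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per record (1 s records)
    if n_samp % spr:
        raise ValueError("signal length must be a whole number of seconds")
    n_rec = n_samp // spr
    if labels is None:
        labels = [f"ECoG ch{c:02d}" for c in range(n_ch)]

    # per-channel symmetric physical range; re-parse the 8-char header text so
    # the scaling used for quantization is exactly what a reader will see
    pmaxs, scales, offsets = [], [], []
    for c in range(n_ch):
        pm = max(float(np.abs(signal[c]).max()), 1e-6)
        pm_txt = _fmt8(pm * 1.000001)  # guard against truncation below the data max
        pm = float(pm_txt)
        pmaxs.append(pm_txt)
        scales.append((_DIG_MAX - _DIG_MIN) / (2.0 * pm))
        offsets.append(-pm)

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.01", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for c in range(n_ch):
            fh.write(_pad(labels[c], 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for c in range(n_ch):
            fh.write(_pad("-" + pmaxs[c], 8))
        for c in range(n_ch):
            fh.write(_pad(pmaxs[c], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        digital = np.empty((n_ch, n_samp), dtype=np.int16)
        for c in range(n_ch):
            d = np.round((signal[c] - offsets[c]) * scales[c]) + _DIG_MIN
            digital[c] = np.clip(d, _DIG_MIN, _DIG_MAX).astype(np.int16)
        # record-major layout: record r holds spr samples of every channel
        interleaved = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(interleaved, dtype="<i2").tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read a plain EDF file; returns (channels x samples µV, fs, labels)."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_rec = int(header[236:244].decode("ascii"))
        rec_dur = float(header[244:252].decode("ascii"))
        n_ch = int(header[252:256].decode("ascii"))
        sig_hdr = fh.read(256 * n_ch)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig_hdr[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmins = [int(v) for v in fields(16 + 80 + 8 + 8 + 8, 8)]
        dmaxs = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8, 8)]
        spr = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    total_per_rec = sum(spr)
    raw = raw[: n_rec * total_per_rec].reshape(n_rec, total_per_rec)
    signal = np.empty((n_ch, n_rec * spr[0]), dtype=np.float64)
    if len(set(spr)) != 1:
        raise ValueError("heterogeneous samples-per-record not supported")
    pos = np.cumsum([0] + spr)
    for c in range(n_ch):
        dig = raw[:, pos[c] : pos[c + 1]].reshape(-1).astype(np.float64)
        scale = (pmaxs[c] - pmins[c]) / (dmaxs[c] - dmins[c])
        signal[c] = (dig - dmins[c]) * scale + pmins[c]
    fs = spr[0] / rec_dur
    return signal, fs, labels


def write_recording(rec: Recording, base: str | Path) -> dict[str, Path]:
    """Persist a Recording as EDF + sidecar tables; returns written paths."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": base.with_suffix(".edf"),
        "windows": base.with_suffix(".windows.csv"),
        "seizures": base.with_suffix(".seizures.csv"),
        "meta": base.with_suffix(".meta.json"),
    }
    write_edf(paths["edf"], rec.signal, rec.fs)
    w = rec.window_length_s
    pd.DataFrame(
        {
            "window_index": np.arange(len(rec.window_labels)),
            "start_s": np.arange(len(rec.window_labels)) * w,
            "end_s": (np.arange(len(rec.window_labels)) + 1) * w,
            "label": np.asarray(rec.window_labels, dtype=int),
        }
    ).to_csv(paths["windows"], index=False)
    pd.DataFrame({"onset_s": rec.seizure_onsets}).to_csv(paths["seizures"], index=False)
    meta = dict(rec.meta)
    meta.update({"fs": rec.fs, "n_channels": rec.n_channels, "window_length_s": w})
    paths["meta"].write_text(json.dumps(meta, indent=2, default=float))
    return paths


def read_recording(
    base: str | Path,
    expected_fs: float | None = None,
    n_channels: int | None = None,
    channels: list[int] | None = None,
) -> Recording:
    """Load a Recording written by :func:`write_recording`.

    ``channels`` selects an explicit channel subset; otherwise, when the file
    holds more channels than ``n_channels``, the first ``n_channels`` are
    kept.  A file with fewer channels than requested is an error, as is a
    sampling-rate mismatch.
    """
    base = Path(base)
    if base.suffix == ".edf":
        base = base.with_suffix("")
    signal, fs, _ = read_edf(base.with_suffix(".edf"))
    if expected_fs is not None and fs != expected_fs:
        raise ValueError(f"sampling rate mismatch: file has {fs} Hz, expected {expected_fs}")
    if channels is not None:
        signal = signal[list(channels)]
    elif n_channels is not None:
        if signal.shape[0] < n_channels:
            raise ValueError(
                f"file has {signal.shape[0]} channels, {n_channels} requested"
            )
        signal = signal[:n_channels]

    meta: dict = {}
    meta_path = base.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    window_length_s = float(meta.get("window_length_s", 20.0))

    win_path = base.with_suffix(".windows.csv")
    n_win = int((signal.shape[1] / fs) // window_length_s)
    labels = np.zeros(n_win, dtype=np.int8)
    if win_path.exists():
        table = pd.read_csv(win_path)
        if len(table):
            labels[table["window_index"].to_numpy(dtype=int)] = table["label"].to_numpy(dtype=np.int8)

    onsets: list[float] = []
    sz_path = base.with_suffix(".seizures.csv")
    if sz_path.exists():
        table = pd.read_csv(sz_path)
        if len(table):
            onsets = [float(v) for v in table["onset_s"]]

    rec = Recording(
        signal=signal,
        fs=fs,
        seizure_onsets=onsets,
        window_labels=labels,
        window_length_s=window_length_s,
        meta=meta,
    )
    rec.validate()
    return rec


def load_config(path: str | Path) -> SynthConfig:
    """Read a SynthConfig from YAML (or JSON, a YAML subset)."""
    data = yaml.safe_load(Path(path).read_text())
    return SynthConfig(**data)


def save_config(cfg: SynthConfig, path: str | Path) -> None:
    from dataclasses import asdict

    Path(path).write_text(yaml.safe_dump(asdict(cfg)))
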
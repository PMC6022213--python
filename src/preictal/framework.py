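"""Streaming seizure-prediction loop: windows → features → labels → hourly alarm.

The recording is processed in disjoint one-hour blocks.  Every 20 s window
in a block is classified; if at least ``ceil(threshold · n_labels)`` of the
block's crisp labels are pre-ictal (126 of 180 at the default 70%), a
seizure alarm is raised at the moment the count first crosses the trigger.
Otherwise the block's ambiguous windows are forwarded to the active
learner, which may query the expert and retrain the base classifier before
the next block.  A trailing partial hour is processed with a
proportionally scaled trigger count; the accumulator resets at block
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .active import LabelledPool, Oracle, fit_bgmm, select_least_confident
from .classify import ClassifierModel, predict, train
from .features import extract_features
from .synth import Recording


@dataclass
class HourBlock:
    index: int
    start_s: float
    labels: np.ndarray  # per-window crisp labels within the block

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_preictal(self) -> int:
        return int(np.sum(self.labels == 1))


@dataclass
class Alarm:
    time_s: float
    block_index: int
    preictal_fraction: float


@dataclass
class AlarmSeries:
    alarms: list[Alarm] = field(default_factory=list)
    threshold: float = 0.70
    sph_s: float = 3600.0

    @property
    def times(self) -> list[float]:
        return [a.time_s for a in self.alarms]

    def __len__(self) -> int:
        return len(self.alarms)


@dataclass
class FrameworkConfig:
    window_length_s: float = 20.0
    block_length_s: float = 3600.0
    threshold: float = 0.70
    feature_set: str = "set_t"
    certainty_cutoff: float = 0.80
    batch_size: int = 1
    sph_s: float = 3600.0
    seed: int = 0


@dataclass
class FrameworkResult:
    alarm_series: AlarmSeries
    model: ClassifierModel
    blocks: list[HourBlock]
    query_log: list[int]


def trigger_count(n_labels: int, threshold: float) -> int:
    """Pre-ictal count needed to fire the alarm: ceil(threshold · n)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    return math.ceil(threshold * n_labels)


def threshold_decision(block: HourBlock, threshold: float = 0.70) -> bool:
    """Alarm decision for a completed block."""
    return block.n_preictal >= trigger_count(block.n_labels, threshold)


def _block_alarm_time(
    crisp: np.ndarray, block_start_s: float, window_s: float, threshold: float
) -> float | None:
    """Time the cumulative pre-ictal count first reaches the trigger, or None."""
    trig = trigger_count(len(crisp), threshold)
    if trig == 0:
        return block_start_s
    cum = np.cumsum(crisp == 1)
    hits = np.flatnonzero(cum >= trig)
    if hits.size == 0:
        return None
    return block_start_s + (hits[0] + 1) * window_s


def run_framework(
    rec: Recording,
    model: ClassifierModel,
    oracle: Oracle | None = None,
    cfg: FrameworkConfig | None = None,
) -> FrameworkResult:
    """Run the hourly prediction loop over a recording.

    With a budget-0 (or None) oracle the model is static and the output is
    exactly the thresholded classifier labels; otherwise each alarm-free
    block triggers one active-learning round on its ambiguous windows, with
    the recording's own window labels as the expert's answers.
    """
    cfg = cfg or FrameworkConfig()
    trigger_count(180, cfg.threshold)  # validate threshold early
    feats = extract_features(rec, cfg.feature_set, cfg.window_length_s)
    windows_per_block = int(cfg.block_length_s / cfg.window_length_s)
    n_windows = feats.n_windows
    n_blocks = max(math.ceil(n_windows / windows_per_block), 1 if n_windows else 0)

    pool = LabelledPool.create(feats.X, np.full(n_windows, -1, dtype=int))
    base_X, base_y = model.train_X, model.train_y
    series = AlarmSeries(threshold=cfg.threshold, sph_s=cfg.sph_s)
    blocks: list[HourBlock] = []
    query_log: list[int] = []

    for b in range(n_blocks):
        lo, hi = b * windows_per_block, min((b + 1) * windows_per_block, n_windows)
        out = predict(model, feats.X[lo:hi])
        start_s = lo * cfg.window_length_s
        block = HourBlock(index=b, start_s=start_s, labels=out.crisp)
        blocks.append(block)
        alarm_time = _block_alarm_time(out.crisp, start_s, cfg.window_length_s, cfg.threshold)
        if alarm_time is not None:
            series.alarms.append(
                Alarm(
                    time_s=alarm_time,
                    block_index=b,
                    preictal_fraction=block.n_preictal / max(block.n_labels, 1),
                )
            )
            continue
        if oracle is None or oracle.remaining <= 0:
            continue
        # active-learning round on this block's ambiguous, still-unlabelled windows
        pool.record_outputs(out.crisp.astype(float), out.soft, rows=np.arange(lo, hi))
        candidates = lo + np.flatnonzero(out.soft <= cfg.certainty_cutoff)
        candidates = np.intersect1d(candidates, pool.unlabelled)
        if candidates.size == 0:
            continue
        seen = LabelledPool.create(feats.X[:hi], pool.y[:hi], K=pool.K)
        seen.U, seen.V, seen.H = pool.U[:hi], pool.V[:hi], pool.H[:hi]
        lab = seen.labelled
        if lab.size and len(np.unique(seen.y[lab])) == 2:
            state = fit_bgmm(seen, seed=cfg.seed, max_iter=100)
            selected = select_least_confident(state, candidates, cfg.batch_size)
        else:  # no usable mixture yet: fall back to classifier uncertainty
            order = np.argsort(out.soft[candidates - lo], kind="stable")
            selected = candidates[order[: cfg.batch_size]]
        before = len(oracle.log)
        answers = oracle.query(selected)
        pool.y[selected[: len(answers)]] = answers
        query_log.extend(oracle.log[before:])
        lab = pool.labelled
        X_aug = np.vstack([base_X, feats.X[lab]])
        y_aug = np.concatenate([base_y, pool.y[lab]])
        model = train(X_aug, y_aug, algorithm=model.algorithm, seed=model.seed)
    return FrameworkResult(alarm_series=series, model=model, blocks=blocks, query_log=query_log)


def threshold_sweep(
    recordings: list[Recording],
    model: ClassifierModel,
    thresholds: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    cfg: FrameworkConfig | None = None,
) -> dict[float, int]:
    """Missed-seizure count per alarm threshold (static model, no querying).

    A seizure is missed when no alarm falls within [onset − SPH, onset).
    Counts are non-decreasing in the threshold: raising it never adds alarms.
    """
    cfg = cfg or FrameworkConfig()
    windows_per_block = int(cfg.block_length_s / cfg.window_length_s)
    per_rec: list[tuple[np.ndarray, list[float]]] = []
    for rec in recordings:
        feats = extract_features(rec, cfg.feature_set, cfg.window_length_s)
        out = predict(model, feats.X)
        per_rec.append((out.crisp, rec.seizure_onsets))

    missed: dict[float, int] = {}
    for th in thresholds:
        count = 0
        for crisp, onsets in per_rec:
            n_blocks = math.ceil(len(crisp) / windows_per_block)
            alarm_times = []
            for b in range(n_blocks):
                seg = crisp[b * windows_per_block : (b + 1) * windows_per_block]
                t = _block_alarm_time(seg, b * cfg.block_length_s, cfg.window_length_s, th)
                if t is not None:
                    alarm_times.append(t)
            for onset in onsets:
                hit = any(onset - cfg.sph_s <= t < onset for t in alarm_times)
                if not hit:
                    count += 1
        missed[th] = count
    return missed
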
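"""Sliding, overlapping analysis windows and time-domain features.

Each kinematic signal is divided into fixed-duration windows (100–600 ms,
nominally 300 ms) advancing by a 25 ms increment; every window is the unit
of continuous classification.  Six time-domain features — minimum, maximum,
mean, standard deviation, first sample, last sample — are extracted per
channel, giving ``6 * n_channels`` features per window.

Conventions fixed here (documented, not inferred):

* ms → samples uses round-to-nearest at the trial sampling rate; at 120 Hz
  the nominal 300 ms / 25 ms spec maps exactly to 36 / 3 samples.
* Windows advance from the start of the recorded signal (sample 0), not
  from THS1; the restriction of accuracy to post-TTO1 windows happens at
  evaluation time.
* A window is timestamped at its END — the causal instant at which a
  controller acting on that window could respond.  A window whose half-open
  span ``[start, end)`` ends exactly at the TTO1 sample has
  ``end_time_rel_TTO1 = 0``.
* Standard deviation uses the sample (n − 1) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KinematicTrial

#: Feature order within each channel block.
FEATURE_NAMES: tuple[str, ...] = ("min", "max", "mean", "std", "first", "last")


@dataclass(frozen=True)
class WindowSpec:
    """Window duration and step, in milliseconds."""

    length_ms: float = 300.0
    increment_ms: float = 25.0

    def __post_init__(self) -> None:
        if not 100.0 <= self.length_ms <= 600.0:
            raise ValueError(f"window length must lie in 100-600 ms, got {self.length_ms}")
        if self.increment_ms <= 0:
            raise ValueError(f"increment must be positive, got {self.increment_ms}")

    def length_samples(self, fs: float) -> int:
        n = int(round(self.length_ms * fs / 1000.0))
        if n < 2:
            raise ValueError(f"window of {self.length_ms} ms is under 2 samples at {fs} Hz")
        return n

    def increment_samples(self, fs: float) -> int:
        return max(1, int(round(self.increment_ms * fs / 1000.0)))


@dataclass(frozen=True)
class AnalysisWindow:
    """One window of one trial, half-open sample span ``[start, end)``."""

    trial_id: str
    start: int
    end: int
    end_time_rel_tto1_ms: float
    label: str


def window_count(n_samples: int, length: int, step: int) -> int:
    """Number of fully contained windows: floor((n - L) / s) + 1."""
    if n_samples < length:
        return 0
    return (n_samples - length) // step + 1


def segment_trial(trial: KinematicTrial, spec: WindowSpec) -> list[AnalysisWindow]:
    """Slice one trial into overlapping windows.

    Windows start at sample 0 and advance by the increment; the last window
    is the last fully contained one.  Every window inherits the parent
    trial's task label.
    """
    L = spec.length_samples(trial.fs)
    s = spec.increment_samples(trial.fs)
    n = trial.n_samples
    if n < L:
        raise ValueError(
            f"trial {trial.trial_id}: {n} samples is shorter than one "
            f"{spec.length_ms} ms window ({L} samples)"
        )
    out = []
    for start in range(0, n - L + 1, s):
        end = start + L
        rel_ms = (end - trial.events.TTO1) * 1000.0 / trial.fs
        out.append(AnalysisWindow(trial.trial_id, start, end, rel_ms, trial.task))
    assert len(out) == window_count(n, L, s)
    return out


def feature_names(channel_names: list[str]) -> list[str]:
    """``"<channel>.<feature>"`` in channel-major order."""
    return [f"{ch}.{feat}" for ch in channel_names for feat in FEATURE_NAMES]


def extract_features(window_signal: np.ndarray) -> np.ndarray:
    """Six time-domain features per channel for one window.

    ``window_signal`` has shape ``(L, n_channels)`` with ``L >= 2``.  Output
    is length ``6 * n_channels``, channel-major, features ordered as
    :data:`FEATURE_NAMES`.
    """
    w = np.asarray(window_signal, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if w.shape[0] < 2:
        raise ValueError(f"window needs >= 2 samples for a sample SD, got {w.shape[0]}")
    bad = ~np.isfinite(w)
    if bad.any():
        t, c = np.argwhere(bad)[0]
        raise ValueError(f"non-finite value in channel column {c} at window sample {t}")
    feats = np.stack(
        [w.min(axis=0), w.max(axis=0), w.mean(axis=0), w.std(axis=0, ddof=1), w[0], w[-1]],
        axis=1,
    )  # (C, 6)
    return feats.reshape(-1)


def _trial_feature_matrix(trial: KinematicTrial, spec: WindowSpec) -> np.ndarray:
    """Vectorized feature extraction for all windows of one trial."""
    L = spec.length_samples(trial.fs)
    s = spec.increment_samples(trial.fs)
    x = trial.signal
    if not np.isfinite(x).all():
        t, c = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(
            f"trial {trial.trial_id}: non-finite value in channel "
            f"{trial.channel_names[c]!r} at sample {t}"
        )
    # (n_windows, C, L) view, stepped by the increment
    win = np.lib.stride_tricks.sliding_window_view(x, L, axis=0)[::s]
    feats = np.stack(
        [
            win.min(axis=2),
            win.max(axis=2),
            win.mean(axis=2),
            win.std(axis=2, ddof=1),
            win[:, :, 0],
            win[:, :, -1],
        ],
        axis=2,
    )  # (n_windows, C, 6)
    return feats.reshape(feats.shape[0], -1)


@dataclass
class WindowDataset:
    """All windows of a cohort: features, labels, timing and provenance.

    ``features`` is ``(n_windows, 6 * n_channels)``; per-window metadata is
    aligned row-wise.  Rows are ordered by (subject, trial, window start).
    """

    features: np.ndarray
    labels: np.ndarray          # task class per window
    end_time_rel_tto1_ms: np.ndarray
    subject: np.ndarray
    trial_id: np.ndarray
    state: np.ndarray
    window_start: np.ndarray
    feature_names: list[str]
    spec: WindowSpec

    @property
    def n_windows(self) -> int:
        return int(self.features.shape[0])

    def rows_for_trial(self, trial_id: str) -> np.ndarray:
        return np.flatnonzero(self.trial_id == trial_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "end_time_rel_tto1_ms", self.end_time_rel_tto1_ms)
        df.insert(0, "window_start", self.window_start)
        df.insert(0, "state", self.state)
        df.insert(0, "label", self.labels)
        df.insert(0, "trial_id", self.trial_id)
        df.insert(0, "subject", self.subject)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, spec: WindowSpec) -> "WindowDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        meta = ["subject", "trial_id", "label", "state", "window_start", "end_time_rel_tto1_ms"]
        feat_cols = [c for c in df.columns if c not in meta]
        return cls(
            features=df[feat_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
            end_time_rel_tto1_ms=df["end_time_rel_tto1_ms"].to_numpy(dtype=float),
            subject=df["subject"].to_numpy(dtype=object),
            trial_id=df["trial_id"].to_numpy(dtype=object),
            state=df["state"].to_numpy(dtype=object),
            window_start=df["window_start"].to_numpy(dtype=int),
            feature_names=feat_cols,
            spec=spec,
        )


def build_dataset(trials: list[KinematicTrial], spec: WindowSpec) -> WindowDataset:
    """Window and featurize a list of trials into one dataset.

    All trials must share the channel set and sampling rate.  Ordering is
    deterministic: trials sorted by (subject, trial_id), windows by start.
    """
    if not trials:
        raise ValueError("no trials supplied")
    ref = trials[0]
    for t in trials:
        if t.channel_names != ref.channel_names:
            raise ValueError(
                f"trial {t.trial_id}: channel set differs from trial {ref.trial_id}"
            )
        if t.fs != ref.fs:
            raise ValueError(f"trial {t.trial_id}: fs={t.fs} differs from {ref.fs}")
    ordered = sorted(trials, key=lambda t: (t.subject_id, t.trial_id))
    blocks, labels, rel, subj, tid, state, wstart = [], [], [], [], [], [], []
    for t in ordered:
        wins = segment_trial(t, spec)
        blocks.append(_trial_feature_matrix(t, spec))
        labels.extend(w.label for w in wins)
        rel.extend(w.end_time_rel_tto1_ms for w in wins)
        wstart.extend(w.start for w in wins)
        subj.extend([t.subject_id] * len(wins))
        tid.extend([t.trial_id] * len(wins))
        state.extend([t.state] * len(wins))
    return WindowDataset(
        features=np.vstack(blocks),
        labels=np.asarray(labels, dtype=object),
        end_time_rel_tto1_ms=np.asarray(rel, dtype=float),
        subject=np.asarray(subj, dtype=object),
        trial_id=np.asarray(tid, dtype=object),
        state=np.asarray(state, dtype=object),
        window_start=np.asarray(wstart, dtype=int),
        feature_names=feature_names(ref.channel_names),
        spec=spec,
    )
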
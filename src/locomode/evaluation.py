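"""Per-subject leave-one-out evaluation, accuracy, confusion and error curves.

Evaluation follows the study protocol: classifiers are subject-specific;
each trial of a subject is held out once, a discriminant is fitted on the
windows of its paradigm's training pool, and every window of the held-out
trial receives a prediction.  Per-subject results are computed first and
then averaged across subjects.

Accuracy for a trial is the percentage of correctly classified windows
among those ending at or after TTO1 (the transition start) — windows of the
approach phase do not enter the score.  Confusion matrices are
row-normalized percentages over the same post-TTO1 window set, so each
diagonal element equals the window-pooled per-class accuracy.  Error-vs-time
curves place each window's 0/100 indicator on a TTO1-synchronized grid of
window end times, average across trials of a task, and truncate at the
shortest contributing trial.

Fitting many heavily overlapping pools is made cheap by caching per-trial
sufficient statistics (window count, feature sums, Gram matrix): any pool's
standardizer, class means and pooled covariance are exact linear
combinations of these, so a leave-one-out sweep costs one Cholesky solve
per distinct pool instead of one full pass over the windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KinematicTrial, TASKS
from .lda import (
    DEFAULT_SHRINKAGE,
    DiscriminantModel,
    Standardizer,
    _invert_spd,
    canonical_class_order,
    predict,
    shrink_covariance,
)
from .paradigms import ParadigmSpec, make_training_pool
from .windows import WindowDataset, WindowSpec, build_dataset


@dataclass
class _TrialStats:
    n: int
    total: np.ndarray   # column sums, (p,)
    gram: np.ndarray    # X^T X, (p, p)
    label: str


class FeatureStore:
    """Windowed features of a cohort plus per-trial sufficient statistics."""

    def __init__(self, trials: list[KinematicTrial], spec: WindowSpec,
                 dataset: WindowDataset | None = None):
        self.trials = {t.trial_id: t for t in trials}
        self.spec = spec
        self.dataset = dataset if dataset is not None else build_dataset(trials, spec)
        self._rows: dict[str, np.ndarray] = {}
        order = self.dataset.trial_id
        # contiguous row blocks per trial (build_dataset orders by trial)
        start = 0
        for i in range(1, len(order) + 1):
            if i == len(order) or order[i] != order[start]:
                self._rows[order[start]] = np.arange(start, i)
                start = i
        self._stats: dict[str, _TrialStats] = {}

    def rows(self, trial_id: str) -> np.ndarray:
        return self._rows[trial_id]

    def _trial_stats(self, trial_id: str) -> _TrialStats:
        st = self._stats.get(trial_id)
        if st is None:
            X = self.dataset.features[self._rows[trial_id]]
            st = _TrialStats(
                n=X.shape[0],
                total=X.sum(axis=0),
                gram=X.T @ X,
                label=self.trials[trial_id].task,
            )
            self._stats[trial_id] = st
        return st

    def fit_pool(self, pool_trial_ids: list[str],
                 shrinkage: float = DEFAULT_SHRINKAGE) -> DiscriminantModel:
        """Fit the discriminant on all windows of the pool trials.

        Produces the same model as :func:`locomode.lda.fit_lda` on the
        stacked window matrix (up to floating-point accumulation order).
        """
        stats = [self._trial_stats(tid) for tid in pool_trial_ids]
        labels = [s.label for s in stats]
        classes = canonical_class_order(labels)
        if len(classes) < 2:
            raise ValueError(f"training pool covers classes {classes}; need >= 2")
        p = stats[0].total.shape[0]
        N = sum(s.n for s in stats)
        grand = np.zeros(p)
        gram = np.zeros((p, p))
        for s in stats:
            grand += s.total
            gram += s.gram
        center = grand / N
        var = np.diag(gram) / N - center**2
        scale = np.sqrt(np.maximum(var, 0.0))
        scale = np.where(scale > 0, scale, 1.0)

        K = len(classes)
        means = np.empty((K, p))
        scatter = np.zeros((p, p))
        for i, c in enumerate(classes):
            cls = [s for s in stats if s.label == c]
            n_k = sum(s.n for s in cls)
            if n_k < 2:
                raise ValueError(f"class {c!r} has {n_k} training window(s); need >= 2")
            total_k = np.zeros(p)
            gram_k = np.zeros((p, p))
            for s in cls:
                total_k += s.total
                gram_k += s.gram
            mu = total_k / n_k
            means[i] = mu
            scatter += gram_k - n_k * np.outer(mu, mu)
        # standardized within-class scatter: the centering shift cancels
        cov = shrink_covariance(
            scatter / (N - K) / np.outer(scale, scale), shrinkage
        )
        return DiscriminantModel(
            classes=classes,
            means=(means - center) / scale,
            pooled_cov=cov,
            precision=_invert_spd(cov, shrinkage),
            priors=np.full(K, 1.0 / K),
            shrinkage=shrinkage,
            standardizer=Standardizer(center=center, scale=scale),
        )


def loo_evaluate(
    trials: list[KinematicTrial],
    paradigm: ParadigmSpec,
    spec: WindowSpec,
    shrinkage: float = DEFAULT_SHRINKAGE,
    store: FeatureStore | None = None,
    test_states: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-window predictions from per-subject leave-one-out evaluation.

    Every eligible test trial (optionally restricted to ``test_states``) is
    held out once; its paradigm pool is built from the same subject's
    remaining trials and a discriminant fitted on the pool's windows.
    Returns one row per predicted window with full provenance.
    """
    if store is None:
        store = FeatureStore(trials, spec)
    model_cache: dict[tuple, DiscriminantModel] = {}
    frames = []
    for trial in sorted(trials, key=lambda t: (t.subject_id, t.trial_id)):
        if test_states is not None and trial.state not in test_states:
            continue
        pool = make_training_pool(trials, trial, paradigm)
        key = tuple(sorted(t.trial_id for t in pool))
        model = model_cache.get(key)
        if model is None:
            try:
                model = store.fit_pool(list(key), shrinkage)
            except (ValueError, np.linalg.LinAlgError) as exc:
                raise type(exc)(
                    f"fitting failed for subject {trial.subject_id}, "
                    f"test trial {trial.trial_id}, paradigm {paradigm.name}: {exc}"
                ) from exc
            model_cache[key] = model
        rows = store.rows(trial.trial_id)
        ds = store.dataset
        pred = predict(model, ds.features[rows])
        frames.append(
            pd.DataFrame(
                {
                    "subject": trial.subject_id,
                    "trial_id": trial.trial_id,
                    "task": trial.task,
                    "state": trial.state,
                    "paradigm": paradigm.name,
                    "window_start": ds.window_start[rows],
                    "end_time_rel_tto1_ms": ds.end_time_rel_tto1_ms[rows],
                    "true": ds.labels[rows],
                    "pred": pred,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = out["true"] == out["pred"]
    return out


def compute_accuracy(pred, true, end_time_rel_tto1_ms) -> float:
    """Trial accuracy: correctly classified / total windows, from TTO1 on,
    as a percentage.  Windows ending before TTO1 are excluded."""
    pred = np.asarray(pred, dtype=object)
    true_arr = np.full(pred.shape, true, dtype=object) if np.isscalar(true) \
        else np.asarray(true, dtype=object)
    rel = np.asarray(end_time_rel_tto1_ms, dtype=float)
    post = rel >= 0.0
    if not post.any():
        raise ValueError("no windows end at or after TTO1; accuracy undefined")
    return 100.0 * float((pred[post] == true_arr[post]).sum()) / int(post.sum())


def per_trial_accuracy(preds: pd.DataFrame) -> pd.DataFrame:
    """Eq.-1 accuracy of every test trial in a prediction table."""
    rows = []
    for (subj, tid), g in preds.groupby(["subject", "trial_id"], sort=True):
        rows.append(
            {
                "subject": subj,
                "trial_id": tid,
                "task": g["task"].iloc[0],
                "state": g["state"].iloc[0],
                "paradigm": g["paradigm"].iloc[0],
                "accuracy": compute_accuracy(
                    g["pred"].to_numpy(), g["true"].to_numpy(),
                    g["end_time_rel_tto1_ms"].to_numpy(),
                ),
            }
        )
    return pd.DataFrame(rows)


def per_task_accuracy(preds: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (task, state): per-trial accuracies averaged within
    each subject first, then across subjects (the study's averaging order)."""
    trial_acc = per_trial_accuracy(preds)
    by_subject = (
        trial_acc.groupby(["subject", "task", "state"], sort=True)["accuracy"]
        .mean()
        .reset_index()
    )
    return (
        by_subject.groupby(["task", "state"], sort=True)["accuracy"]
        .mean()
        .reset_index()
    )


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion percentages: entry (i, j) is the share of
    class-i windows predicted as class j; every row sums to 100."""

    classes: list
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)

    def diagonal(self) -> dict:
        return {c: float(self.matrix[i, i]) for i, c in enumerate(self.classes)}


def compute_confusion_matrix(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Row-normalized confusion matrix over a window set."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if classes is None:
        classes = canonical_class_order(y_true)
    K = len(classes)
    counts = np.zeros((K, K))
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        counts[index[t], index.get(p, -1)] += 1 if p in index else 0
    totals = counts.sum(axis=1)
    empty = [classes[i] for i in np.flatnonzero(totals == 0)]
    if empty:
        raise ValueError(f"no windows observed for class(es) {empty}; matrix undefined")
    return ConfusionMatrix(classes=list(classes), matrix=100.0 * counts / totals[:, None])


@dataclass
class ErrorCurve:
    """Across-trial mean of per-window 0/100 error indicators on a
    TTO1-synchronized window-end-time grid, truncated to the span covered by
    every contributing trial (the shortest-trial rule)."""

    times_ms: np.ndarray
    error: np.ndarray
    n_trials: int
    event_marks_ms: dict[str, float]


def error_vs_time(
    preds: pd.DataFrame,
    trials: list[KinematicTrial],
    spec: WindowSpec,
) -> dict[str, ErrorCurve]:
    """One error curve per task from a prediction table.

    Each trial's windows are anchored at the first window ending at or
    after TTO1 (grid position 0); positions step by the window increment.
    The caller filters the table to one paradigm / state / window spec
    before calling.
    """
    trial_map = {t.trial_id: t for t in trials}
    fs = next(iter(trial_map.values())).fs
    step_ms = spec.increment_samples(fs) * 1000.0 / fs
    curves: dict[str, ErrorCurve] = {}
    for task, g in preds.groupby("task", sort=False):
        series = []
        marks: dict[str, list[float]] = {}
        lo_common, hi_common = -(10**9), 10**9
        for tid, gt in g.groupby("trial_id", sort=True):
            gt = gt.sort_values("window_start")
            starts = gt["window_start"].to_numpy()
            step = spec.increment_samples(fs)
            if len(starts) > 1 and not np.all(np.diff(starts) == step):
                raise ValueError(
                    f"trial {tid}: window starts are not on the {step}-sample "
                    "increment grid; error curves require a common grid"
                )
            rel = gt["end_time_rel_tto1_ms"].to_numpy()
            post = np.flatnonzero(rel >= 0.0)
            if post.size == 0:
                raise ValueError(f"trial {tid}: no windows end at or after TTO1")
            anchor = post[0]
            pos = np.arange(len(gt)) - anchor
            err = np.where(gt["correct"].to_numpy(), 0.0, 100.0)
            series.append((pos, err))
            lo_common = max(lo_common, pos[0])
            hi_common = min(hi_common, pos[-1])
            trial = trial_map[tid]
            for name, idx in trial.events.as_dict().items():
                if idx is not None:
                    marks.setdefault(name, []).append(
                        (idx - trial.events.TTO1) * 1000.0 / fs
                    )
        grid = np.arange(lo_common, hi_common + 1)
        stacked = np.stack([e[np.searchsorted(p, grid)] for p, e in series])
        curves[task] = ErrorCurve(
            times_ms=grid * step_ms,
            error=stacked.mean(axis=0),
            n_trials=len(series),
            event_marks_ms={
                k: float(np.mean(v)) for k, v in marks.items() if len(v) == len(series)
            },
        )
    return curves


@dataclass
class EvaluationReport:
    """Tidy results of a paradigm x window-length sweep."""

    #: one row per (subject, task, state, paradigm, window length)
    accuracy: pd.DataFrame
    #: window-pooled confusion matrix per (paradigm, state) at the nominal window
    confusions: dict[tuple[str, str], ConfusionMatrix]
    #: error curve per (paradigm, state, task) at the nominal window
    error_curves: dict[tuple[str, str, str], ErrorCurve]
    #: raw per-window predictions at the nominal window, per paradigm
    predictions: dict[str, pd.DataFrame]

    def overall_accuracy(self, paradigm: str, state: str,
                         window_ms: float, pooled: bool = True) -> float:
        """Overall accuracy across tasks: window-pooled by default, or the
        unweighted mean of per-task accuracies."""
        preds = self.predictions[paradigm]
        sub = preds[(preds["state"] == state)]
        if pooled:
            post = sub[sub["end_time_rel_tto1_ms"] >= 0.0]
            return 100.0 * float(post["correct"].mean())
        acc = per_task_accuracy(sub)
        return float(acc[acc["state"] == state]["accuracy"].mean())


def run_evaluation(
    trials: list[KinematicTrial],
    paradigms: list[ParadigmSpec],
    window_specs: list[WindowSpec],
    shrinkage: float = DEFAULT_SHRINKAGE,
    nominal: WindowSpec | None = None,
) -> EvaluationReport:
    """Full sweep: per-subject LOO for every paradigm and window length.

    Confusion matrices and error curves are computed at the nominal window
    (300 ms / 25 ms unless given).
    """
    if nominal is None:
        nominal = WindowSpec(300.0, 25.0)
        if nominal not in window_specs:
            nominal = window_specs[0]
    acc_rows = []
    confusions: dict[tuple[str, str], ConfusionMatrix] = {}
    error_curves: dict[tuple[str, str, str], ErrorCurve] = {}
    predictions: dict[str, pd.DataFrame] = {}
    for spec in window_specs:
        store = FeatureStore(trials, spec)
        for paradigm in paradigms:
            preds = loo_evaluate(trials, paradigm, spec, shrinkage, store=store)
            tacc = per_trial_accuracy(preds)
            by_subject = (
                tacc.groupby(["subject", "task", "state"], sort=True)["accuracy"]
                .mean()
                .reset_index()
            )
            by_subject["paradigm"] = paradigm.name
            by_subject["window_ms"] = spec.length_ms
            acc_rows.append(by_subject)
            if spec == nominal:
                predictions[paradigm.name] = preds
                for state in ("A", "UA"):
                    sub = preds[preds["state"] == state]
                    post = sub[sub["end_time_rel_tto1_ms"] >= 0.0]
                    confusions[(paradigm.name, state)] = compute_confusion_matrix(
                        post["true"], post["pred"],
                        classes=[c for c in TASKS if c in set(post["true"])],
                    )
                    for task, curve in error_vs_time(sub, trials, spec).items():
                        error_curves[(paradigm.name, state, task)] = curve
    return EvaluationReport(
        accuracy=pd.concat(acc_rows, ignore_index=True),
        confusions=confusions,
        error_curves=error_curves,
        predictions=predictions,
    )
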
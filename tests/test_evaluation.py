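"""Evaluation: accuracy from TTO1, confusion conservation, error-vs-time
alignment, leave-one-out coverage and the sufficient-statistics fast fit."""

import numpy as np
import pandas as pd
import pytest

from locomode import (
    CohortConfig,
    FeatureStore,
    ParadigmSpec,
    TASKS,
    WindowSpec,
    compute_accuracy,
    compute_confusion_matrix,
    error_vs_time,
    fit_lda,
    loo_evaluate,
    per_trial_accuracy,
    predict,
)
from locomode.evaluation import per_task_accuracy
from locomode.synthetic import generate_cohort, noise_free


SPEC = WindowSpec(300.0, 25.0)


def test_fast_fit_matches_direct_fit(small_cohort, small_store):
    pool_ids = sorted(
        t.trial_id for t in small_cohort if t.subject_id == "S01" and t.state == "A"
    )[:20]
    fast = small_store.fit_pool(pool_ids, shrinkage=0.01)
    rows = np.concatenate([small_store.rows(tid) for tid in pool_ids])
    ds = small_store.dataset
    direct = fit_lda(ds.features[rows], ds.labels[rows], shrinkage=0.01)
    assert fast.classes == direct.classes
    np.testing.assert_allclose(fast.standardizer.center, direct.standardizer.center, rtol=1e-9)
    np.testing.assert_allclose(fast.standardizer.scale, direct.standardizer.scale, rtol=1e-9)
    np.testing.assert_allclose(fast.means, direct.means, rtol=1e-8, atol=1e-10)
    np.testing.assert_allclose(fast.pooled_cov, direct.pooled_cov, rtol=1e-7, atol=1e-9)
    Xt = ds.features[small_store.rows(pool_ids[0])]
    np.testing.assert_array_equal(predict(fast, Xt), predict(direct, Xt))


def test_accuracy_counts_only_post_tto1_windows():
    pred = np.array(["CO"] * 4 + ["W"] * 2 + ["CO"] * 8 + ["SS"] * 2, dtype=object)
    rel = np.concatenate([np.arange(-6, 0), np.arange(0, 10)]) * 25.0
    # post-TTO1: 10 windows, 8 correct
    assert compute_accuracy(pred, "CO", rel) == pytest.approx(80.0)
    # flipping every pre-TTO1 prediction must not change the value
    pred2 = pred.copy()
    pred2[:6] = "SSS"
    assert compute_accuracy(pred2, "CO", rel) == pytest.approx(80.0)


def test_accuracy_bounds():
    rel = np.arange(5) * 25.0
    assert compute_accuracy(np.array(["W"] * 5, dtype=object), "W", rel) == 100.0
    assert compute_accuracy(np.array(["CO"] * 5, dtype=object), "W", rel) == 0.0
    with pytest.raises(ValueError, match="TTO1"):
        compute_accuracy(np.array(["W"], dtype=object), "W", np.array([-50.0]))


def test_confusion_perfect_and_constant():
    y = np.array(sum(([c] * 4 for c in TASKS), []), dtype=object)
    cm = compute_confusion_matrix(y, y)
    np.testing.assert_allclose(cm.matrix, 100.0 * np.eye(5))
    cm2 = compute_confusion_matrix(y, np.array(["SS"] * 20, dtype=object))
    np.testing.assert_allclose(cm2.matrix[:, cm2.classes.index("SS")], 100.0)
    assert cm2.matrix.sum() == pytest.approx(500.0)


def test_confusion_matches_brute_force_tally(rng):
    classes = ["W", "CO", "SS"]
    y = rng.choice(classes, size=400).astype(object)
    p = rng.choice(classes, size=400).astype(object)
    cm = compute_confusion_matrix(y, p, classes=classes)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            n_ij = sum(1 for a, b in zip(y, p) if a == ci and b == cj)
            n_i = sum(1 for a in y if a == ci)
            assert cm.matrix[i, j] == pytest.approx(100.0 * n_ij / n_i)
    np.testing.assert_allclose(cm.matrix.sum(axis=1), 100.0, atol=1e-9)


def test_confusion_empty_class_error():
    y = np.array(["W", "W"], dtype=object)
    with pytest.raises(ValueError, match="CO"):
        compute_confusion_matrix(y, y, classes=["W", "CO"])


def test_diagonal_equals_pooled_accuracy_same_window_set(small_cohort, small_store):
    """Cross-module consistency: confusion diagonal is the window-pooled
    per-class accuracy over the identical post-TTO1 window set."""
    preds = loo_evaluate(
        small_cohort, ParadigmSpec("ZeroTrial"), SPEC, store=small_store, test_states=("A",)
    )
    post = preds[preds["end_time_rel_tto1_ms"] >= 0.0]
    cm = compute_confusion_matrix(post["true"], post["pred"])
    for i, c in enumerate(cm.classes):
        sub = post[post["true"] == c]
        assert cm.matrix[i, i] == pytest.approx(100.0 * sub["correct"].mean())


def _preds_frame(trial_id, task, rel_times, correct, paradigm="ZeroTrial"):
    n = len(rel_times)
    return pd.DataFrame(
        {
            "subject": "S01",
            "trial_id": trial_id,
            "task": task,
            "state": "UA",
            "paradigm": paradigm,
            "window_start": np.arange(n) * 3,
            "end_time_rel_tto1_ms": rel_times,
            "true": task,
            "pred": np.where(correct, task, "W"),
            "correct": correct,
        }
    )


def _curve_trial(trial_id, n, tto1, small_channels):
    from locomode.core import GaitEvents, KinematicTrial

    return KinematicTrial(
        subject_id="S01",
        task="CO",
        state="UA",
        fs=120.0,
        signal=np.zeros((n, len(small_channels))),
        channels=list(small_channels),
        events=GaitEvents(THS1=2, TTO1=tto1, THS2=min(n - 1, tto1 + 40), cue=tto1 - 10),
        trial_id=trial_id,
    )


def test_error_curve_single_trial_is_its_own_sequence(small_channels):
    rel = np.arange(-4, 8) * 25.0
    correct = np.tile([True, False], 6)
    preds = _preds_frame("t1", "CO", rel, correct)
    trial = _curve_trial("t1", 200, 48, small_channels)
    curves = error_vs_time(preds, [trial], SPEC)
    c = curves["CO"]
    np.testing.assert_allclose(c.error, np.where(correct, 0.0, 100.0))
    np.testing.assert_allclose(c.times_ms, rel)
    assert c.n_trials == 1
    assert c.event_marks_ms["TTO1"] == pytest.approx(0.0)


def test_error_curve_right_wrong_pair_is_flat_fifty(small_channels):
    rel = np.arange(-3, 6) * 25.0
    right = _preds_frame("t1", "CO", rel, np.ones(len(rel), bool))
    wrong = _preds_frame("t2", "CO", rel, np.zeros(len(rel), bool))
    trials = [
        _curve_trial("t1", 200, 48, small_channels),
        _curve_trial("t2", 200, 48, small_channels),
    ]
    curve = error_vs_time(pd.concat([right, wrong]), trials, SPEC)["CO"]
    np.testing.assert_allclose(curve.error, 50.0)
    assert curve.n_trials == 2


def test_error_curve_truncates_at_shortest_trial(small_channels):
    long = _preds_frame("t1", "CO", np.arange(-5, 12) * 25.0, np.ones(17, bool))
    short = _preds_frame("t2", "CO", np.arange(-2, 4) * 25.0, np.ones(6, bool))
    trials = [
        _curve_trial("t1", 300, 51, small_channels),
        _curve_trial("t2", 120, 42, small_channels),
    ]
    curve = error_vs_time(pd.concat([long, short]), trials, SPEC)["CO"]
    assert len(curve.times_ms) == 6
    assert curve.times_ms[0] == -50.0 and curve.times_ms[-1] == 75.0


def test_error_curve_grid_mismatch_rejected(small_channels):
    preds = _preds_frame("t1", "CO", np.arange(-2, 4) * 25.0, np.ones(6, bool))
    preds.loc[3, "window_start"] = 11  # off the 3-sample increment grid
    with pytest.raises(ValueError, match="increment"):
        error_vs_time(preds, [_curve_trial("t1", 120, 42, small_channels)], SPEC)


def test_each_trial_held_out_exactly_once(small_cohort, small_store):
    preds = loo_evaluate(small_cohort, ParadigmSpec("UA_A", 2), SPEC, store=small_store)
    tested = preds.groupby("trial_id").size()
    assert set(tested.index) == {t.trial_id for t in small_cohort}
    acc = per_trial_accuracy(preds)
    assert len(acc) == len(small_cohort)


def test_separable_limit_reaches_perfect_anticipated_accuracy(small_channels):
    """Zero-noise, zero-jitter cohort: anticipated test trials classify
    perfectly after TTO1 under Zero-Trial training."""
    cfg = noise_free(
        CohortConfig(n_subjects=1, trials_per_condition=3,
                     channel_set=list(small_channels), seed=2)
    )
    trials = generate_cohort(cfg)
    preds = loo_evaluate(trials, ParadigmSpec("ZeroTrial"), SPEC, test_states=("A",))
    acc = per_task_accuracy(preds)
    assert (acc["accuracy"] == 100.0).all()


def test_state_restriction(small_cohort, small_store):
    preds = loo_evaluate(
        small_cohort, ParadigmSpec("ZeroTrial"), SPEC, store=small_store, test_states=("UA",)
    )
    assert set(preds["state"]) == {"UA"}
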
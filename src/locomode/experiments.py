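"""Canned experiment drivers for the study's headline comparisons.

These wrap the evaluation engine into the specific contrasts the analysis
reports: anticipated vs unanticipated recognition under anticipated-only
training, and the recovery of unanticipated accuracy as bouts of the target
task enter the training pool.
"""

from __future__ import annotations

import numpy as np

from .core import MIXED_TRANSITIONS, SINGLE_TRANSITIONS
from .evaluation import FeatureStore, loo_evaluate, per_task_accuracy
from .paradigms import ParadigmSpec
from .synthetic import CohortConfig, generate_cohort
from .windows import WindowSpec

NOMINAL = WindowSpec(300.0, 25.0)


def paradigm_comparison(
    seed: int,
    config: CohortConfig | None = None,
    shrinkage: float = 0.01,
    spec: WindowSpec = NOMINAL,
) -> dict:
    """Zero-/One-/Two-Trial comparison on one synthetic cohort.

    Returns per-task unanticipated accuracies per paradigm, the anticipated
    Zero-Trial accuracies, and the derived headline quantities: the
    anticipated-unanticipated gap, the paradigm progression of mean
    unanticipated accuracy, and the One-Trial improvement split into mixed
    (COS/SSS) and single (CO/SS) transitions.
    """
    if config is None:
        config = CohortConfig(seed=seed)
    trials = generate_cohort(config)
    store = FeatureStore(trials, spec)
    bout_seed = seed + 1

    per_task: dict[str, dict[str, float]] = {}
    preds = loo_evaluate(trials, ParadigmSpec("ZeroTrial", bout_seed), spec, shrinkage, store=store)
    acc = per_task_accuracy(preds)
    per_task["A_ZeroTrial"] = dict(
        zip(acc[acc["state"] == "A"]["task"], acc[acc["state"] == "A"]["accuracy"])
    )
    per_task["UA_ZeroTrial"] = dict(
        zip(acc[acc["state"] == "UA"]["task"], acc[acc["state"] == "UA"]["accuracy"])
    )
    for name in ("OneTrial", "TwoTrials"):
        preds = loo_evaluate(
            trials, ParadigmSpec(name, bout_seed), spec, shrinkage,
            store=store, test_states=("UA",),
        )
        acc = per_task_accuracy(preds)
        per_task[f"UA_{name}"] = dict(zip(acc["task"], acc["accuracy"]))

    def mean_over(d: dict[str, float], tasks=None) -> float:
        keys = tasks if tasks is not None else list(d)
        return float(np.mean([d[k] for k in keys]))

    ua0, ua1, ua2 = (per_task[f"UA_{p}"] for p in ("ZeroTrial", "OneTrial", "TwoTrials"))
    gain1 = {t: ua1[t] - ua0[t] for t in ua0}
    return {
        "per_task": per_task,
        "anticipated_zero": mean_over(per_task["A_ZeroTrial"]),
        "unanticipated_zero": mean_over(ua0),
        "unanticipated_one": mean_over(ua1),
        "unanticipated_two": mean_over(ua2),
        "one_trial_gain_mixed": mean_over(gain1, MIXED_TRANSITIONS),
        "one_trial_gain_single": mean_over(gain1, SINGLE_TRANSITIONS),
    }
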
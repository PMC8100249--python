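"""Training paradigms: which trials may train the classifier for a test trial.

Classifiers are subject-specific, so every pool is restricted to the test
trial's subject, and the held-out test trial is never in its own pool.

* ``ZeroTrial`` — anticipated trials only.
* ``OneTrial`` — anticipated trials plus one bout (trial) of the
  unanticipated target task, i.e. the task of the held-out test trial.
* ``TwoTrials`` — anticipated trials plus two such bouts.
* ``AllUA`` — unanticipated trials only.
* ``UA_A`` — all anticipated and unanticipated trials.

Target bouts are drawn without replacement from the subject's unanticipated
trials of the test task, excluding the test trial itself, with a seeded RNG
so runs are reproducible; pools are rebuilt per test trial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import KinematicTrial

PARADIGM_NAMES: tuple[str, ...] = ("ZeroTrial", "OneTrial", "TwoTrials", "AllUA", "UA_A")

_TARGET_BOUTS = {"ZeroTrial": 0, "OneTrial": 1, "TwoTrials": 2, "AllUA": 0, "UA_A": 0}


@dataclass(frozen=True)
class ParadigmSpec:
    """One training paradigm plus the seed governing bout selection."""

    name: str
    bout_selection_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in PARADIGM_NAMES:
            raise ValueError(f"unknown paradigm {self.name!r}; expected one of {PARADIGM_NAMES}")

    @property
    def n_target_bouts(self) -> int:
        return _TARGET_BOUTS[self.name]


def make_training_pool(
    all_trials: list[KinematicTrial],
    test_trial: KinematicTrial,
    paradigm: ParadigmSpec,
) -> list[KinematicTrial]:
    """The training trials for one held-out test trial under one paradigm.

    Raises ``ValueError`` if the subject has fewer unanticipated trials of
    the target task (excluding the test trial) than the requested bouts.
    """
    subject = [t for t in all_trials if t.subject_id == test_trial.subject_id]
    others = [t for t in subject if t.trial_id != test_trial.trial_id]
    a_pool = [t for t in others if t.state == "A"]
    ua_pool = [t for t in others if t.state == "UA"]

    if paradigm.name == "ZeroTrial":
        return a_pool
    if paradigm.name == "AllUA":
        return ua_pool
    if paradigm.name == "UA_A":
        return a_pool + ua_pool

    # OneTrial / TwoTrials: anticipated data plus seeded target-task bouts
    candidates = sorted(
        (t for t in ua_pool if t.task == test_trial.task), key=lambda t: t.trial_id
    )
    k = paradigm.n_target_bouts
    if len(candidates) < k:
        raise ValueError(
            f"paradigm {paradigm.name} needs {k} unanticipated {test_trial.task} "
            f"bout(s) for subject {test_trial.subject_id} excluding test trial "
            f"{test_trial.trial_id}, but only {len(candidates)} are available"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [paradigm.bout_selection_seed & 0x7FFFFFFF,
             zlib.crc32(test_trial.trial_id.encode())]
        )
    )
    chosen = rng.choice(len(candidates), size=k, replace=False)
    return a_pool + [candidates[i] for i in sorted(chosen)]
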
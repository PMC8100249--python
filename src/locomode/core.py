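"""Shared domain types for the locomotion-mode classification pipeline.

The pipeline operates on per-trial multichannel kinematic time series
(segment linear accelerations, segment angular velocities, joint angles)
sampled at 120 Hz.  Five locomotion modes are distinguished:

* ``W``   — straight-line level walking;
* ``CO``  — crossover cut (swing leg crosses over the stance leg);
* ``SS``  — sidestep cut (swing leg placed laterally, away from the stance leg);
* ``COS`` — crossover cut followed by stair ascent (a "mixed" transition);
* ``SSS`` — sidestep cut followed by stair ascent (a "mixed" transition).

Each trial is performed either anticipated (``A`` — the subject knows the
upcoming task) or unanticipated (``UA`` — a randomized auditory cue arrives
during the trailing-leg swing phase, half a step before the transition point).

Trials are annotated with gait events: the first/second/third trailing-leg
heel strikes (THS1/THS2/THS3), the first trailing-leg toe off (TTO1, the
transition start and the synchronization point for all time-resolved
analyses), and — for mixed transitions — the second leading-leg toe off
(LTO2, the stair-ascent start).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical class order.  Tie-breaking in the classifier and all reports
#: follow this order.
TASKS: tuple[str, ...] = ("W", "CO", "SS", "COS", "SSS")

STATES: tuple[str, ...] = ("A", "UA")

SINGLE_TRANSITIONS: tuple[str, ...] = ("CO", "SS")
MIXED_TRANSITIONS: tuple[str, ...] = ("COS", "SSS")

#: Default sampling rate of the motion-capture-derived kinematics, Hz.
DEFAULT_FS: float = 120.0

QUANTITIES: tuple[str, ...] = ("linear_acceleration", "angular_velocity", "joint_angle")


@dataclass(frozen=True)
class ChannelSpec:
    """One kinematic channel: a quantity measured on a segment or joint.

    Parameters
    ----------
    name
        Unique channel name within a cohort, e.g. ``"shank_l.gyro.z"``.
    source
        Segment (``foot/shank/thigh`` per side, ``trunk``, ``pelvis``) or
        joint (``ankle/knee/hip`` per side) identifier.
    quantity
        One of :data:`QUANTITIES`.
    axis
        ``"x"``, ``"y"``, ``"z"`` for triaxial quantities; a single named
        axis (e.g. ``"flexion"``) for uniaxial joint angles.
    """

    name: str
    source: str
    quantity: str
    axis: str

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r} for channel {self.name!r}")


def default_channel_set() -> list[ChannelSpec]:
    """The 58-channel set used throughout.

    8 segments (bilateral foot, shank, thigh; trunk; pelvis) each contribute
    triaxial linear acceleration and triaxial angular velocity (48 channels),
    plus bilateral ankle dorsi-plantarflexion angle (2), bilateral knee
    flexion-extension angle (2), and bilateral three-dimensional hip rotation
    angles (6): 58 channels total.
    """
    channels: list[ChannelSpec] = []
    segments = ["foot_l", "foot_r", "shank_l", "shank_r", "thigh_l", "thigh_r", "trunk", "pelvis"]
    for seg in segments:
        for axis in "xyz":
            channels.append(ChannelSpec(f"{seg}.acc.{axis}", seg, "linear_acceleration", axis))
        for axis in "xyz":
            channels.append(ChannelSpec(f"{seg}.gyro.{axis}", seg, "angular_velocity", axis))
    for side in ("l", "r"):
        channels.append(ChannelSpec(f"ankle_{side}.angle.flexion", f"ankle_{side}", "joint_angle", "flexion"))
    for side in ("l", "r"):
        channels.append(ChannelSpec(f"knee_{side}.angle.flexion", f"knee_{side}", "joint_angle", "flexion"))
    for side in ("l", "r"):
        for axis in "xyz":
            channels.append(ChannelSpec(f"hip_{side}.angle.{axis}", f"hip_{side}", "joint_angle", axis))
    names = [c.name for c in channels]
    assert len(names) == len(set(names)) == 58
    return channels


@dataclass(frozen=True)
class GaitEvents:
    """Gait-event sample indices for one trial.

    ``THS1 < TTO1 < THS2`` always; mixed transitions additionally carry
    ``THS2 <= LTO2 < THS3``.  ``cue`` is present for unanticipated trials
    only and satisfies ``THS1 <= cue < TTO1`` (the auditory cue arrives at
    the beginning of the trailing-leg swing phase, half a step before the
    transition point).  For walking and single transitions THS2 serves as
    the nominal end-of-locomotion marker and LTO2/THS3 are absent.
    """

    THS1: int
    TTO1: int
    THS2: int
    LTO2: int | None = None
    THS3: int | None = None
    cue: int | None = None

    def __post_init__(self) -> None:
        if not (self.THS1 < self.TTO1 < self.THS2):
            raise ValueError(
                f"gait events must satisfy THS1 < TTO1 < THS2, got "
                f"THS1={self.THS1}, TTO1={self.TTO1}, THS2={self.THS2}"
            )
        if (self.LTO2 is None) != (self.THS3 is None):
            raise ValueError("LTO2 and THS3 must be both present or both absent")
        if self.LTO2 is not None:
            if not (self.THS2 <= self.LTO2 < self.THS3):
                raise ValueError(
                    f"gait events must satisfy THS2 <= LTO2 < THS3, got "
                    f"THS2={self.THS2}, LTO2={self.LTO2}, THS3={self.THS3}"
                )
        if self.cue is not None and not (self.THS1 <= self.cue < self.TTO1):
            raise ValueError(
                f"cue must satisfy THS1 <= cue < TTO1, got "
                f"THS1={self.THS1}, cue={self.cue}, TTO1={self.TTO1}"
            )

    @property
    def last_event(self) -> int:
        return self.THS3 if self.THS3 is not None else self.THS2

    def as_dict(self) -> dict[str, int | None]:
        return {
            "THS1": self.THS1,
            "TTO1": self.TTO1,
            "THS2": self.THS2,
            "LTO2": self.LTO2,
            "THS3": self.THS3,
            "cue": self.cue,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitEvents":
        return cls(
            THS1=int(d["THS1"]),
            TTO1=int(d["TTO1"]),
            THS2=int(d["THS2"]),
            LTO2=None if d.get("LTO2") is None else int(d["LTO2"]),
            THS3=None if d.get("THS3") is None else int(d["THS3"]),
            cue=None if d.get("cue") is None else int(d["cue"]),
        )


@dataclass
class KinematicTrial:
    """One trial: a channel matrix plus metadata.

    ``signal`` has shape ``(n_samples, n_channels)``; column order matches
    ``channels``.  ``trial_id`` is unique within a cohort.
    """

    subject_id: str
    task: str
    state: str
    fs: float
    signal: np.ndarray
    channels: list[ChannelSpec]
    events: GaitEvents
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.channels):
            raise ValueError(
                f"trial {self.trial_id or '<unnamed>'}: signal shape {self.signal.shape} "
                f"does not match {len(self.channels)} channels"
            )
        n = self.signal.shape[0]
        for name, idx in self.events.as_dict().items():
            if idx is not None and not (0 <= idx < n):
                raise ValueError(
                    f"trial {self.trial_id or '<unnamed>'}: event {name}={idx} "
                    f"outside [0, {n})"
                )
        if not self.trial_id:
            self.trial_id = f"{self.subject_id}_{self.task}_{self.state}"

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.signal.shape[1])

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def is_mixed(self) -> bool:
        return self.task in MIXED_TRANSITIONS
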
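"""Seeded synthetic gait-kinematics cohorts.

The generator emulates the statistical structure of a five-subject cutting /
cut-to-stair study so every downstream stage (windowing, discriminant
training, paradigm evaluation) is testable without recorded data.  Per
channel ``c`` and sample ``t`` the signal model is

    x(t) = base_c(phi(t)) + d[task, c] * g(t) * s(t) + u[subject, c] + eps(t)

where ``phi`` is a piecewise-linear gait phase anchored at the trial's gait
events, ``g`` is the anticipation gate (for anticipated trials it ramps from
0 to 1 starting at THS1 — preparatory adaptation that is complete before the
transition at TTO1; for unanticipated trials it is 0 before the auditory cue
and ramps only after it), ``s`` is 1 except for mixed transitions where it
becomes ``stair_deviation_gain`` after LTO2 (stair ascent recruits larger
multi-plane joint excursions), ``u`` is a per-(subject, channel) offset drawn
once, and ``eps`` is white Gaussian measurement/physiological noise.  The
executed deviation ``d`` is itself a trial-level random effect,
``d = d[task] + eta_trial`` with ``eta_trial ~ N(0, sigma_trial^2 I)`` drawn
once per trial: every execution of a transition is idiosyncratic, and
``sigma_trial`` is substantially larger for unanticipated trials —
unanticipated perturbations raise trial-to-trial kinematic variability, so
no single bout fully represents another unanticipated trial.

Unanticipated execution is not merely a delayed copy of the anticipated
pattern: reacting to a cue mid-swing forces a compensatory strategy.  Each
task therefore has two deviation patterns — an anticipated one and an
unanticipated one — that differ by (i) a dense task-generic compensatory
shift (``ua_shift_amp``), (ii) a task-specific execution difference reusing
the planned similarity geometry (``ua_pattern_scale``), and (iii) an
attenuated stair component (``ua_stair_scale``): a reactive cut-to-stair
approach completes only part of the stair preparation, which parks
unanticipated mixed-transition patterns between their own class and their
level-ground counterpart.  A classifier trained only on anticipated data
misreads these shifted patterns — the kinematic dissimilarity between
anticipatory states that makes anticipated-only training generalize
poorly — while a bout of the target task exposes the unanticipated pattern
and restores whatever separation the trial-to-trial variability leaves
intact.  Walking has zero planned deviation, but unanticipated walking
still carries its gated compensatory shift: a randomized cue perturbs gait
even when it says "walk".

Task deviation patterns are fixed properties of the tasks (drawn once from a
constant internal seed, not the cohort seed): the crossover and sidestep
patterns are strongly correlated — the two cut styles share most of their
kinematic signature, which is what makes them mutually confusable — and each
mixed transition equals its cut style's pattern plus a shared stair
component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DEFAULT_FS,
    MIXED_TRANSITIONS,
    STATES,
    TASKS,
    ChannelSpec,
    GaitEvents,
    KinematicTrial,
    default_channel_set,
)

#: Constant seed for the task geometry (base waveforms and deviation
#: patterns).  These play the role of the tasks' biomechanics, which are
#: fixed across replications of the study; the cohort seed varies subjects,
#: event timing and noise only.
_GEOMETRY_SEED = 715

#: Gait phase assigned to each event (strides since THS1); phase is
#: piecewise-linear between consecutive events and extrapolated beyond them.
_EVENT_PHASE = {"THS1": 0.0, "TTO1": 0.6, "THS2": 1.0, "LTO2": 1.4, "THS3": 2.0}


@dataclass(frozen=True)
class EventTiming:
    """Mean and jitter SD (both in ms from trial start) for each gait event,
    the cue, and the per-task tail appended after the last event."""

    ths1_ms: tuple[float, float] = (100.0, 20.0)
    cue_ms: tuple[float, float] = (400.0, 30.0)
    tto1_ms: tuple[float, float] = (700.0, 30.0)
    ths2_ms: tuple[float, float] = (1300.0, 40.0)
    lto2_ms: tuple[float, float] = (1500.0, 40.0)
    ths3_ms: tuple[float, float] = (2100.0, 50.0)
    #: signal recorded after the last event, per task family (ms); walking
    #: trials are structurally shortest and mixed transitions longest, so the
    #: shortest-trial truncation rule in the evaluation is exercised.
    tail_ms: dict = field(
        default_factory=lambda: {"W": 150.0, "single": 350.0, "mixed": 250.0}
    )

    def means(self) -> list[float]:
        return [self.ths1_ms[0], self.cue_ms[0], self.tto1_ms[0], self.ths2_ms[0], self.lto2_ms[0], self.ths3_ms[0]]


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    The defaults are the emulated study conditions: 5 subjects, 5 trials per
    (task, state) condition, the 58-channel kinematic set at 120 Hz, and
    signal/noise scales calibrated so that anticipated trials classify with
    high accuracy while unanticipated trials suffer the characteristic
    crossover/sidestep confusion until target-task bouts enter training.
    """

    n_subjects: int = 5
    trials_per_condition: int = 5
    channel_set: list[ChannelSpec] = field(default_factory=default_channel_set)
    #: per-channel Fourier coefficients over gait phase; filled from the
    #: fixed task geometry when None
    base_waveform: dict | None = None
    #: per (task, channel) deviation amplitude; filled from the fixed task
    #: geometry when None
    task_deviation: dict | None = None
    #: per (task, channel) deviation pattern of unanticipated trials;
    #: filled from the fixed task geometry when None
    ua_task_deviation: dict | None = None
    #: amplitude of the cut deviation pattern (per-channel SD)
    cut_amp: float = 0.35
    #: amplitude of the stair component shared by COS/SSS
    stair_amp: float = 0.6
    #: correlation between the crossover and sidestep deviation patterns
    style_corr: float = 0.97
    #: correlation between the COS and SSS stair components: the stair
    #: approach differs by entry style (foot placement into the staircase),
    #: so the two mixed transitions share only part of their stair signature
    stair_style_corr: float = 0.6
    #: multiplier (>= 1) applied to COS/SSS deviations after LTO2
    stair_deviation_gain: float = 1.6
    #: amplitude of the task-generic compensatory shift shared by all
    #: unanticipated trials (per-channel SD); 0 makes unanticipated
    #: execution a delayed copy of the anticipated pattern
    ua_shift_amp: float = 0.5
    #: scale of the task-specific part of the unanticipated execution
    #: pattern, relative to the planned deviation amplitudes; it reuses the
    #: planned patterns' similarity geometry (near-identical cut styles,
    #: partially distinct stair components)
    ua_pattern_scale: float = 0.5
    #: fraction of the stair component expressed in unanticipated mixed
    #: transitions (reactive execution completes the stair preparation only
    #: partially)
    ua_stair_scale: float = 0.55
    #: deviation-onset ramp duration, ms (from THS1 for A, from cue for UA)
    anticipation_ramp_ms: float = 250.0
    #: multiplier (>= 1) on the ramp duration for UA trials: without a
    #: preparatory phase the kinematic reorganization completes more slowly,
    #: so unanticipated deviations approach the anticipated pattern late
    ua_ramp_gain: float = 4.0
    #: trial-level execution-deviation SD for anticipated trials
    sigma_trial_A: float = 0.1
    #: trial-level execution-deviation SD for unanticipated trials
    #: (>= sigma_trial_A)
    sigma_trial_UA: float = 0.35
    #: white sample-noise SD (measurement + within-trial physiological)
    sigma_noise: float = 1.0
    #: multiplier (>= 1) on all event/cue timing jitter SDs for UA trials:
    #: reacting to a randomized cue makes execution timing more variable
    #: from trial to trial than a planned transition
    ua_timing_jitter_gain: float = 1.5
    #: per-(subject, channel) offset SD
    sigma_subject: float = 0.5
    #: optional AR(1) coefficient for the noise; 0 gives white noise
    ar1: float = 0.0
    event_timing: EventTiming = field(default_factory=EventTiming)
    fs: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 2:
            raise ValueError(
                "trials_per_condition must be >= 2 (leave-one-out is undefined "
                f"with fewer), got {self.trials_per_condition}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in (
            "cut_amp", "stair_amp", "style_corr", "stair_style_corr",
            "stair_deviation_gain", "ua_shift_amp", "ua_pattern_scale",
            "ua_stair_scale",
            "anticipation_ramp_ms", "sigma_trial_A", "sigma_trial_UA",
            "sigma_noise", "sigma_subject", "ar1", "fs",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"config parameter {name} must be finite, got {v}")
        if self.sigma_trial_UA < self.sigma_trial_A:
            raise ValueError(
                "sigma_trial_UA must be >= sigma_trial_A "
                f"(got {self.sigma_trial_UA} < {self.sigma_trial_A}): unanticipated "
                "perturbations raise, never lower, trial-to-trial variability"
            )
        if self.ua_ramp_gain < 1.0:
            raise ValueError(f"ua_ramp_gain must be >= 1, got {self.ua_ramp_gain}")
        if self.ua_timing_jitter_gain < 1.0:
            raise ValueError(
                f"ua_timing_jitter_gain must be >= 1, got {self.ua_timing_jitter_gain}"
            )
        if self.stair_deviation_gain < 1.0:
            raise ValueError(
                f"stair_deviation_gain must be >= 1, got {self.stair_deviation_gain}"
            )
        if min(self.sigma_trial_A, self.sigma_trial_UA,
               self.sigma_subject, self.sigma_noise) < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= abs(self.ar1) < 1.0:
            raise ValueError(f"ar1 must lie in (-1, 1), got {self.ar1}")
        if self.base_waveform is None:
            self.base_waveform = default_waveforms(self.channel_set)
        if self.task_deviation is None:
            self.task_deviation = default_task_deviations(
                self.channel_set,
                cut_amp=self.cut_amp,
                stair_amp=self.stair_amp,
                style_corr=self.style_corr,
                stair_style_corr=self.stair_style_corr,
            )
        if self.ua_task_deviation is None:
            self.ua_task_deviation = default_ua_task_deviations(
                self.channel_set,
                cut_amp=self.cut_amp,
                stair_amp=self.stair_amp,
                style_corr=self.style_corr,
                stair_style_corr=self.stair_style_corr,
                ua_shift_amp=self.ua_shift_amp,
                ua_pattern_scale=self.ua_pattern_scale,
                ua_stair_scale=self.ua_stair_scale,
            )


def default_waveforms(
    channels: list[ChannelSpec], n_harmonics: int = 3, seed: int = _GEOMETRY_SEED
) -> dict[str, np.ndarray]:
    """Per-channel Fourier coefficients over gait phase.

    Returns ``{name: array of shape (n_harmonics, 2)}`` holding the cosine
    and sine coefficients of harmonic ``h+1``; amplitudes fall off as
    ``1/(h+1)``, the canonical spectral decay of joint-kinematic waveforms.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        coeffs = rng.normal(size=(n_harmonics, 2))
        coeffs /= np.arange(1, n_harmonics + 1)[:, None]
        out[ch.name] = coeffs
    return out


def default_task_deviations(
    channels: list[ChannelSpec],
    cut_amp: float = 0.35,
    stair_amp: float = 0.6,
    style_corr: float = 0.97,
    stair_style_corr: float = 0.6,
    seed: int = _GEOMETRY_SEED,
) -> dict[str, np.ndarray]:
    """Per-(task, channel) deviation amplitudes ``d[task, c]``.

    The sidestep pattern correlates with the crossover pattern at
    ``style_corr`` — the two cut styles share almost all of their kinematic
    signature, which keeps them mutually confusable.  Each mixed transition
    adds a large, dense stair component; the COS and SSS stair components
    correlate at ``stair_style_corr`` only, because the stair approach
    executed out of a crossover differs from one executed out of a sidestep.
    Walking has zero deviation.
    """
    parts = _deviation_parts(
        channels, cut_amp, stair_amp, style_corr, stair_style_corr, seed + 1
    )
    return {
        "W": np.zeros(len(channels)),
        "CO": parts["cut_CO"],
        "SS": parts["cut_SS"],
        "COS": parts["cut_CO"] + parts["stair_COS"],
        "SSS": parts["cut_SS"] + parts["stair_SSS"],
    }


def _deviation_parts(
    channels: list[ChannelSpec],
    cut_amp: float,
    stair_amp: float,
    style_corr: float,
    stair_style_corr: float,
    seed: int,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = len(channels)
    z_co = rng.normal(size=n)
    z_ind = rng.normal(size=n)
    z_stair = rng.normal(size=n)
    z_stair_ind = rng.normal(size=n)
    return {
        "cut_CO": cut_amp * z_co,
        "cut_SS": cut_amp * (style_corr * z_co + math.sqrt(1.0 - style_corr**2) * z_ind),
        "stair_COS": stair_amp * z_stair,
        "stair_SSS": stair_amp * (
            stair_style_corr * z_stair
            + math.sqrt(1.0 - stair_style_corr**2) * z_stair_ind
        ),
    }


def default_ua_task_deviations(
    channels: list[ChannelSpec],
    cut_amp: float = 0.35,
    stair_amp: float = 0.6,
    style_corr: float = 0.97,
    stair_style_corr: float = 0.6,
    ua_shift_amp: float = 0.5,
    ua_pattern_scale: float = 0.5,
    ua_stair_scale: float = 0.55,
    seed: int = _GEOMETRY_SEED,
) -> dict[str, np.ndarray]:
    """Per-(task, channel) deviation patterns of unanticipated trials.

    Built from the planned (anticipated) patterns by (i) adding a dense
    task-generic compensatory shift, (ii) adding a task-specific execution
    difference that reuses the planned similarity geometry — so the two cut
    styles remain nearly indistinguishable in the unanticipated state while
    the mixed transitions keep partially distinct stair signatures — and
    (iii) attenuating the stair component to ``ua_stair_scale`` of its
    planned amplitude.
    """
    rng = np.random.default_rng(seed + 2)
    shared = ua_shift_amp * rng.normal(size=len(channels))
    planned = _deviation_parts(
        channels, cut_amp, stair_amp, style_corr, stair_style_corr, seed + 1
    )
    extra = _deviation_parts(
        channels,
        ua_pattern_scale * cut_amp,
        ua_pattern_scale * stair_amp,
        style_corr,
        stair_style_corr,
        seed + 3,
    )
    out = {}
    for task in TASKS:
        dev = shared.copy()
        if task != "W":
            style = "CO" if task in ("CO", "COS") else "SS"
            dev = dev + planned[f"cut_{style}"] + extra[f"cut_{style}"]
            if task in MIXED_TRANSITIONS:
                dev = dev + ua_stair_scale * (
                    planned[f"stair_{task}"] + extra[f"stair_{task}"]
                )
        out[task] = dev
    return out


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def draw_events(
    config: CohortConfig, task: str, state: str, rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[GaitEvents, int]:
    """Draw jittered gait events for one trial.

    Returns ``(events, n_samples)`` where ``n_samples`` includes the
    task-dependent tail after the last event.  Jittered draws violating the
    event-ordering invariants are re-drawn up to ``max_retries`` times.
    """
    t = config.event_timing
    mixed = task in MIXED_TRANSITIONS
    fs = config.fs
    jg = config.ua_timing_jitter_gain if state == "UA" else 1.0
    for _ in range(max_retries):
        ths1 = rng.normal(t.ths1_ms[0], jg * t.ths1_ms[1])
        cue = rng.normal(t.cue_ms[0], jg * t.cue_ms[1])
        tto1 = rng.normal(t.tto1_ms[0], jg * t.tto1_ms[1])
        ths2 = rng.normal(t.ths2_ms[0], jg * t.ths2_ms[1])
        lto2 = rng.normal(t.lto2_ms[0], jg * t.lto2_ms[1])
        ths3 = rng.normal(t.ths3_ms[0], jg * t.ths3_ms[1])
        ev = {
            "THS1": max(0, _ms_to_samples(ths1, fs)),
            "TTO1": _ms_to_samples(tto1, fs),
            "THS2": _ms_to_samples(ths2, fs),
        }
        if not ev["THS1"] < ev["TTO1"] < ev["THS2"]:
            continue
        if mixed:
            ev["LTO2"] = _ms_to_samples(lto2, fs)
            ev["THS3"] = _ms_to_samples(ths3, fs)
            if not ev["THS2"] <= ev["LTO2"] < ev["THS3"]:
                continue
        if state == "UA":
            ev["cue"] = _ms_to_samples(cue, fs)
            if not ev["THS1"] <= ev["cue"] < ev["TTO1"]:
                continue
        tail_key = "mixed" if mixed else ("W" if task == "W" else "single")
        last = ev["THS3"] if mixed else ev["THS2"]
        n_samples = last + _ms_to_samples(t.tail_ms[tail_key], fs) + 1
        return GaitEvents(**ev), n_samples
    raise RuntimeError(
        f"could not draw ordered gait events for task={task}, state={state} "
        f"after {max_retries} attempts; event-timing jitter is too large "
        "relative to the inter-event gaps"
    )


def gait_phase(n_samples: int, events: GaitEvents, fs: float) -> np.ndarray:
    """Piecewise-linear gait phase (strides since THS1) for every sample.

    Phase is anchored at the trial's events and extrapolated linearly before
    the first and after the last event using the adjacent segment slope, so
    waveforms stay event-aligned across jittered trials.
    """
    nodes = [(events.THS1, _EVENT_PHASE["THS1"]),
             (events.TTO1, _EVENT_PHASE["TTO1"]),
             (events.THS2, _EVENT_PHASE["THS2"])]
    if events.LTO2 is not None:
        nodes.append((events.LTO2, _EVENT_PHASE["LTO2"]))
        nodes.append((events.THS3, _EVENT_PHASE["THS3"]))
    xs = np.array([x for x, _ in nodes], dtype=float)
    ys = np.array([y for _, y in nodes], dtype=float)
    t = np.arange(n_samples, dtype=float)
    phi = np.interp(t, xs, ys)
    # np.interp clamps outside [xs[0], xs[-1]]; extrapolate with edge slopes
    lo = t < xs[0]
    hi = t > xs[-1]
    slope0 = (ys[1] - ys[0]) / (xs[1] - xs[0])
    slope1 = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    phi[lo] = ys[0] + (t[lo] - xs[0]) * slope0
    phi[hi] = ys[-1] + (t[hi] - xs[-1]) * slope1
    return phi


def _base_signal(phi: np.ndarray, waveforms: dict[str, np.ndarray],
                 channel_names: list[str]) -> np.ndarray:
    n_harm = next(iter(waveforms.values())).shape[0]
    h = np.arange(1, n_harm + 1)
    ang = 2.0 * np.pi * phi[:, None] * h[None, :]       # (n, H)
    cos, sin = np.cos(ang), np.sin(ang)
    coeffs = np.stack([waveforms[name] for name in channel_names])  # (C, H, 2)
    return cos @ coeffs[:, :, 0].T + sin @ coeffs[:, :, 1].T        # (n, C)


def anticipation_gate(
    n_samples: int, events: GaitEvents, state: str, ramp_ms: float, fs: float,
    ua_ramp_gain: float = 1.0,
) -> np.ndarray:
    """The gate ``g(t)`` switching the task deviation on.

    Anticipated trials ramp 0 → 1 over ``ramp_ms`` starting at THS1
    (preparatory adaptation, complete before TTO1 at default timings);
    unanticipated trials stay at 0 until the cue and ramp only after it, so
    the deviation is still incomplete when the transition starts.
    """
    start = events.THS1 if state == "A" else events.cue
    if start is None:
        raise ValueError("UA trials require a cue event to place the gate")
    if state == "UA":
        ramp_ms = ramp_ms * ua_ramp_gain
    ramp = max(ramp_ms * fs / 1000.0, 1.0)
    t = np.arange(n_samples, dtype=float)
    return np.clip((t - start) / ramp, 0.0, 1.0)


def _stair_gate(n_samples: int, events: GaitEvents, task: str, gain: float) -> np.ndarray:
    s = np.ones(n_samples)
    if task in MIXED_TRANSITIONS and events.LTO2 is not None:
        s[events.LTO2:] = gain
    return s


def _noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float, ar1: float) -> np.ndarray:
    eps = rng.normal(0.0, 1.0, size=shape)
    if ar1 != 0.0:
        from scipy.signal import lfilter

        # innovation scaled so the marginal SD stays sigma
        eps = lfilter([1.0], [1.0, -ar1], eps, axis=0) * math.sqrt(1.0 - ar1**2)
    return sigma * eps


def generate_cohort(config: CohortConfig) -> list[KinematicTrial]:
    """Generate the full cohort: n_subjects x 5 tasks x 2 states x
    trials_per_condition trials, bit-identical for identical (config, seed).
    """
    names = [c.name for c in config.channel_set]
    if len(names) != len(set(names)):
        raise ValueError("channel names must be unique within a cohort")
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    trials: list[KinematicTrial] = []
    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        offs_ss, trials_ss = subject_seeds[si].spawn(2)
        offsets = np.random.default_rng(offs_ss).normal(
            0.0, config.sigma_subject, size=len(names)
        )
        cond_seeds = iter(trials_ss.spawn(len(TASKS) * len(STATES) * config.trials_per_condition))
        for task in TASKS:
            for state in STATES:
                for rep in range(config.trials_per_condition):
                    rng = np.random.default_rng(next(cond_seeds))
                    events, n = draw_events(config, task, state, rng)
                    phi = gait_phase(n, events, config.fs)
                    x = _base_signal(phi, config.base_waveform, names)
                    pattern = (
                        config.task_deviation if state == "A"
                        else config.ua_task_deviation
                    )
                    g = anticipation_gate(
                        n, events, state, config.anticipation_ramp_ms, config.fs,
                        ua_ramp_gain=config.ua_ramp_gain,
                    )
                    s = _stair_gate(n, events, task, config.stair_deviation_gain)
                    d = np.asarray(pattern[task], dtype=float)
                    sigma_exec = (
                        config.sigma_trial_A if state == "A" else config.sigma_trial_UA
                    )
                    eta = rng.normal(0.0, sigma_exec, size=len(names))
                    dev = d + eta
                    x = x + (g * s)[:, None] * dev[None, :]
                    x = x + offsets[None, :]
                    if config.sigma_noise > 0:
                        x = x + _noise(rng, x.shape, config.sigma_noise, config.ar1)
                    trials.append(
                        KinematicTrial(
                            subject_id=subject_id,
                            task=task,
                            state=state,
                            fs=config.fs,
                            signal=x,
                            channels=list(config.channel_set),
                            events=events,
                            trial_id=f"{subject_id}_{task}_{state}_{rep + 1:02d}",
                        )
                    )
    return trials


def noise_free(config: CohortConfig, jitter: bool = False) -> CohortConfig:
    """A copy of ``config`` with all stochastic terms silenced.

    With ``jitter=False`` event timing is also made deterministic, so trials
    within a condition are identical — the separability limit used in tests.
    """
    cfg = replace(
        config,
        sigma_trial_A=0.0,
        sigma_trial_UA=0.0,
        sigma_noise=0.0,
        sigma_subject=0.0,
        base_waveform=None if config.base_waveform is None else dict(config.base_waveform),
        ua_task_deviation=(
            None if config.ua_task_deviation is None else dict(config.ua_task_deviation)
        ),
        task_deviation=None if config.task_deviation is None else dict(config.task_deviation),
        channel_set=list(config.channel_set),
    )
    if not jitter:
        t = config.event_timing
        cfg = replace(
            cfg,
            event_timing=EventTiming(
                ths1_ms=(t.ths1_ms[0], 0.0),
                cue_ms=(t.cue_ms[0], 0.0),
                tto1_ms=(t.tto1_ms[0], 0.0),
                ths2_ms=(t.ths2_ms[0], 0.0),
                lto2_ms=(t.lto2_ms[0], 0.0),
                ths3_ms=(t.ths3_ms[0], 0.0),
                tail_ms=dict(t.tail_ms),
            ),
        )
    return cfg
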
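"""Adaptive detection-threshold staircase and 2AFC frequency-detection analysis.

The threshold procedure is a transformed up-down (1-up-3-down) staircase:
after three consecutive correct 2AFC responses the current amplitude is
lowered by 2 dB; after any incorrect response it is raised by 2 dB.  The
run stops at the fifth direction change and the threshold is the mean of
the ten amplitudes tested immediately before it.  A 1-up-3-down rule
converges on the amplitude where P(correct) = 0.5^(1/3) ~ 79.4%.

The fixed-amplitude task presents randomly interleaved pulse frequencies
at 1.2x the 100 Hz threshold and compares detection accuracy across
frequencies (one-sample t against chance, one-way ANOVA with Tukey HSD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AMPLITUDE_RANGE_UA, DetectionTrial, StimulusTrain, ValidationError
from .synthetic import PsychometricObserver


class StaircaseError(RuntimeError):
    """Staircase could not produce a threshold; carries the trial history."""

    def __init__(self, message: str, history: tuple):
        super().__init__(message)
        self.history = history


# --------------------------------------------------------------------------
# Staircase state machine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseState:
    """State of a 1-up-3-down staircase between trials.

    ``history`` holds (amplitude, correct) per completed trial.  A
    direction exists only once the amplitude has actually moved; the first
    step sets ``last_direction`` without counting a change, and steps
    clamped in place at the stimulator floor/ceiling neither set nor flip
    the direction.
    """

    amplitude_uA: float = 10.0
    consecutive_correct: int = 0
    history: tuple[tuple[float, bool], ...] = ()
    direction_changes: int = 0
    last_direction: str = "none"  # 'up' | 'down' | 'none'
    reversal_trials: tuple[int, ...] = ()
    step_db: float = 2.0
    floor_uA: float = AMPLITUDE_RANGE_UA[0]
    ceiling_uA: float = AMPLITUDE_RANGE_UA[1]


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one 2AFC trial outcome.

    Correct responses increment the consecutive-correct counter; the third
    in a row steps the amplitude down by ``step_db`` and resets the
    counter.  Any incorrect response steps up immediately and resets the
    counter.  Amplitudes are clamped to the stimulator range; a clamped
    step that does not move the amplitude is not a direction event.
    """
    history = state.history + ((state.amplitude_uA, bool(correct)),)
    trial_index = len(history) - 1

    if correct:
        cc = state.consecutive_correct + 1
        if cc < 3:
            return replace(state, consecutive_correct=cc, history=history)
        direction = "down"
        factor = 10.0 ** (-state.step_db / 20.0)
        cc = 0
    else:
        direction = "up"
        factor = 10.0 ** (state.step_db / 20.0)
        cc = 0

    new_amp = min(max(state.amplitude_uA * factor, state.floor_uA),
                  state.ceiling_uA)
    if math.isclose(new_amp, state.amplitude_uA):
        # pinned at floor/ceiling: no movement, no direction bookkeeping
        return replace(state, consecutive_correct=cc, history=history)

    changes = state.direction_changes
    reversals = state.reversal_trials
    if state.last_direction != "none" and direction != state.last_direction:
        changes += 1
        reversals = reversals + (trial_index,)
    return replace(state, amplitude_uA=new_amp, consecutive_correct=cc,
                   history=history, direction_changes=changes,
                   last_direction=direction, reversal_trials=reversals)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Threshold = mean of exactly ten tested amplitudes (µA)."""

    threshold_uA: float
    n_trials: int
    reversal_amplitudes: tuple[float, ...]
    history: tuple[tuple[float, bool], ...]


def threshold_from_history(
    history,
    n_reversals: int = 5,
    n_average: int = 10,
    include_reversal_trial: bool = False,
    step_db: float = 2.0,
    start_uA: float | None = None,
) -> ThresholdEstimate:
    """Replay a (amplitude, correct) trial log and estimate the threshold.

    The threshold is the mean of the ``n_average`` amplitudes presented on
    the trials immediately preceding the trial on which the
    ``n_reversals``-th direction change registers (exclusive of that trial
    by default; ``include_reversal_trial=True`` shifts the window to end
    on it).
    """
    history = tuple((float(a), bool(c)) for a, c in history)
    if not history:
        raise StaircaseError("empty history", history)
    state = StaircaseState(amplitude_uA=history[0][0], step_db=step_db)
    stop_index = None
    for t, (amp, correct) in enumerate(history):
        if not math.isclose(state.amplitude_uA, amp, rel_tol=1e-9):
            raise ValidationError(
                f"trial {t}: amplitude {amp} inconsistent with replayed "
                f"staircase state {state.amplitude_uA}")
        state = staircase_step(state, correct)
        if state.direction_changes >= n_reversals:
            stop_index = t
            break
    if stop_index is None:
        raise StaircaseError(
            f"fewer than {n_reversals} direction changes in the log", history)
    amps = [a for a, _ in history]
    if include_reversal_trial:
        window = amps[stop_index - n_average + 1: stop_index + 1]
    else:
        window = amps[stop_index - n_average: stop_index]
    if len(window) < n_average:
        raise StaircaseError(
            f"only {len(window)} trials precede the {n_reversals}th "
            f"direction change; need {n_average}", history)
    reversal_amps = tuple(amps[i] for i in state.reversal_trials)
    return ThresholdEstimate(threshold_uA=float(np.mean(window)),
                             n_trials=stop_index + 1,
                             reversal_amplitudes=reversal_amps,
                             history=history[: stop_index + 1])


def run_staircase(
    observer: PsychometricObserver,
    start_uA: float = 10.0,
    seed: int | np.random.Generator | None = None,
    max_trials: int = 200,
    step_db: float = 2.0,
    n_reversals: int = 5,
    include_reversal_trial: bool = False,
) -> ThresholdEstimate:
    """Simulate a 1-up-3-down staircase against a psychometric observer.

    Trials draw correct/incorrect from the observer's psychometric
    function at the current amplitude.  Stops at the ``n_reversals``-th
    direction change; raises :class:`StaircaseError` (carrying the
    history) if ``max_trials`` is exhausted first — e.g. an observer that
    is always correct descends monotonically to the 2 µA floor and never
    reverses.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState(amplitude_uA=start_uA, step_db=step_db)
    for _ in range(max_trials):
        correct = bool(rng.random() < observer.p_correct(state.amplitude_uA))
        state = staircase_step(state, correct)
        if state.direction_changes >= n_reversals:
            return threshold_from_history(
                state.history, n_reversals=n_reversals,
                include_reversal_trial=include_reversal_trial, step_db=step_db)
    raise StaircaseError(
        f"no {n_reversals}th direction change within {max_trials} trials",
        state.history)


# --------------------------------------------------------------------------
# Fixed-amplitude 2AFC frequency-detection task
# --------------------------------------------------------------------------

def simulate_2afc_block(
    observers: dict[float, PsychometricObserver],
    amplitude_uA: float | None = None,
    frequencies=(20.0, 100.0, 300.0),
    n_per_freq: int = 30,
    seed: int | np.random.Generator | None = None,
    electrode_id: int = 0,
    duration_s: float = 1.0,
) -> list[DetectionTrial]:
    """Simulate one randomly interleaved fixed-amplitude detection block.

    Each requested pulse frequency is presented ``n_per_freq`` times in a
    single randomly interleaved sequence (3 frequencies x 30 = 90 trials
    in the standard design).  The test amplitude defaults to 1.2x the
    observer's 100 Hz threshold.  The stimulus interval is uniform on
    {1, 2}; the response interval matches it when the observer responds
    correctly.
    """
    rng = np.random.default_rng(seed)
    missing = [f for f in frequencies if float(f) not in observers]
    if missing:
        raise ValidationError(f"no observer for frequencies {missing}")
    if amplitude_uA is None:
        if 100.0 not in observers:
            raise ValidationError(
                "default amplitude rule needs a 100 Hz observer")
        amplitude_uA = 1.2 * observers[100.0].threshold_uA
    condition_list = np.repeat(np.asarray(frequencies, dtype=float), n_per_freq)
    rng.shuffle(condition_list)

    trials: list[DetectionTrial] = []
    for f in condition_list:
        obs = observers[float(f)]
        stimulus_interval = int(rng.integers(1, 3))
        correct = bool(rng.random() < obs.p_correct(amplitude_uA))
        response = stimulus_interval if correct else 3 - stimulus_interval
        trials.append(DetectionTrial(
            electrode_id=electrode_id,
            stimulus=StimulusTrain(amplitude_uA, float(f), duration_s),
            stimulus_interval=stimulus_interval,
            response_interval=response))
    return trials


def detection_trials_to_frame(trials: list[DetectionTrial]) -> pd.DataFrame:
    return pd.DataFrame({
        "electrode": [t.electrode_id for t in trials],
        "frequency_Hz": [t.stimulus.frequency_Hz for t in trials],
        "amplitude_uA": [t.stimulus.amplitude_uA for t in trials],
        "stimulus_interval": [t.stimulus_interval for t in trials],
        "response_interval": [t.response_interval for t in trials],
        "correct": [t.correct for t in trials],
    })


@dataclass
class AccuracyAnalysis:
    """Per-frequency detection accuracy with chance and omnibus tests."""

    per_frequency: pd.DataFrame   # frequency_Hz, mean_accuracy, n_electrodes, t_p_value
    anova_p: float | None
    posthoc: pd.DataFrame | None  # pairwise Tukey HSD across frequencies


def accuracy_analysis(df: pd.DataFrame) -> AccuracyAnalysis:
    """Analyse fixed-amplitude detection accuracy across pulse frequencies.

    The analysis unit is per-electrode accuracy at each frequency: a
    one-sample t-test against the 50% chance level per frequency, then a
    one-way ANOVA across frequencies with Tukey HSD post-hoc.  Frequencies
    with no trials are excluded with a warning; with a single frequency
    present the ANOVA is skipped (warning) and the t-tests still run.
    Requires accuracies from at least two electrodes.
    """
    acc = (df.groupby(["electrode", "frequency_Hz"])["correct"]
             .mean().rename("accuracy").reset_index())
    if acc["electrode"].nunique() < 2:
        raise ValidationError("need >= 2 electrodes for the accuracy analysis")

    rows = []
    groups = []
    for f, sub in acc.groupby("frequency_Hz"):
        vals = sub["accuracy"].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"no trials at {f} Hz; excluded", stacklevel=2)
            continue
        if np.ptp(vals) == 0:
            t_p = 1.0 if np.isclose(vals[0], 0.5) else 0.0
        else:
            t_p = float(stats.ttest_1samp(vals, 0.5).pvalue)
        rows.append((f, float(vals.mean()), len(vals), t_p))
        groups.append((f, vals))
    per_freq = pd.DataFrame(
        rows, columns=["frequency_Hz", "mean_accuracy", "n_electrodes", "t_p_value"])

    anova_p = None
    posthoc = None
    if len(groups) >= 2:
        arrays = [g for _, g in groups]
        anova_p = float(stats.f_oneway(*arrays).pvalue)
        res = stats.tukey_hsd(*arrays)
        names = [f for f, _ in groups]
        pairs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append((names[i], names[j], float(res.pvalue[i, j])))
        posthoc = pd.DataFrame(
            pairs, columns=["frequency_a", "frequency_b", "p_value"])
    else:
        warnings.warn("single frequency present; ANOVA skipped", stacklevel=2)
    return AccuracyAnalysis(per_frequency=per_freq, anova_p=anova_p, posthoc=posthoc)
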
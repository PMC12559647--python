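"""Transformed up-down 3-AFC staircase engine and threshold estimation.

The detection experiments use a three-alternative forced-choice task
with a 1-up/2-down rule: the distortion amount decreases after two
consecutive correct responses and increases after any error, which makes
the track converge on the 70.7% correct point of the psychometric
function (0.5^(1/2)).  The step size starts at the kind-specific initial
value and halves at each reversal until the minimum step is reached;
six reversals are then collected at the minimum step and averaged, and
the final threshold is the mean of two independent runs (test-retest).
Step arithmetic is additive in the printed units (dB, alpha, dB,
degrees) and amounts are floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulated_listener import SimulatedListener, simulate_trial_response


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-track rule and step schedule for one distortion kind."""

    kind: str
    start_value: float
    initial_step: float
    minimum_step: float
    n_down: int = 2
    n_up: int = 1
    n_intervals: int = 3
    reversals_to_average: int = 6
    runs_per_threshold: int = 2
    trial_cap: int = 400

    def __post_init__(self):
        if self.minimum_step > self.initial_step:
            raise ValueError("minimum step must not exceed the initial step")
        if self.minimum_step <= 0:
            raise ValueError("steps must be positive")


#: Step schedules of the detection/discrimination experiments:
#: (starting value, initial step, minimum step) in printed units.
STAIRCASE_CONFIGS = {
    "ripple": StaircaseConfig("ripple", 30.0, 5.0, 1.5),
    "saturation": StaircaseConfig("saturation", 0.82, 0.2, 0.035),
    "intensity": StaircaseConfig("intensity", 8.0, 2.0, 0.4),
    "spatial": StaircaseConfig("spatial", 28.0, 4.0, 0.5),
}


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    amount: float
    correct: bool
    reversal: bool


@dataclass(frozen=True)
class StaircaseRun:
    """One adaptive track: trial log and measured reversal values."""

    trials: tuple[TrialRecord, ...]
    reversal_values: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.reversal_values))


@dataclass(frozen=True)
class ThresholdEstimate:
    """Reversal-averaged threshold from test and retest runs."""

    kind: str
    context: str
    runs: tuple[StaircaseRun, ...]

    @property
    def run_means(self) -> tuple[float, ...]:
        return tuple(r.mean for r in self.runs)

    @property
    def threshold(self) -> float:
        return float(np.mean(self.run_means))


class StaircaseError(RuntimeError):
    """Raised when a track fails to converge; carries the partial track."""

    def __init__(self, message: str, trials: tuple[TrialRecord, ...]):
        super().__init__(message)
        self.trials = trials


def staircase_convergence_probability(n_down: int, n_up: int = 1) -> float:
    """Asymptotic percent-correct tracked by an n_up/n_down rule.

    The track equilibrates where the probability of a down-move equals
    that of an up-move: p^n_down = 0.5, hence p = 0.5^(1/n_down)
    (0.707 for 1-up/2-down).
    """
    if n_down < 1 or n_up != 1:
        raise ValueError("rule must be 1-up/n-down with n_down >= 1")
    return 0.5 ** (1.0 / n_down)


def _run_one_track(
    config: StaircaseConfig,
    listener: SimulatedListener,
    context: str,
    rng: np.random.Generator,
) -> StaircaseRun:
    amount = config.start_value
    step = config.initial_step
    consecutive = 0
    last_direction = 0  # +1 up, -1 down
    at_minimum = step <= config.minimum_step
    measured: list[float] = []
    trials: list[TrialRecord] = []

    for trial in range(1, config.trial_cap + 1):
        correct = simulate_trial_response(listener, config.kind, context, amount, rng)
        direction = 0
        if correct:
            consecutive += 1
            if consecutive >= config.n_down:
                direction = -1
                consecutive = 0
        else:
            direction = +1
            consecutive = 0

        reversal = direction != 0 and last_direction != 0 and direction != last_direction
        trials.append(TrialRecord(trial, amount, correct, reversal))
        if reversal:
            if at_minimum:
                measured.append(amount)
                if len(measured) >= config.reversals_to_average:
                    return StaircaseRun(tuple(trials), tuple(measured))
            else:
                step = max(step / 2.0, config.minimum_step)
                at_minimum = step <= config.minimum_step
        if direction != 0:
            amount = max(0.0, amount + direction * step)
            last_direction = direction
    raise StaircaseError(
        f"track did not converge within {config.trial_cap} trials",
        tuple(trials),
    )


def run_staircase(
    config: StaircaseConfig,
    listener: SimulatedListener,
    context: str,
    seed: int,
) -> ThresholdEstimate:
    """Measure one threshold: two independent runs, reversal-averaged."""
    ss = np.random.SeedSequence(seed)
    runs = tuple(
        _run_one_track(config, listener, context, np.random.default_rng(child))
        for child in ss.spawn(config.runs_per_threshold)
    )
    return ThresholdEstimate(kind=config.kind, context=context, runs=runs)


def measure_convergence(
    config: StaircaseConfig,
    listener: SimulatedListener,
    context: str,
    n_tracks: int,
    seed: int,
    n_reversals: int = 24,
    n_discard: int = 8,
) -> tuple[float, float]:
    """Asymptotic tracked level of the up-down rule, and the observer's
    percent-correct there.

    The six-reversal experimental estimate retains a small entry
    transient (the track approaches its equilibrium from the high
    starting value; the resulting bias stays below one minimum step).
    To characterize what the rule itself converges to, tracks are run
    for ``n_reversals`` minimum-step reversals and the first
    ``n_discard`` are dropped — the standard way of reading off an
    adaptive track's equilibrium.  Returns (mean converged level,
    observer percent-correct at that level).
    """
    from dataclasses import replace

    long_cfg = replace(
        config,
        reversals_to_average=n_reversals,
        trial_cap=max(config.trial_cap, 12 * n_reversals),
    )
    ss = np.random.SeedSequence(seed)
    levels = []
    for child in ss.spawn(n_tracks):
        run = _run_one_track(
            long_cfg, listener, context, np.random.default_rng(child)
        )
        levels.append(np.mean(run.reversal_values[n_discard:]))
    mean_level = float(np.mean(levels))
    pc = listener.prob_correct(config.kind, context, mean_level)
    return mean_level, pc
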
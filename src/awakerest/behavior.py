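"""Adaptive staircase psychophysics: 2-down 1-up blocks and thresholds.

The detection task staircases the stimulus S/N ratio: every block starts
at 25% S/N, the level is lowered after two consecutive correct responses
at the same level and raised after any error (a rule converging at 70.7%
correct), and the block ends after the tenth reversal.  The block
threshold is the geometric mean of the last six reversal levels, and the
per-day threshold is the arithmetic mean over the day's three blocks.
Performance improvement is the relative threshold drop from before to
after training, (pre - post) / pre.

The stepping is multiplicative (default 1.5 dB, x or / 10^0.15),
consistent with a geometric-mean threshold; level bounds clip the level
and clipping is logged in the trace.  The module also implements the
asymmetric yes/no staircase of the decoder scan's spatial-frequency task
(-0.02 on hits, +0.02 on misses, unchanged on correct rejections and
false alarms) and, with a step of 2 on a color intensity starting at 40,
the fixation task's color staircase reuses :func:`run_staircase` with an
additive step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ObserverModel, simulate_observer_response

__all__ = [
    "StaircaseConfig",
    "StaircaseBlock",
    "ImprovementScore",
    "StaircaseError",
    "run_staircase",
    "threshold_geomean_reversals",
    "performance_improvement",
    "run_frequency_task_staircase",
    "expected_frequency_drift_per_trial",
    "COLOR_STAIRCASE",
]


class StaircaseError(RuntimeError):
    """A staircase failed to terminate within its trial guard."""


@dataclass(frozen=True)
class StaircaseConfig:
    """2-down 1-up staircase parameters.

    ``step`` is a factor for multiplicative stepping (S/N ratios; the
    default is 1.5 dB, 10**0.15) or an increment for additive stepping (the
    fixation color staircase uses step 2 on a starting level of 40).
    """

    start_level: float = 0.25
    step: float = 10.0 ** 0.15
    step_mode: str = "multiplicative"
    n_reversals: int = 10
    floor: float = 0.01
    ceiling: float = 1.0
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if self.step_mode not in ("multiplicative", "additive"):
            raise ValueError("step_mode must be 'multiplicative' or 'additive'")
        if self.step_mode == "multiplicative":
            if self.step <= 1.0:
                raise ValueError("multiplicative step must exceed 1")
            if self.floor <= 0:
                raise ValueError("floor must be positive (geometric mean defined)")
        elif self.step <= 0:
            raise ValueError("additive step must be positive")
        if self.floor >= self.ceiling:
            raise ValueError("floor must be below ceiling")
        if not self.floor <= self.start_level <= self.ceiling:
            raise ValueError("start_level must lie within [floor, ceiling]")

    def down(self, level: float) -> float:
        new = level / self.step if self.step_mode == "multiplicative" else level - self.step
        return max(new, self.floor)

    def up(self, level: float) -> float:
        new = level * self.step if self.step_mode == "multiplicative" else level + self.step
        return min(new, self.ceiling)


# the fixation-dot color staircase: x starts at 40, step size 2
COLOR_STAIRCASE = StaircaseConfig(
    start_level=40.0, step=2.0, step_mode="additive", floor=0.0 + 1e-9, ceiling=255.0
)


@dataclass(frozen=True)
class StaircaseBlock:
    """Trial-by-trial staircase trace for one block."""

    levels: np.ndarray  # level presented on each trial
    responses: np.ndarray  # True = correct
    directions: np.ndarray  # prescribed step after each trial: -1, 0, +1
    reversal_trials: np.ndarray
    reversal_levels: np.ndarray
    clipped_trials: np.ndarray
    config: StaircaseConfig

    @property
    def n_trials(self) -> int:
        return int(self.levels.size)

    @property
    def n_reversals(self) -> int:
        return int(self.reversal_levels.size)

    @property
    def threshold(self) -> float:
        return threshold_geomean_reversals(self)


def run_staircase(
    config: StaircaseConfig,
    observer: ObserverModel | None = None,
    seed: int | np.random.Generator | None = None,
    responses=None,
) -> StaircaseBlock:
    """Run one 2-down 1-up block until the tenth reversal.

    Responses come either from a simulated observer (with ``seed``) or
    from an explicit ``responses`` sequence of booleans (for scripted
    traces).  Standard Levitt bookkeeping: the two-consecutive-correct
    counter resets on every level change and on every error; a reversal
    is a trial whose prescribed direction differs from the previous
    prescribed direction.  The reversal level recorded is the level at
    which the direction change occurred.
    """
    if (observer is None) == (responses is None):
        raise ValueError("provide exactly one of observer or responses")
    rng = None
    if observer is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    script = iter(responses) if responses is not None else None

    level = config.start_level
    streak = 0
    last_dir = 0
    levels, resp, dirs = [], [], []
    rev_trials, rev_levels, clipped = [], [], []

    for trial in range(config.max_trials):
        if script is not None:
            try:
                correct = bool(next(script))
            except StopIteration:
                break
        else:
            correct = simulate_observer_response(observer, min(level, 1.0), rng)

        direction = 0
        if correct:
            streak += 1
            if streak == 2:
                direction = -1
                streak = 0
        else:
            direction = +1
            streak = 0

        levels.append(level)
        resp.append(correct)
        dirs.append(direction)

        if direction != 0:
            if last_dir != 0 and direction != last_dir:
                rev_trials.append(trial)
                rev_levels.append(level)
            last_dir = direction
            new_level = config.down(level) if direction < 0 else config.up(level)
            if new_level == level:
                clipped.append(trial)
            level = new_level
            if len(rev_levels) >= config.n_reversals:
                break
    else:
        if script is None:
            raise StaircaseError(
                f"staircase did not reach {config.n_reversals} reversals within "
                f"{config.max_trials} trials (last level {level:.4g}; trace of "
                f"{len(levels)} trials)"
            )

    return StaircaseBlock(
        levels=np.asarray(levels, dtype=float),
        responses=np.asarray(resp, dtype=bool),
        directions=np.asarray(dirs, dtype=int),
        reversal_trials=np.asarray(rev_trials, dtype=int),
        reversal_levels=np.asarray(rev_levels, dtype=float),
        clipped_trials=np.asarray(clipped, dtype=int),
        config=config,
    )


def threshold_geomean_reversals(block: StaircaseBlock, n_last: int = 6) -> float:
    """Geometric mean of the last ``n_last`` reversal levels."""
    levels = np.asarray(block.reversal_levels, dtype=float)
    if levels.size < n_last:
        raise ValueError(
            f"need at least {n_last} reversals, block has {levels.size}"
        )
    tail = levels[-n_last:]
    if np.any(tail <= 0):
        raise ValueError("reversal levels must be positive for a geometric mean")
    return float(np.exp(np.mean(np.log(tail))))


@dataclass(frozen=True)
class ImprovementScore:
    """Relative threshold improvement from before to after training."""

    threshold_pre: float
    threshold_post: float

    @property
    def improvement(self) -> float:
        return (self.threshold_pre - self.threshold_post) / self.threshold_pre


def performance_improvement(
    pre_blocks: list[StaircaseBlock], post_blocks: list[StaircaseBlock]
) -> ImprovementScore:
    """Improvement from the day-2 to the day-4 behavioral test.

    Each day's threshold is the arithmetic mean of its three block
    thresholds; improvement = (pre - post) / pre, positive = learning.
    """
    if len(pre_blocks) != 3 or len(post_blocks) != 3:
        raise ValueError("each day requires exactly 3 staircase blocks")
    pre = float(np.mean([b.threshold for b in pre_blocks]))
    post = float(np.mean([b.threshold for b in post_blocks]))
    return ImprovementScore(threshold_pre=pre, threshold_post=post)


def run_frequency_task_staircase(
    signal_present,
    reported,
    start: float = 0.24,
    step: float = 0.02,
) -> np.ndarray:
    """Asymmetric yes/no staircase on the spatial-frequency increment.

    ``signal_present[t]`` says whether trial t contained a frequency
    change and ``reported[t]`` whether the subject reported one.  The
    increment decreases by ``step`` on hits, increases by ``step`` on
    misses, and is unchanged on correct rejections and false alarms;
    values driven below zero are clipped at zero.  Returns the increment
    *after* each trial; run-to-run carry-over is achieved by passing the
    last value as the next run's ``start``.
    """
    present = np.asarray(signal_present, dtype=bool)
    rep = np.asarray(reported, dtype=bool)
    if present.shape != rep.shape:
        raise ValueError("signal_present and reported must have the same length")
    level = float(start)
    trace = np.empty(present.size, dtype=float)
    for t in range(present.size):
        if present[t] and rep[t]:  # hit
            level -= step
        elif present[t] and not rep[t]:  # miss
            level += step
        # correct rejection / false alarm: unchanged
        if level < 0.0:
            level = 0.0
        trace[t] = level
    return trace


def expected_frequency_drift_per_trial(hit_rate: float, step: float = 0.02) -> float:
    """Expected increment change per trial when half the trials carry a
    signal and the observer hits with probability ``hit_rate``:
    step * (1 - 2 h) / 2 (negative = descending toward threshold)."""
    return step * (1.0 - 2.0 * hit_rate) / 2.0
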
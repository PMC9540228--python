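"""Headless adaptive n-match training engine.

The task is a continuous-recognition working-memory game: on every trial a
stimulus (a bird) appears in one of ``n`` visuo-spatial contexts (trees) and
the player judges whether it matches the stimulus *last shown in that same
context*.  Because the context sequence is random, the player must hold and
unpredictably update ``n`` items at once.

Difficulty adapts between 80-trial blocks on three axes:

* **contexts** ``n`` (1..6) — incremented after every block whose corrected
  d' meets the current threshold;
* **d' threshold** — raised by 0.2 (0.6 .. 3.0) each time an ``n = 6`` block
  is passed, which resets ``n`` to 1 and unlocks a new background;
* **MaxRT** — the per-trial response window, tightened by 0.5 s for each 10%
  of the expected total training time elapsed (floor 1 s) and relaxed by
  0.5 s after every three consecutive failed blocks (ceiling 6 s).

The grid of (threshold epoch 0..11) x (n 1..6) gives 72 upward difficulty
states; the pass that would push the threshold past 2.8 sets it to its 3.0
cap and freezes the progression (terminal state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "EngineConfig",
    "EngineState",
    "Trial",
    "TrialResult",
    "BlockRecord",
    "ConfigurationError",
    "DegenerateBlockError",
    "generate_block_trials",
    "classify_response",
    "block_dprime",
    "block_score",
    "update_difficulty",
    "play_block",
]


class ConfigurationError(ValueError):
    """Invalid engine configuration or state."""


class DegenerateBlockError(ValueError):
    """Block has no trials of one stimulus class, so d' is undefined."""


@dataclass(frozen=True)
class EngineConfig:
    """Static parameters of the adaptive task.

    Defaults reproduce the deployed training configuration: 80-trial blocks,
    up to six contexts, d' threshold 0.6 rising by 0.2 to a 3.0 cap, a 5 s
    response window bounded to [1, 6] s in 0.5 s steps, and 20 h of expected
    training with a MaxRT decrement each 10% of that time.
    """

    block_length: int = 80
    n_max: int = 6
    dprime_start: float = 0.6
    dprime_step: float = 0.2
    dprime_cap: float = 3.0
    maxrt_start: float = 5.0
    maxrt_min: float = 1.0
    maxrt_max: float = 6.0
    maxrt_step: float = 0.5
    expected_total_hours: float = 20.0
    decrement_milestone_frac: float = 0.10
    fail_streak_for_relief: int = 3
    match_rate: float = 0.5
    stimulus_pool_size: int = 8
    iti_seconds: float = 0.5

    def __post_init__(self) -> None:
        if self.block_length <= 0 or self.n_max <= 0:
            raise ConfigurationError("block_length and n_max must be positive")
        if not (0.0 < self.match_rate < 1.0):
            raise ConfigurationError("match_rate must be in (0, 1)")
        if self.dprime_start > self.dprime_cap:
            raise ConfigurationError("dprime_start must not exceed dprime_cap")
        if not (self.maxrt_min <= self.maxrt_start <= self.maxrt_max):
            raise ConfigurationError("maxrt_start must lie in [maxrt_min, maxrt_max]")
        for name in ("dprime_step", "maxrt_step", "expected_total_hours",
                     "decrement_milestone_frac", "maxrt_min", "iti_seconds"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.stimulus_pool_size < 2:
            raise ConfigurationError("stimulus_pool_size must be >= 2")

    @property
    def n_threshold_epochs(self) -> int:
        """Number of sub-cap threshold epochs (12 under the defaults: 0.6..2.8)."""
        return int(round((self.dprime_cap - self.dprime_start) / self.dprime_step))


@dataclass
class EngineState:
    """Live parameters of the adaptive controller between blocks."""

    n_contexts: int = 1
    threshold_epoch: int = 0
    maxrt: float = 5.0
    consecutive_failures: int = 0
    elapsed_seconds: float = 0.0
    milestones_crossed: int = 0
    terminal: bool = False
    unlock_count: int = 0

    def dprime_threshold(self, config: EngineConfig) -> float:
        return min(config.dprime_start + self.threshold_epoch * config.dprime_step,
                   config.dprime_cap)

    def validate(self, config: EngineConfig) -> None:
        if not (1 <= self.n_contexts <= config.n_max):
            raise ConfigurationError(
                f"n_contexts={self.n_contexts} outside 1..{config.n_max}")
        if not (config.maxrt_min - 1e-9 <= self.maxrt <= config.maxrt_max + 1e-9):
            raise ConfigurationError(f"maxrt={self.maxrt} out of bounds")
        offset = (self.maxrt - config.maxrt_start) / config.maxrt_step
        if abs(offset - round(offset)) > 1e-9:
            raise ConfigurationError("maxrt is not on the step grid")


@dataclass(frozen=True)
class Trial:
    index: int
    context_id: int
    stimulus_id: int
    is_match: bool
    is_switch: bool
    # an "update" trial presents a new stimulus in its context, forcing the
    # stored item for that context to be replaced; recorded as metadata only
    is_update: bool


@dataclass(frozen=True)
class TrialResult:
    response: str  # "match" | "nonmatch" | "timeout"
    rt: Optional[float]
    category: str  # "hit" | "correct_rejection" | "miss" | "false_alarm"


@dataclass(frozen=True)
class BlockRecord:
    block_index: int
    n: int
    dprime_threshold: float
    maxrt: float
    hit: int
    cr: int
    miss: int
    fa: int
    dprime: float
    score: float
    passed: bool
    duration_seconds: float
    cumulative_hours: float


def generate_block_trials(state: EngineState, config: EngineConfig,
                          rng: np.random.Generator) -> list[Trial]:
    """Generate one block of trials under the current number of contexts.

    Each context is seeded with an unscored preview stimulus before trial 1,
    so every scored trial has a defined match/non-match status and the
    accuracy range stays 0..block_length.  The context sequence is uniform
    random; the match/non-match status of each trial is Bernoulli(match_rate),
    realised by either repeating the context's last stimulus or drawing a
    different one from the pool.
    """
    state.validate(config)
    n = state.n_contexts
    pool = config.stimulus_pool_size
    last = {c: int(rng.integers(0, pool)) for c in range(1, n + 1)}
    trials: list[Trial] = []
    prev_context: Optional[int] = None
    for i in range(config.block_length):
        c = int(rng.integers(1, n + 1))
        is_match = bool(rng.random() < config.match_rate)
        if is_match:
            stim = last[c]
        else:
            stim = int(rng.integers(0, pool - 1))
            if stim >= last[c]:
                stim += 1
        trials.append(Trial(
            index=i + 1,
            context_id=c,
            stimulus_id=stim,
            is_match=is_match,
            is_switch=(prev_context is not None and c != prev_context),
            is_update=not is_match,
        ))
        last[c] = stim
        prev_context = c
    return trials


_CATEGORY = {
    (True, "match"): "hit",
    (True, "nonmatch"): "miss",
    (False, "nonmatch"): "correct_rejection",
    (False, "match"): "false_alarm",
}


def classify_response(trial: Trial, response: str, rt: Optional[float],
                      maxrt: float) -> TrialResult:
    """Map a response to the signal-detection category.

    A timeout is always scored as a miss (the deployed rule marks the trial
    as a miss when no input arrives within MaxRT, regardless of whether the
    trial was a match).
    """
    if response == "timeout":
        return TrialResult(response="timeout", rt=None, category="miss")
    if response not in ("match", "nonmatch"):
        raise ValueError(f"unknown response {response!r}")
    if rt is None or rt < 0:
        raise ValueError("a non-timeout response requires rt >= 0")
    if rt > maxrt:
        raise ValueError(f"rt={rt} exceeds maxrt={maxrt} for a non-timeout response")
    return TrialResult(response=response, rt=rt,
                       category=_CATEGORY[(trial.is_match, response)])


def block_dprime(hit: int, miss: int, fa: int, cr: int) -> float:
    """Corrected discriminability d' for one block.

    d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate), with rates of exactly
    0 or 1 replaced by 1/(2N) or 1 - 1/(2N) (N = trial count of that class)
    so the quantiles stay finite at floor/ceiling.
    """
    if min(hit, miss, fa, cr) < 0:
        raise ValueError("counts must be non-negative")
    n_sig = hit + miss
    n_noise = fa + cr
    if n_sig == 0 or n_noise == 0:
        raise DegenerateBlockError("block has no trials of one stimulus class")
    hit_rate = hit / n_sig
    fa_rate = fa / n_noise
    if hit_rate == 0.0:
        hit_rate = 1.0 / (2 * n_sig)
    elif hit_rate == 1.0:
        hit_rate = 1.0 - 1.0 / (2 * n_sig)
    if fa_rate == 0.0:
        fa_rate = 1.0 / (2 * n_noise)
    elif fa_rate == 1.0:
        fa_rate = 1.0 - 1.0 / (2 * n_noise)
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def block_score(hit: int, cr: int, miss: int, fa: int, dprime: float,
                maxrt: float) -> float:
    """Game score: 100(Hit+CR) - 50(Miss+FA) + 1000 d'(7 - MaxRT)."""
    return 100.0 * (hit + cr) - 50.0 * (miss + fa) + 1000.0 * dprime * (7.0 - maxrt)


def update_difficulty(state: EngineState, record: BlockRecord,
                      config: EngineConfig) -> tuple[EngineState, list[str]]:
    """Advance the adaptive controller after one block.

    Pass (d' >= threshold): n rises until 6; a pass at n = 6 raises the
    threshold one epoch and resets n to 1 (unlock event); the pass at the
    final sub-cap epoch (threshold 2.8 under defaults) sets the threshold to
    its cap and freezes the progression.  Fail: the failure streak counts up
    and every ``fail_streak_for_relief``-th consecutive failure relaxes MaxRT
    by one step (counter reset).  Independently, every newly crossed
    10%-of-expected-time milestone tightens MaxRT by one step; when both fire
    between the same blocks the decrement is applied before the increment.
    """
    if record.n != state.n_contexts or abs(
            record.dprime_threshold - state.dprime_threshold(config)) > 1e-9:
        raise ValueError("block record does not match engine state")
    events: list[str] = []
    new = replace(state)
    new.elapsed_seconds = state.elapsed_seconds + record.duration_seconds

    # milestone decrements first
    milestone_seconds = (config.decrement_milestone_frac
                         * config.expected_total_hours * 3600.0)
    total_milestones = int(new.elapsed_seconds // milestone_seconds)
    for _ in range(total_milestones - new.milestones_crossed):
        if new.maxrt - config.maxrt_step >= config.maxrt_min - 1e-9:
            new.maxrt = round(new.maxrt - config.maxrt_step, 6)
            events.append("maxrt_decrement")
    new.milestones_crossed = total_milestones

    if record.passed:
        new.consecutive_failures = 0
        if not new.terminal:
            if new.n_contexts < config.n_max:
                new.n_contexts += 1
                events.append("context_up")
            elif new.threshold_epoch < config.n_threshold_epochs - 1:
                new.threshold_epoch += 1
                new.n_contexts = 1
                new.unlock_count += 1
                events.append("threshold_up")
                events.append("unlock")
            else:
                # final pass: threshold jumps to its cap and difficulty freezes
                new.threshold_epoch = config.n_threshold_epochs
                new.terminal = True
                new.unlock_count += 1
                events.append("threshold_up")
                events.append("unlock")
                events.append("terminal")
    else:
        new.consecutive_failures += 1
        if new.consecutive_failures % config.fail_streak_for_relief == 0:
            if new.maxrt + config.maxrt_step <= config.maxrt_max + 1e-9:
                new.maxrt = round(new.maxrt + config.maxrt_step, 6)
                events.append("maxrt_relief")
            new.consecutive_failures = 0
    return new, events


Responder = Callable[[Trial, EngineState], tuple[str, Optional[float]]]


def play_block(state: EngineState, config: EngineConfig, respond: Responder,
               rng: np.random.Generator, block_index: int = 1) -> BlockRecord:
    """Run one block: generate trials, collect responses, score the block.

    ``respond`` maps (trial, state) to a (response, rt) pair; responses with
    rt beyond MaxRT must be delivered as ("timeout", None).  Block duration
    is the sum of per-trial times (rt, or MaxRT on timeout) plus a fixed
    inter-trial interval.
    """
    trials = generate_block_trials(state, config, rng)
    counts = {"hit": 0, "correct_rejection": 0, "miss": 0, "false_alarm": 0}
    duration = 0.0
    for trial in trials:
        response, rt = respond(trial, state)
        result = classify_response(trial, response, rt, state.maxrt)
        counts[result.category] += 1
        duration += (state.maxrt if result.rt is None else result.rt) + config.iti_seconds
    hit, cr = counts["hit"], counts["correct_rejection"]
    miss, fa = counts["miss"], counts["false_alarm"]
    dp = block_dprime(hit, miss, fa, cr)
    threshold = state.dprime_threshold(config)
    return BlockRecord(
        block_index=block_index,
        n=state.n_contexts,
        dprime_threshold=threshold,
        maxrt=state.maxrt,
        hit=hit, cr=cr, miss=miss, fa=fa,
        dprime=dp,
        score=block_score(hit, cr, miss, fa, dp, state.maxrt),
        passed=dp >= threshold,
        duration_seconds=duration,
        cumulative_hours=(state.elapsed_seconds + duration) / 3600.0,
    )
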
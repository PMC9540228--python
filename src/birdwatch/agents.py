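"""Synthetic participants for the adaptive n-match engine.

There is no public trial dataset for this task, so cohorts are simulated
from an explicit generative model chosen to reproduce the study conditions:

* a logistic psychometric response model whose correct-response probability
  is floored at 0.5 (guessing), so chance-level unscaled accuracy is 40/80;
* latent ability grows with the log of the global block index, which makes
  the Simple Score trajectory logarithmic, matching the observed group-level
  learning shape;
* day-level psychosocial states (wellbeing, stress, busyness, mood, sleep)
  follow stationary AR(1) processes, enter the ability logit linearly
  through per-agent coefficients, and are reported once per session through
  a 1-5 Likert survey plus sleep hours;
* adherence is heterogeneous: total trained hours average 17.35 h with SD
  5.93 h across the cohort, with an explicit early-discontinuation path
  (mean stopping time 3.48 h) mirroring the three observed adherence groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .engine import (EngineConfig, EngineState, Trial, play_block,
                     update_difficulty)

__all__ = [
    "AgentParams",
    "DailySurvey",
    "LatentDayState",
    "LIKERT_CUTPOINTS",
    "CONTEXT_VARS",
    "agent_respond",
    "generate_survey",
    "advance_day_state",
    "initial_day_state",
    "sample_total_hours",
    "simulate_participant",
    "sample_cohort",
]

# daily context variables in survey column order
CONTEXT_VARS = ("wellbeing", "stress", "busyness", "mood", "sleep")

# fixed cut-points discretising a standard-normal latent into Likert 1..5
LIKERT_CUTPOINTS = (-1.5, -0.5, 0.5, 1.5)

_SLEEP_MEAN = 7.0
_SLEEP_SD = 1.2


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant.

    Ability is expressed in logit units of the above-chance probability:
    P(correct) = lapse/2 + (1-lapse) * [0.5 + 0.5 * logistic(eta)] with
    eta = ability_base + ability_gain*ln(t) - load_cost*(n-1)
          - epoch_cost*epoch + context_coefs . x_day + eps_day.
    """

    ability_base: float = -0.5
    ability_gain: float = 0.55
    load_cost: float = 0.25
    epoch_cost: float = 0.18
    lapse_rate: float = 0.02
    context_coefs: dict[str, float] = field(default_factory=dict)
    day_noise_sd: float = 0.25
    rt_median: float = 0.9          # seconds; scale of the log-normal RT
    rt_log_sd: float = 0.35         # sigma of log RT
    adherence_hours_mean: float = 17.35
    adherence_hours_sd: float = 5.93
    session_hours_mean: float = 0.67
    dropout_prob: float = 5.0 / 37.0
    dropout_hours_mean: float = 3.48
    ar_phi: float = 0.5             # AR(1) coefficient of the daily latents

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.rt_median <= 0 or self.rt_log_sd <= 0:
            raise ValueError("response-time parameters must be positive")
        if self.adherence_hours_mean <= 0 or self.adherence_hours_sd <= 0:
            raise ValueError("adherence parameters must be positive")
        if abs(self.ar_phi) >= 1.0:
            raise ValueError("ar_phi must have magnitude < 1 (stationary latents)")
        unknown = set(self.context_coefs) - set(CONTEXT_VARS)
        if unknown:
            raise ValueError(f"unknown context variables: {sorted(unknown)}")


@dataclass(frozen=True)
class DailySurvey:
    day_index: int
    wellbeing: int
    stress: int
    busyness: int
    mood: int
    sleep_hours: float


@dataclass(frozen=True)
class LatentDayState:
    """Continuous daily psychosocial state (standard-normal scale latents).

    ``sleep`` is kept on its standardized scale here; hours are recovered as
    7 + 1.2 * sleep when the survey is generated.
    """

    day_index: int
    wellbeing: float
    stress: float
    busyness: float
    mood: float
    sleep: float
    eps: float  # idiosyncratic daily ability perturbation, already scaled

    def vector(self) -> np.ndarray:
        return np.array([self.wellbeing, self.stress, self.busyness,
                         self.mood, self.sleep])


def initial_day_state(rng: np.random.Generator, agent: AgentParams,
                      day_index: int = 1) -> LatentDayState:
    vals = rng.normal(0.0, 1.0, size=5)
    return LatentDayState(day_index, *vals,
                          eps=rng.normal(0.0, agent.day_noise_sd))


def advance_day_state(state: LatentDayState, rng: np.random.Generator,
                      agent: AgentParams, n_days: int = 1) -> LatentDayState:
    """Step the AR(1) latents forward ``n_days`` calendar days."""
    phi = agent.ar_phi
    innov_sd = math.sqrt(1.0 - phi * phi)
    vals = state.vector()
    for _ in range(n_days):
        vals = phi * vals + rng.normal(0.0, innov_sd, size=5)
    return LatentDayState(state.day_index + n_days, *vals,
                          eps=rng.normal(0.0, agent.day_noise_sd))


def generate_survey(day: LatentDayState,
                    rng: Optional[np.random.Generator] = None) -> DailySurvey:
    """Discretize the latent day state into the four Likert items + sleep.

    Discretization is deterministic given the latents (fixed cut-points);
    ``rng`` is accepted for interface symmetry but unused.
    """
    def likert(x: float) -> int:
        return 1 + int(np.searchsorted(LIKERT_CUTPOINTS, x, side="right"))

    sleep = float(np.clip(_SLEEP_MEAN + _SLEEP_SD * day.sleep, 0.0, 14.0))
    return DailySurvey(
        day_index=day.day_index,
        wellbeing=likert(day.wellbeing),
        stress=likert(day.stress),
        busyness=likert(day.busyness),
        mood=likert(day.mood),
        sleep_hours=round(sleep, 2),
    )


def _ability(agent: AgentParams, n: int, epoch: int, day: LatentDayState,
             t: int) -> float:
    eta = (agent.ability_base
           + agent.ability_gain * math.log(max(t, 1))
           - agent.load_cost * (n - 1)
           - agent.epoch_cost * epoch)
    if agent.context_coefs:
        x = dict(zip(CONTEXT_VARS, day.vector()))
        eta += sum(coef * x[name] for name, coef in agent.context_coefs.items())
    return eta + day.eps


def p_correct(agent: AgentParams, n: int, epoch: int, day: LatentDayState,
              t: int) -> float:
    """Probability of a correct response on one trial of block ``t``."""
    eta = _ability(agent, n, epoch, day, t)
    base = 0.5 + 0.5 / (1.0 + math.exp(-eta)) if eta > -700 else 0.5
    return agent.lapse_rate * 0.5 + (1.0 - agent.lapse_rate) * base


def agent_respond(trial: Trial, block_context: tuple[int, int, float],
                  agent: AgentParams, day: LatentDayState, t: int,
                  rng: np.random.Generator) -> tuple[str, Optional[float]]:
    """Respond to one trial: correct with probability p_correct, RT log-normal.

    Draws exceeding MaxRT are delivered as timeouts (scored as misses by the
    engine), so tighter response windows degrade effective accuracy.
    """
    n, epoch, maxrt = block_context
    p = p_correct(agent, n, epoch, day, t)
    correct = rng.random() < p
    rt = agent.rt_median * math.exp(agent.rt_log_sd * rng.standard_normal())
    if rt >= maxrt:
        return "timeout", None
    if correct:
        return ("match" if trial.is_match else "nonmatch"), rt
    return ("nonmatch" if trial.is_match else "match"), rt


def sample_total_hours(agent: AgentParams, rng: np.random.Generator) -> tuple[float, bool]:
    """Sample total trained hours and whether the agent discontinued early.

    Mixture calibrated so the cohort matches the target adherence moments
    (mean 17.35 h, SD 5.93 h under the defaults): with probability
    ``dropout_prob`` an exponential stopping time (mean
    ``dropout_hours_mean``); otherwise a truncated normal whose mean is
    solved from the mixture identity and whose SD (~2.0 h) makes the overall
    mixture SD equal the target.
    """
    dropout = bool(rng.random() < agent.dropout_prob)
    if dropout:
        hours = float(rng.exponential(agent.dropout_hours_mean))
        return max(hours, 0.5), True
    p = agent.dropout_prob
    mu_d, sd_d = agent.dropout_hours_mean, agent.dropout_hours_mean  # exponential
    mu = agent.adherence_hours_mean
    mu_nd = (mu - p * mu_d) / (1.0 - p)
    # mixture variance: p(sd_d^2 + (mu_d-mu)^2) + (1-p)(sd_nd^2 + (mu_nd-mu)^2)
    resid = (agent.adherence_hours_sd ** 2
             - p * (sd_d ** 2 + (mu_d - mu) ** 2)
             - (1.0 - p) * (mu_nd - mu) ** 2)
    sd_nd = math.sqrt(max(resid / (1.0 - p), 0.25))
    for _ in range(100):
        hours = float(rng.normal(mu_nd, sd_nd))
        if 1.0 <= hours <= 35.0:
            return hours, False
    return mu_nd, False


def simulate_participant(agent: AgentParams, engine_config: EngineConfig,
                         seed: int | np.random.SeedSequence,
                         participant_id: str = "p001",
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one participant's full training history.

    Sessions are scheduled 2-3 per week on random weekdays until the sampled
    total hours are reached (or the agent drops out).  The engine state
    persists across sessions; one daily survey is emitted per session before
    its first block.  Returns (block log, survey log) as tidy DataFrames.
    """
    rng = np.random.default_rng(seed)
    total_hours, dropout = sample_total_hours(agent, rng)
    total_seconds = total_hours * 3600.0

    config = engine_config
    state = EngineState(maxrt=config.maxrt_start)
    day_state = initial_day_state(rng, agent, day_index=0)

    blocks: list[dict] = []
    surveys: list[dict] = []
    t = 0  # global block index
    week = 0
    done = False
    while not done:
        n_sessions = int(rng.integers(2, 4))  # 2 or 3 sessions this week
        offsets = np.sort(rng.choice(7, size=n_sessions, replace=False))
        for off in offsets:
            day_index = 7 * week + int(off) + 1
            day_state = advance_day_state(day_state, rng, agent,
                                          n_days=day_index - day_state.day_index)
            survey = generate_survey(day_state)
            surveys.append({"participant_id": participant_id, **vars(survey)})

            session_len = max(rng.normal(agent.session_hours_mean, 0.25), 0.15) * 3600.0
            session_elapsed = 0.0
            while True:
                t += 1
                ctx = (state.n_contexts, min(state.threshold_epoch, 11), state.maxrt)

                def respond(trial: Trial, st: EngineState,
                            _ctx=ctx) -> tuple[str, Optional[float]]:
                    return agent_respond(trial, _ctx, agent, day_state, t, rng)

                record = play_block(state, config, respond, rng, block_index=t)
                blocks.append({"participant_id": participant_id,
                               "day_index": day_index, **vars(record)})
                session_elapsed += record.duration_seconds
                state, _ = update_difficulty(state, record, config)
                if state.elapsed_seconds >= total_seconds:
                    done = True
                    break
                if session_elapsed >= session_len:
                    break
            if done:
                break
        week += 1

    block_df = pd.DataFrame(blocks)
    survey_df = pd.DataFrame(surveys)
    return block_df, survey_df


def sample_cohort(n_participants: int, seed: int | np.random.SeedSequence,
                  context_sensitive_frac: float = 0.5,
                  base_params: Optional[AgentParams] = None) -> list[AgentParams]:
    """Draw a heterogeneous cohort of agent parameter sets.

    Ability parameters vary between subjects; a ``context_sensitive_frac``
    fraction of agents receive nonzero (negative) coefficients on one or two
    daily context variables, mirroring the observed split between
    context-predicted and context-independent participants.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    rng = np.random.default_rng(seed)
    base = base_params or AgentParams()
    n_sensitive = int(round(context_sensitive_frac * n_participants))
    sensitive = np.zeros(n_participants, dtype=bool)
    sensitive[rng.permutation(n_participants)[:n_sensitive]] = True

    cohort = []
    for i in range(n_participants):
        coefs: dict[str, float] = {}
        if sensitive[i]:
            k = int(rng.integers(1, 3))
            for name in rng.choice(CONTEXT_VARS, size=k, replace=False):
                coefs[str(name)] = float(-abs(rng.normal(0.45, 0.1)))
        cohort.append(replace(
            base,
            ability_base=float(rng.normal(base.ability_base, 0.35)),
            ability_gain=float(max(rng.normal(base.ability_gain, 0.12), 0.05)),
            load_cost=float(max(rng.normal(base.load_cost, 0.05), 0.02)),
            epoch_cost=float(max(rng.normal(base.epoch_cost, 0.04), 0.02)),
            context_coefs=coefs,
        ))
    return cohort
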
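"""Synthetic choice policies standing in for human participants.

None of these agents is a cognitive model fitted to human data; they are
data generators whose statistical structure is known in closed form, so the
analysis pipeline can be validated against analytic oracles:

- ``random``: uniform over the three positions.
- ``attribute``: picks the option with the highest *perceived* payoff,
  where the perceived area carries multiplicative Gaussian noise (areas are
  judged visually; prices are printed numerals and read exactly).
- ``cue_hybrid``: follows the cue with a fixed probability ``w`` (or, for
  parameter-recovery designs, an affine probability ``w0 + w1*h`` in the
  historical predictivity ``h``), otherwise falls back to another policy.
- ``matching_learner``: probability matching — follows the cue with
  probability equal to the historical predictivity experienced so far.

A cue-following probability ``w`` mixed with a uniform fallback yields
``P(choose cue) = w + (1 - w)/3``, so a matching learner produces a
test-round regression of cue choice on historical predictivity with slope
2/3, not 1 — the mixture correction the recovery tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .environment import (
    POSITIONS,
    Condition,
    RoundKind,
    Session,
    SessionConfig,
    Trial,
    generate_session,
)

__all__ = [
    "POLICIES",
    "AgentParams",
    "ChoiceRecord",
    "random_choice",
    "attribute_choice",
    "cue_hybrid_choice",
    "matching_learner_choice",
    "choose",
    "simulate_session",
    "simulate_study",
    "CHOICE_COLUMNS",
]

POLICIES = ("random", "attribute", "cue_hybrid", "matching_learner")

#: Empty-history convention: before any feedback the cue is worth chance.
CHANCE_PRIOR = 1.0 / 3.0


@dataclass(slots=True)
class AgentParams:
    """Parameters of a synthetic choice policy.

    ``cue_weight`` is the fixed cue-following probability of the
    ``cue_hybrid`` policy. If ``intercept_weight`` is set, the hybrid agent
    instead follows the cue with the affine probability
    ``intercept_weight + cue_weight * h`` (clipped to [0, 1]), which is the
    configuration used for parameter-recovery checks. ``perceptual_sd`` is
    the multiplicative noise scale on perceived areas for the ``attribute``
    policy and the fallback of the hybrid policies.
    """

    policy: str = "matching_learner"
    cue_weight: float = 0.0
    intercept_weight: Optional[float] = None
    perceptual_sd: float = 0.0
    fallback: str = "random"

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.fallback not in ("random", "attribute"):
            raise ValueError("fallback must be 'random' or 'attribute'")
        if not 0.0 <= self.cue_weight <= 1.0:
            raise ValueError("cue_weight must lie in [0, 1]")
        if self.intercept_weight is not None:
            if self.intercept_weight < 0 or (
                self.intercept_weight + self.cue_weight > 1.0 + 1e-12
            ):
                raise ValueError(
                    "affine cue response needs w0 >= 0 and w0 + w1 <= 1"
                )
        if self.perceptual_sd < 0:
            raise ValueError("perceptual_sd must be nonnegative")


@dataclass(slots=True)
class ChoiceRecord:
    """One observed choice with the regressors the analysis consumes."""

    participant_id: str
    condition: str
    assigned_predictivity: float
    round_index: int
    round_kind: str
    chosen_position: str
    chose_cue_option: int
    realised_payoff: float
    cue_predictive: int
    historical_predictivity: float  # NaN on round 1 (no history yet)
    cue_position: str
    superior_position: str
    chose_superior: int


CHOICE_COLUMNS = [
    "participant_id",
    "condition",
    "assigned_predictivity",
    "round_index",
    "round_kind",
    "chosen_position",
    "chose_cue_option",
    "realised_payoff",
    "cue_predictive",
    "historical_predictivity",
    "cue_position",
    "superior_position",
    "chose_superior",
]


def random_choice(trial: Trial, rng: np.random.Generator) -> str:
    """Uniform choice over the three positions."""
    return POSITIONS[int(rng.integers(0, 3))]


def attribute_choice(
    trial: Trial, perceptual_sd: float, rng: np.random.Generator
) -> str:
    """Choose the option maximising the perceived payoff.

    Perceived payoff of option i is ``area_i * (1 + e_i) - price_i`` with
    ``e_i ~ Normal(0, perceptual_sd)`` independent across options. With no
    noise this returns the superior position. Ties (possible only with
    degenerate inputs) go to the leftmost contender.
    """
    if perceptual_sd == 0.0:
        perceived = [o.area - o.price for o in trial.options]
    else:
        eps = rng.normal(0.0, perceptual_sd, 3)
        perceived = [
            o.area * (1.0 + eps[i]) - o.price for i, o in enumerate(trial.options)
        ]
    best = max(range(3), key=lambda i: (perceived[i], -i))
    return trial.options[best].position


def _fallback_choice(
    trial: Trial, params: AgentParams, rng: np.random.Generator
) -> str:
    if params.fallback == "attribute":
        return attribute_choice(trial, params.perceptual_sd, rng)
    return random_choice(trial, rng)


def cue_hybrid_choice(
    trial: Trial,
    w: float,
    rng: np.random.Generator,
    fallback: Callable[[Trial, np.random.Generator], str] = random_choice,
) -> str:
    """Follow the cue with probability ``w``; otherwise delegate to
    ``fallback``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if rng.uniform() < w:
        return trial.cue_position
    return fallback(trial, rng)


def historical_share(flags: Sequence[int]) -> float:
    """Mean of the cue-predictive flags seen so far; chance (1/3) when the
    history is empty."""
    if len(flags) == 0:
        return CHANCE_PRIOR
    return float(np.mean(flags))


def matching_learner_choice(
    trial: Trial,
    history: Sequence[int],
    rng: np.random.Generator,
    fallback: Callable[[Trial, np.random.Generator], str] = random_choice,
) -> str:
    """Probability matching: follow the cue with probability equal to the
    historical predictivity experienced so far (1/3 before any feedback)."""
    return cue_hybrid_choice(trial, historical_share(history), rng, fallback)


def choose(
    trial: Trial,
    params: AgentParams,
    history: Sequence[int],
    rng: np.random.Generator,
) -> str:
    """Dispatch one choice for the configured policy.

    The choice at round r depends only on the current trial, the history of
    cue-predictive flags from rounds before r, and the generator state.
    """
    if params.policy == "random":
        return random_choice(trial, rng)
    if params.policy == "attribute":
        return attribute_choice(trial, params.perceptual_sd, rng)
    if params.policy == "cue_hybrid":
        if params.intercept_weight is None:
            w = params.cue_weight
        else:
            h = historical_share(history)
            w = min(1.0, max(0.0, params.intercept_weight + params.cue_weight * h))
        return cue_hybrid_choice(
            trial, w, rng, lambda t, g: _fallback_choice(t, params, g)
        )
    return matching_learner_choice(
        trial, history, rng, lambda t, g: _fallback_choice(t, params, g)
    )


def simulate_session(
    session: Session,
    params: AgentParams,
    rng: np.random.Generator,
    *,
    include_practice_in_history: bool = True,
) -> list[ChoiceRecord]:
    """Run an agent through a session, updating the cue history online.

    Feedback is full: the cue-predictive flag of every round enters the
    history whether or not the agent chose the cue option. The recorded
    ``historical_predictivity`` at round r is the share of predictive
    rounds among rounds 1..r-1 (NaN at r = 1, where it is undefined).
    """
    records: list[ChoiceRecord] = []
    flags: list[int] = []
    for trial in session.trials:
        h = float(np.mean(flags)) if flags else math.nan
        pos = choose(trial, params, flags, rng)
        chosen = trial.option_at(pos)
        records.append(
            ChoiceRecord(
                participant_id=session.participant_id,
                condition=session.config.condition.value,
                assigned_predictivity=session.config.assigned_predictivity,
                round_index=trial.round_index,
                round_kind=trial.round_kind.value,
                chosen_position=pos,
                chose_cue_option=int(pos == trial.cue_position),
                realised_payoff=chosen.area - chosen.price,
                cue_predictive=trial.cue_predictive,
                historical_predictivity=h,
                cue_position=trial.cue_position,
                superior_position=trial.superior_position,
                chose_superior=int(pos == trial.superior_position),
            )
        )
        if include_practice_in_history or trial.round_kind is not RoundKind.PRACTICE:
            flags.append(trial.cue_predictive)
    return records


def simulate_study(
    n_per_condition: int,
    agent: AgentParams,
    *,
    conditions: Sequence[str | Condition] = ("decoy", "default", "rule"),
    config_template: Optional[SessionConfig] = None,
    predictivity_sampler: Optional[
        Callable[[np.random.Generator], float]
    ] = None,
    seed: int = 0,
    include_practice_in_history: bool = True,
) -> pd.DataFrame:
    """Simulate a full study and return the long-format choice dataset.

    For each condition, ``n_per_condition`` sessions are generated with an
    assigned predictivity drawn per participant (Uniform(0, 1) by default),
    and the agent is run through all rounds. The result has one row per
    participant x round in the canonical analysis schema and is a
    deterministic function of ``seed``.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    template = config_template or SessionConfig()
    root = np.random.SeedSequence(seed)
    records: list[ChoiceRecord] = []
    for cond in (Condition(c) for c in conditions):
        cond_seq = root.spawn(1)[0]
        draw_rng = np.random.default_rng(cond_seq)
        session_seeds = cond_seq.spawn(n_per_condition)
        for i in range(n_per_condition):
            if predictivity_sampler is None:
                p = float(draw_rng.uniform(0.0, 1.0))
            else:
                p = float(predictivity_sampler(draw_rng))
            config = replace(
                template,
                condition=cond,
                assigned_predictivity=p,
                seed=int(session_seeds[i].generate_state(1)[0] >> 1),
            )
            session = generate_session(config, f"{cond.value}-{i:04d}")
            agent_rng = np.random.default_rng(session_seeds[i].spawn(1)[0])
            records.extend(
                simulate_session(
                    session,
                    agent,
                    agent_rng,
                    include_practice_in_history=include_practice_in_history,
                )
            )
    rows = [[getattr(r, c) for c in CHOICE_COLUMNS] for r in records]
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)
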
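"""Stochastic generator for the three-option cue-learning choice task.

The simulated task presents three geometric shapes per round, each with a
visible area and a price; choosing an option pays its area minus its price.
One stimulus characteristic acts as a *cue* for the highest-payoff
("superior") option, depending on the between-participant condition:

- ``decoy``: one option has a dominated decoy (same shape, smaller area,
  higher price) attached to it;
- ``default``: one option is pre-selected;
- ``rule``: one option bears the participant's "indicator shape".

On *treatment* rounds the cue lands on the superior option with probability
``p`` (the participant's assigned predictivity). On *test* rounds the cue is
unpredictive in expectation: placed on the superior or second-best option
with equal probability (decoy) or uniformly over all three options (default,
rule). Sessions consist of 3 practice rounds followed by a random
interleaving of 28 treatment and 12 test rounds, 43 rounds in total.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SHAPES",
    "POSITIONS",
    "Condition",
    "RoundKind",
    "OptionSpec",
    "SessionConfig",
    "Trial",
    "Session",
    "draw_option_set",
    "make_decoy",
    "build_trial",
    "generate_session",
]

#: The six geometric shapes an option can take.
SHAPES: tuple[str, ...] = (
    "vertical_rectangle",
    "horizontal_rectangle",
    "vertical_ellipse",
    "horizontal_ellipse",
    "square",
    "circle",
)

#: Screen positions, in canonical left-to-right order (also the tie-break order).
POSITIONS: tuple[str, ...] = ("left", "middle", "right")


class Condition(str, enum.Enum):
    """Between-participant cue-type condition."""

    DECOY = "decoy"
    DEFAULT = "default"
    RULE = "rule"


class RoundKind(str, enum.Enum):
    """Round type: practice rounds behave like treatment rounds but are
    excluded from hypothesis tests; test rounds carry an unpredictive cue."""

    PRACTICE = "practice"
    TREATMENT = "treatment"
    TEST = "test"


@dataclass(slots=True)
class OptionSpec:
    """One choice option: a shape with an area, a price, and cue-role flags.

    The payoff of an option is ``area - price``, exactly; areas and prices
    are stored as drawn (integers for plain options, possibly fractional for
    decoys, whose construction conserves the payoff in continuous units).
    """

    shape: str
    area: float
    price: float
    position: str
    has_decoy: bool = False
    is_decoy: bool = False
    is_default: bool = False
    is_indicator: bool = False

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if not self.area > 0:
            raise ValueError(f"area must be positive, got {self.area}")
        if self.price < 0:
            raise ValueError(f"price must be nonnegative, got {self.price}")
        if self.is_decoy and self.has_decoy:
            raise ValueError("an option cannot both be a decoy and have one")

    @property
    def payoff(self) -> float:
        """Payoff collected when this option is chosen: area minus price."""
        return self.area - self.price


@dataclass(slots=True)
class SessionConfig:
    """Generating parameters for one synthetic participant session.

    Payoffs are drawn from ``Normal(payoff_mean, payoff_sd)`` and prices
    from ``Normal(price_mean, price_sd)`` truncated below at 1; the area of
    an option is payoff + price. Defaults are chosen so that displayed
    magnitudes resemble the task (area ~ 180, price ~ 55, payoff ~ 130).
    """

    condition: Condition = Condition.DECOY
    assigned_predictivity: float = 0.5
    payoff_mean: float = 130.0
    payoff_sd: float = 30.0
    price_mean: float = 55.0
    price_sd: float = 15.0
    n_practice: int = 3
    n_treatment: int = 28
    n_test: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if not 0.0 <= self.assigned_predictivity <= 1.0:
            raise ValueError("assigned_predictivity must lie in [0, 1]")
        if self.payoff_sd <= 0 or self.price_sd <= 0:
            raise ValueError("payoff_sd and price_sd must be positive")
        if min(self.n_practice, self.n_treatment, self.n_test) < 0:
            raise ValueError("round counts must be nonnegative")

    @property
    def n_rounds(self) -> int:
        return self.n_practice + self.n_treatment + self.n_test


@dataclass(slots=True)
class Trial:
    """One round: three options, the cue placement, and the outcome flags.

    ``cue_predictive`` is the dummy that equals 1 when the cue-indicated
    option is also the superior (highest-payoff) option.
    """

    round_index: int
    round_kind: RoundKind
    options: tuple[OptionSpec, OptionSpec, OptionSpec]
    cue_position: str
    superior_position: str
    cue_predictive: int
    decoy_proportion: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.options) != 3:
            raise ValueError("a trial needs exactly 3 options")
        if len({o.position for o in self.options}) != 3:
            raise ValueError("option positions must be distinct")
        payoffs = [o.payoff for o in self.options]
        best = max(payoffs)
        if payoffs.count(best) != 1:
            raise ValueError("superior option must be unique")
        if self.options[int(np.argmax(payoffs))].position != self.superior_position:
            raise ValueError("superior_position does not match option payoffs")
        if self.cue_predictive != int(self.cue_position == self.superior_position):
            raise ValueError("cue_predictive inconsistent with cue placement")

    def option_at(self, position: str) -> OptionSpec:
        for o in self.options:
            if o.position == position:
                return o
        raise KeyError(position)

    @property
    def superior_option(self) -> OptionSpec:
        return self.option_at(self.superior_position)

    @property
    def cue_option(self) -> OptionSpec:
        return self.option_at(self.cue_position)


@dataclass(slots=True)
class Session:
    """One synthetic participant: condition, assigned predictivity, and the
    full ordered sequence of trials."""

    participant_id: str
    config: SessionConfig
    trials: tuple[Trial, ...]
    indicator_shape: Optional[str] = None

    def __post_init__(self) -> None:
        if self.config.condition is Condition.RULE and self.indicator_shape is None:
            raise ValueError("rule sessions need an indicator shape")


_MAX_REDRAWS = 1000


def draw_option_set(
    config: SessionConfig, rng: np.random.Generator
) -> list[OptionSpec]:
    """Draw three options, returned ranked best-payoff first.

    Three payoffs are drawn from one normal distribution and ranked; each
    option's price comes from a second normal distribution (truncated below
    at 1) and its area is payoff + price. Areas and prices are rounded to
    integers as displayed, and payoffs are recomputed on the rounded values
    so the on-screen arithmetic is exact. Shapes are i.i.d. uniform over the
    six shapes and positions are a uniform permutation of left/middle/right.

    Rounded payoff ties (or nonpositive areas) trigger a re-draw; an
    impossible configuration (e.g. a degenerate payoff distribution) raises
    ``RuntimeError`` after a bounded number of attempts.
    """
    for _ in range(_MAX_REDRAWS):
        payoffs = np.sort(rng.normal(config.payoff_mean, config.payoff_sd, 3))[::-1]
        prices = rng.normal(config.price_mean, config.price_sd, 3)
        for _ in range(_MAX_REDRAWS):
            low = prices < 1.0
            if not low.any():
                break
            prices[low] = rng.normal(config.price_mean, config.price_sd, low.sum())
        else:
            raise RuntimeError("price distribution cannot produce prices >= 1")
        areas = np.rint(payoffs + prices)
        prices = np.rint(prices)
        rounded_payoffs = areas - prices
        if (areas <= 0).any() or len(set(rounded_payoffs)) != 3:
            continue  # payoff tie after rounding, or degenerate area: re-draw
        order = np.argsort(rounded_payoffs)[::-1]
        shapes = rng.integers(0, len(SHAPES), 3)
        positions = rng.permutation(3)
        return [
            OptionSpec(
                shape=SHAPES[shapes[i]],
                area=float(areas[i]),
                price=float(prices[i]),
                position=POSITIONS[positions[i]],
            )
            for i in order
        ]
    raise RuntimeError(
        "could not draw three options with distinct payoffs; "
        "check payoff_sd and price_sd"
    )


def make_decoy(target: OptionSpec, source: OptionSpec, q: float) -> OptionSpec:
    """Turn ``source`` into a decoy dominated by ``target``.

    With payoff difference ``d = target.payoff - source.payoff`` and a
    proportion ``q`` in [0, 1], the decoy's price is ``target.price + q*d``
    and its area is ``target.area - (1-q)*d``. The decoy keeps the target's
    shape and the source's screen position, and its payoff equals the
    source's payoff exactly (the construction conserves it). For
    ``q`` strictly inside (0, 1) the decoy is strictly dominated in both
    attributes; at the endpoints dominance is weak in one attribute.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    d = target.payoff - source.payoff
    if d <= 0:
        raise ValueError(
            "target payoff must exceed source payoff for a dominated decoy"
        )
    return OptionSpec(
        shape=target.shape,
        area=target.area - (1.0 - q) * d,
        price=target.price + q * d,
        position=source.position,
        is_decoy=True,
    )


def _attach_decoy(
    ranked: list[OptionSpec], target_idx: int, source_idx: int, q: float
) -> None:
    """Replace ranked[source_idx] with a decoy of ranked[target_idx] in place."""
    ranked[source_idx] = make_decoy(ranked[target_idx], ranked[source_idx], q)
    ranked[target_idx] = replace(ranked[target_idx], has_decoy=True)


def build_trial(
    config: SessionConfig,
    round_kind: RoundKind | str,
    rng: np.random.Generator,
    *,
    round_index: int = 1,
    indicator_shape: Optional[str] = None,
) -> Trial:
    """Generate one trial with condition-specific cue placement.

    Practice and treatment rounds place the cue on the superior option with
    probability ``p = config.assigned_predictivity``:

    - decoy: with probability p the superior option receives a decoy (the
      second- or third-best option becomes the decoy, 50/50); otherwise the
      second-best option receives a decoy and the worst option is the decoy.
    - default: with probability p the superior option is pre-selected;
      otherwise one of the two inferior options, chosen uniformly.
    - rule: with probability p the superior option is forced to the
      indicator shape; otherwise one of the two inferior options, chosen
      uniformly. The other two options are re-randomised to non-indicator
      shapes either way.

    Test rounds are unpredictive in expectation: decoy — the superior or
    second-best option has a decoy with equal probability and the worst
    option is the decoy; default and rule — the cue lands uniformly on one
    of the three options.
    """
    round_kind = RoundKind(round_kind)
    condition = config.condition
    if condition is Condition.RULE and indicator_shape is None:
        raise ValueError("indicator_shape is required in the rule condition")

    ranked = draw_option_set(config, rng)
    p = config.assigned_predictivity
    is_test = round_kind is RoundKind.TEST
    decoy_q: Optional[float] = None

    if condition is Condition.DECOY:
        decoy_q = float(rng.uniform(0.0, 1.0))
        if is_test:
            target_idx = int(rng.integers(0, 2))  # superior or second-best
            source_idx = 2
        elif rng.uniform() < p:
            target_idx = 0
            source_idx = int(rng.integers(1, 3))  # 2nd or 3rd best, 50/50
        else:
            target_idx, source_idx = 1, 2
        _attach_decoy(ranked, target_idx, source_idx, decoy_q)
        cue_idx = target_idx
    else:
        if is_test:
            cue_idx = int(rng.integers(0, 3))
        elif rng.uniform() < p:
            cue_idx = 0
        else:
            cue_idx = int(rng.integers(1, 3))  # inferior options, uniform
        if condition is Condition.DEFAULT:
            ranked[cue_idx] = replace(ranked[cue_idx], is_default=True)
        else:  # rule: force indicator shape, re-randomise the other two
            other_shapes = [s for s in SHAPES if s != indicator_shape]
            for i in range(3):
                if i == cue_idx:
                    ranked[i] = replace(
                        ranked[i], shape=indicator_shape, is_indicator=True
                    )
                else:
                    ranked[i] = replace(
                        ranked[i],
                        shape=other_shapes[int(rng.integers(0, len(other_shapes)))],
                    )

    superior_position = ranked[0].position
    cue_position = ranked[cue_idx].position
    options = tuple(sorted(ranked, key=lambda o: POSITIONS.index(o.position)))
    return Trial(
        round_index=round_index,
        round_kind=round_kind,
        options=options,  # type: ignore[arg-type]
        cue_position=cue_position,
        superior_position=superior_position,
        cue_predictive=int(cue_position == superior_position),
        decoy_proportion=decoy_q,
    )


def generate_session(
    config: SessionConfig, participant_id: str = "P0"
) -> Session:
    """Generate a full, reproducible session for one synthetic participant.

    Rounds 1..n_practice are practice rounds generated exactly like
    treatment rounds (at the assigned predictivity); the remaining rounds
    are a uniformly random interleaving of the treatment and test rounds.
    In the rule condition one indicator shape is sampled uniformly per
    session. The session is a deterministic function of ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    indicator_shape: Optional[str] = None
    if config.condition is Condition.RULE:
        indicator_shape = SHAPES[int(rng.integers(0, len(SHAPES)))]

    kinds = np.array(
        [0] * config.n_treatment + [1] * config.n_test, dtype=np.int64
    )
    rng.shuffle(kinds)
    sequence = [RoundKind.PRACTICE] * config.n_practice + [
        RoundKind.TEST if k else RoundKind.TREATMENT for k in kinds
    ]
    trials = tuple(
        build_trial(
            config,
            kind,
            rng,
            round_index=r,
            indicator_shape=indicator_shape,
        )
        for r, kind in enumerate(sequence, start=1)
    )
    return Session(
        participant_id=str(participant_id),
        config=config,
        trials=trials,
        indicator_shape=indicator_shape,
    )
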
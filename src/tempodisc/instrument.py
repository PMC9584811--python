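"""Adaptive intertemporal-choice instrument.

The instrument elicits time preferences through three baseline titration
(staircase) sets followed by four anomaly items, all binary choices between
an earlier and a later monetary prospect.

Baseline sets
-------------
Each baseline set starts from a country-specific *base* amount (roughly 10%
of the average monthly household income) offered immediately against 110% of
that amount in 12 months.  The staircase then branches on the first answer:

* choosing the **earlier** prospect on a gain raises the delayed offer
  (120%, then 150%),
* choosing the **later** prospect lowers it (102%, then 101%),

and a reversal at the second item ends the set, so a set takes two or three
items.  The three sets are a small-magnitude gain, the same values framed as
payments (losses, with the branching mirrored), and a large-magnitude gain
(base multiplied by ``large_multiplier``).

Anomaly items
-------------
The small-gain set yields a coarse *indifference value* — the smallest
delayed amount the respondent accepted.  Four further items are built from
it: a present-bias item (base in 12 months vs. indifference in 24), a
subadditivity item (base now vs. base plus twice the waiting premium in 24
months) and a delay/speedup framing pair (base now vs. indifference in 12
months, framed either as a bonus for waiting or as a fee for accelerating).
Every complete path therefore contains 10-13 items.

Choices are encoded as single characters: ``"I"`` for the earlier
("immediate") prospect and ``"D"`` for the later ("delayed") one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterator

import numpy as np

__all__ = [
    "IMMEDIATE",
    "DELAYED",
    "BASELINE_SETS",
    "ANOMALY_SETS",
    "TERMINAL_PATTERNS",
    "CountryAnchor",
    "ChoiceItem",
    "TitrationSchedule",
    "TitrationState",
    "InstrumentPath",
    "InstrumentError",
    "InvalidConfigError",
    "IncompletePathError",
    "StateError",
    "round_amount",
    "build_titration_schedule",
    "next_multiplier",
    "next_item",
    "derive_indifference",
    "build_anomaly_items",
    "walk_instrument",
    "enumerate_paths",
    "path_items",
]

IMMEDIATE = "I"
DELAYED = "D"

BASELINE_SETS = ("small_gain", "loss", "large_gain")
ANOMALY_SETS = ("present_bias", "subadditivity", "delay_framing", "speedup_framing")

FIRST_MULTIPLIER = 1.10
ASCENDING_MULTIPLIERS = (1.20, 1.50)
DESCENDING_MULTIPLIERS = (1.02, 1.01)

#: the six ways a baseline staircase can terminate
TERMINAL_PATTERNS = ("DDD", "DDI", "DI", "ID", "IID", "III")

#: smallest delayed multiplier accepted along each terminal gain pattern
_INDIFFERENCE_MULTIPLIER = {
    "DDD": 1.01,
    "DDI": 1.02,
    "DI": 1.10,
    "ID": 1.20,
    "IID": 1.50,
    "III": 1.50,  # never accepted: censored at the ceiling
}


class InstrumentError(ValueError):
    """Base class for instrument construction/state errors."""


class InvalidConfigError(InstrumentError):
    """Raised for non-positive anchors or malformed configuration."""


class IncompletePathError(InstrumentError):
    """Raised when an operation requires a completed titration set."""


class StateError(InstrumentError):
    """Raised when an item is requested after the staircase terminated."""


def round_amount(x: float) -> float:
    """Round a constructed amount to the nearest whole currency unit.

    Exact halves resolve to the nearest even unit (IEEE round-half-even),
    matching :func:`numpy.rint` so scalar and vectorised code agree.
    """
    return float(np.rint(x))


@dataclass(frozen=True)
class CountryAnchor:
    """Monetary and economic context for one country.

    ``anchor_value`` is the small-magnitude base amount in local currency
    (approximately 10% of the average monthly household income);
    ``large_multiplier`` scales it up for the large-magnitude gain set.
    ``gini`` is expressed as a fraction in [0, 1].
    """

    country_id: str
    currency_label: str = ""
    anchor_value: float = 0.0
    large_multiplier: float = 10.0
    gini: float | None = None
    log_gdp_pc: float | None = None
    inflation_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.country_id:
            raise InvalidConfigError("country_id must be non-empty")
        if not self.anchor_value > 0:
            raise InvalidConfigError(
                f"anchor_value must be positive, got {self.anchor_value!r}"
            )
        if not self.large_multiplier > 0:
            raise InvalidConfigError(
                f"large_multiplier must be positive, got {self.large_multiplier!r}"
            )
        if self.gini is not None and not 0.0 <= self.gini <= 1.0:
            raise InvalidConfigError(f"gini must lie in [0, 1], got {self.gini!r}")


@dataclass(frozen=True)
class ChoiceItem:
    """One binary prospect pair.

    ``immediate_*`` is the earlier prospect, ``delayed_*`` the later one;
    times are months from today.  For losses both amounts are payments.
    """

    set_id: str
    sign: str  # "gain" | "loss"
    immediate_amount: float
    immediate_time: int
    delayed_amount: float
    delayed_time: int
    framing: str = "neutral"  # "neutral" | "delay" | "speedup"

    def __post_init__(self) -> None:
        if self.delayed_time <= self.immediate_time:
            raise InstrumentError("delayed_time must exceed immediate_time")
        if self.delayed_amount < self.immediate_amount:
            raise InstrumentError(
                "the later prospect must be at least as large as the earlier one"
            )


@dataclass(frozen=True)
class TitrationSchedule:
    """Value schedule for one baseline set.

    ``ascending``/``descending`` hold the delayed amounts reached after
    repeated impatient/patient answers; ``ascending[0]`` is the first item's
    delayed amount (110% of base).
    """

    set_id: str
    sign: str
    base: float
    immediate_amount: float
    ascending: tuple[float, float, float]  # 1.10, 1.20, 1.50 x base
    descending: tuple[float, float]  # 1.02, 1.01 x base

    def delayed_amount(self, multiplier: float) -> float:
        table = {
            FIRST_MULTIPLIER: self.ascending[0],
            ASCENDING_MULTIPLIERS[0]: self.ascending[1],
            ASCENDING_MULTIPLIERS[1]: self.ascending[2],
            DESCENDING_MULTIPLIERS[0]: self.descending[0],
            DESCENDING_MULTIPLIERS[1]: self.descending[1],
        }
        return table[multiplier]


def build_titration_schedule(
    anchor: CountryAnchor,
    set_id: str,
    rounder: Callable[[float], float] = round_amount,
) -> TitrationSchedule:
    """Construct the value schedule of one baseline set for a country.

    The immediate amount is the anchor value (times ``large_multiplier``
    for the large-magnitude set); the five possible delayed amounts are
    {110%, 120%, 150%, 102%, 101%} of it, rounded by ``rounder``.  The loss
    set mirrors the small-gain values as payments.
    """
    if set_id not in BASELINE_SETS:
        raise InvalidConfigError(f"{set_id!r} is not a baseline set")
    base = anchor.anchor_value
    if set_id == "large_gain":
        base = base * anchor.large_multiplier
    base = rounder(base)
    sign = "loss" if set_id == "loss" else "gain"
    asc = tuple(
        rounder(m * base) for m in (FIRST_MULTIPLIER, *ASCENDING_MULTIPLIERS)
    )
    desc = tuple(rounder(m * base) for m in DESCENDING_MULTIPLIERS)
    return TitrationSchedule(set_id, sign, base, base, asc, desc)


def _is_ascending(set_id: str, first_choice: str) -> bool:
    # Gains escalate after impatient answers; the loss staircase mirrors
    # this, escalating when the respondent prefers to pay later.
    if set_id == "loss":
        return first_choice == DELAYED
    return first_choice == IMMEDIATE


def next_multiplier(set_id: str, responses: str) -> float | None:
    """Return the delayed-value multiplier of the next item, or None.

    ``responses`` is the choice string recorded so far in this set (e.g.
    ``"ID"``).  None signals that the staircase has terminated: either the
    second answer reversed the first, or three items were answered.
    """
    for c in responses:
        if c not in (IMMEDIATE, DELAYED):
            raise InstrumentError(f"invalid choice code {c!r}")
    n = len(responses)
    if n == 0:
        return FIRST_MULTIPLIER
    if n >= 2 and responses[1] != responses[0]:
        return None
    if n >= 3:
        return None
    branch = (
        ASCENDING_MULTIPLIERS
        if _is_ascending(set_id, responses[0])
        else DESCENDING_MULTIPLIERS
    )
    return branch[n - 1]


@dataclass
class TitrationState:
    """Mutable walk through one baseline staircase."""

    schedule: TitrationSchedule
    responses: str = ""

    @property
    def set_id(self) -> str:
        return self.schedule.set_id

    @property
    def branch(self) -> str:
        if not self.responses:
            return "undecided"
        return (
            "ascending"
            if _is_ascending(self.set_id, self.responses[0])
            else "descending"
        )

    @property
    def terminal(self) -> bool:
        return next_multiplier(self.set_id, self.responses) is None

    def current_item(self) -> ChoiceItem:
        m = next_multiplier(self.set_id, self.responses)
        if m is None:
            raise StateError(f"{self.set_id} staircase already terminated")
        return ChoiceItem(
            set_id=self.set_id,
            sign=self.schedule.sign,
            immediate_amount=self.schedule.immediate_amount,
            immediate_time=0,
            delayed_amount=self.schedule.delayed_amount(m),
            delayed_time=12,
        )

    def record(self, choice: str) -> None:
        if self.terminal:
            raise StateError(f"{self.set_id} staircase already terminated")
        if choice not in (IMMEDIATE, DELAYED):
            raise InstrumentError(f"invalid choice code {choice!r}")
        self.responses += choice


def next_item(state: TitrationState, prior_choice: str | None = None) -> ChoiceItem | None:
    """Record ``prior_choice`` (if given) and return the next item.

    Returns None exactly once, when the recorded choice terminates the
    staircase; requesting a further item afterwards raises
    :class:`StateError`.
    """
    if prior_choice is None and state.responses:
        raise StateError("prior_choice required after the first item")
    if state.terminal:
        raise StateError(f"{state.set_id} staircase already terminated")
    if prior_choice is not None:
        state.record(prior_choice)
    if state.terminal:
        return None
    return state.current_item()


def derive_indifference(
    small_gain_responses: str,
    schedule: TitrationSchedule,
    rounder: Callable[[float], float] = round_amount,
) -> tuple[float, bool]:
    """Smallest delayed amount accepted in the small-gain set.

    A respondent who rejected the delayed option even at 150% is assigned
    the 150% value with ``censored=True``; downstream anomaly items are
    still constructed from it.
    """
    if small_gain_responses not in TERMINAL_PATTERNS:
        raise IncompletePathError(
            f"{small_gain_responses!r} is not a completed small-gain set"
        )
    m = _INDIFFERENCE_MULTIPLIER[small_gain_responses]
    value = rounder(m * schedule.base)
    return value, small_gain_responses == "III"


def build_anomaly_items(
    indifference_value: float,
    anchor: CountryAnchor,
    rounder: Callable[[float], float] = round_amount,
) -> dict[str, ChoiceItem]:
    """Construct the four anomaly items from base and indifference value.

    With base *b*, indifference *v* and waiting premium *p = v - b*:

    * ``present_bias``: *b* in 12 months vs. *v* in 24 months,
    * ``subadditivity``: *b* now vs. *b + 2p* in 24 months (the premium is
      extended additively over the second year),
    * ``delay_framing`` / ``speedup_framing``: *b* now vs. *v* in 12
      months, worded either as "+p for waiting" or "-p to receive now".
    """
    base = rounder(anchor.anchor_value)
    v = rounder(indifference_value)
    if v < base:
        raise InstrumentError(
            f"indifference value {v} below base amount {base}"
        )
    premium = v - base
    return {
        "present_bias": ChoiceItem(
            "present_bias", "gain", base, 12, v, 24
        ),
        "subadditivity": ChoiceItem(
            "subadditivity", "gain", base, 0, rounder(base + 2 * premium), 24
        ),
        "delay_framing": ChoiceItem(
            "delay_framing", "gain", base, 0, v, 12, framing="delay"
        ),
        "speedup_framing": ChoiceItem(
            "speedup_framing", "gain", base, 0, v, 12, framing="speedup"
        ),
    }


@dataclass(frozen=True)
class InstrumentPath:
    """A complete walk through the instrument for one respondent."""

    participant_id: str
    country_id: str
    choices_small_gain: str
    choices_loss: str
    choices_large_gain: str
    choice_present_bias: str
    choice_subadditivity: str
    choice_delay_framing: str
    choice_speedup_framing: str
    indifference_value: float
    indifference_censored: bool

    def __post_init__(self) -> None:
        for pat in (
            self.choices_small_gain,
            self.choices_loss,
            self.choices_large_gain,
        ):
            if pat not in TERMINAL_PATTERNS:
                raise IncompletePathError(f"baseline pattern {pat!r} incomplete")
        for c in self.anomaly_choices.values():
            if c not in (IMMEDIATE, DELAYED):
                raise InstrumentError(f"invalid anomaly choice {c!r}")

    @property
    def anomaly_choices(self) -> dict[str, str]:
        return {
            "present_bias": self.choice_present_bias,
            "subadditivity": self.choice_subadditivity,
            "delay_framing": self.choice_delay_framing,
            "speedup_framing": self.choice_speedup_framing,
        }

    @property
    def n_items(self) -> int:
        return (
            len(self.choices_small_gain)
            + len(self.choices_loss)
            + len(self.choices_large_gain)
            + len(ANOMALY_SETS)
        )


def walk_instrument(
    anchor: CountryAnchor,
    chooser: Callable[[ChoiceItem], str],
    participant_id: str = "",
    rounder: Callable[[float], float] = round_amount,
) -> InstrumentPath:
    """Walk one respondent through the full instrument.

    ``chooser`` maps each presented :class:`ChoiceItem` to ``"I"`` or
    ``"D"``.  Baseline sets run in the fixed order small gain, loss, large
    gain; anomaly items follow only once every baseline set is complete.
    """
    patterns: dict[str, str] = {}
    for set_id in BASELINE_SETS:
        schedule = build_titration_schedule(anchor, set_id, rounder)
        state = TitrationState(schedule)
        while not state.terminal:
            state.record(chooser(state.current_item()))
        patterns[set_id] = state.responses

    small_schedule = build_titration_schedule(anchor, "small_gain", rounder)
    indifference, censored = derive_indifference(
        patterns["small_gain"], small_schedule, rounder
    )
    items = build_anomaly_items(indifference, anchor, rounder)
    anomaly = {name: chooser(items[name]) for name in ANOMALY_SETS}
    return InstrumentPath(
        participant_id=participant_id,
        country_id=anchor.country_id,
        choices_small_gain=patterns["small_gain"],
        choices_loss=patterns["loss"],
        choices_large_gain=patterns["large_gain"],
        choice_present_bias=anomaly["present_bias"],
        choice_subadditivity=anomaly["subadditivity"],
        choice_delay_framing=anomaly["delay_framing"],
        choice_speedup_framing=anomaly["speedup_framing"],
        indifference_value=indifference,
        indifference_censored=censored,
    )


def enumerate_paths(anchor: CountryAnchor) -> Iterator[InstrumentPath]:
    """Yield every valid complete response pattern.

    Each baseline staircase has exactly six terminal patterns and each
    anomaly item two answers, so the instrument admits 6^3 x 2^4 = 3456
    complete paths, with item counts between 10 and 13.
    """
    small_schedule = build_titration_schedule(anchor, "small_gain")
    for sg, loss, lg in product(TERMINAL_PATTERNS, repeat=3):
        indifference, censored = derive_indifference(sg, small_schedule)
        for pb, sub, dly, spd in product((IMMEDIATE, DELAYED), repeat=4):
            yield InstrumentPath(
                participant_id="",
                country_id=anchor.country_id,
                choices_small_gain=sg,
                choices_loss=loss,
                choices_large_gain=lg,
                choice_present_bias=pb,
                choice_subadditivity=sub,
                choice_delay_framing=dly,
                choice_speedup_framing=spd,
                indifference_value=indifference,
                indifference_censored=censored,
            )


def path_items(
    path: InstrumentPath,
    anchor: CountryAnchor,
    rounder: Callable[[float], float] = round_amount,
) -> list[tuple[ChoiceItem, str]]:
    """Reconstruct the ordered (item, choice) log of a completed path."""
    log: list[tuple[ChoiceItem, str]] = []
    for set_id, pattern in (
        ("small_gain", path.choices_small_gain),
        ("loss", path.choices_loss),
        ("large_gain", path.choices_large_gain),
    ):
        schedule = build_titration_schedule(anchor, set_id, rounder)
        state = TitrationState(schedule)
        for choice in pattern:
            log.append((state.current_item(), choice))
            state.record(choice)
    items = build_anomaly_items(path.indifference_value, anchor, rounder)
    for name in ANOMALY_SETS:
        log.append((items[name], path.anomaly_choices[name]))
    return log
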
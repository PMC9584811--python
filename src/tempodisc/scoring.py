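"""Titration categories, the 0-19 discounting score, and anomaly flags.

Each baseline staircase terminates in one of six patterns, ordered here by
revealed impatience into a 0-5 *titration category*: on gains, 0 means the
respondent accepted a delayed premium of only 1% while 5 means even a 50%
premium was rejected.  The loss staircase is mirrored so that preferring
delayed (larger) payments scores high.  The aggregate discounting score adds
the three categories (0-15) and one point per anomaly item on which the
discount-consistent option — the earlier gain — was chosen, spanning 0
("always prefer delayed gains or earlier losses") to 19 ("always prefer
immediate gains or delayed losses").

Anomaly flags follow the first-item choice rules of the classic worked
examples (``variant="example"``); a stricter category-difference variant is
available for the two flags that compare whole staircases
(``variant="category"``).  Each anomaly flag has a mirror *inconsistency*
flag for the reversal pattern of the opposite direction; by construction a
flag and its mirror are never both true.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .instrument import (
    ANOMALY_SETS,
    DELAYED,
    IMMEDIATE,
    InstrumentPath,
    TERMINAL_PATTERNS,
)

__all__ = [
    "ANOMALY_FLAGS",
    "INCONSISTENCY_FLAGS",
    "ScoredResponse",
    "titration_category",
    "discounting_score",
    "classify_anomalies",
    "flag_inconsistencies",
    "score_path",
    "score_table",
    "standardize",
]

#: terminal pattern -> 0-5 category for gain staircases
GAIN_CATEGORY = {"DDD": 0, "DDI": 1, "DI": 2, "ID": 3, "IID": 4, "III": 5}
#: loss staircases mirrored: always delaying payments scores 5
LOSS_CATEGORY = {p: 5 - c for p, c in GAIN_CATEGORY.items()}

ANOMALY_FLAGS = (
    "absolute_magnitude",
    "gain_loss",
    "delay_speedup",
    "present_bias",
    "subadditivity",
)
INCONSISTENCY_FLAGS = (
    "reverse_magnitude",
    "reverse_gain_loss",
    "reverse_framing",
    "future_bias",
    "superadditivity",
)

_VARIANTS = ("example", "category")


@dataclass(frozen=True)
class ScoredResponse:
    """Scored record for one respondent."""

    participant_id: str
    country_id: str
    category_small_gain: int
    category_loss: int
    category_large_gain: int
    indifference_value: float
    indifference_censored: bool
    discounting_score: int
    absolute_magnitude: bool
    gain_loss: bool
    delay_speedup: bool
    present_bias: bool
    subadditivity: bool
    reverse_magnitude: bool
    reverse_gain_loss: bool
    reverse_framing: bool
    future_bias: bool
    superadditivity: bool
    z_score: float = float("nan")


def titration_category(responses: str, set_id: str) -> int:
    """Map one completed staircase pattern to its 0-5 category."""
    if responses not in TERMINAL_PATTERNS:
        raise ValueError(f"{responses!r} is not a completed staircase pattern")
    if set_id == "loss":
        return LOSS_CATEGORY[responses]
    return GAIN_CATEGORY[responses]


def _anomaly_points(path: InstrumentPath) -> int:
    # the four anomaly items are gains: the earlier option is the
    # discount-consistent choice
    return sum(1 for c in path.anomaly_choices.values() if c == IMMEDIATE)


def discounting_score(path: InstrumentPath) -> int:
    """Aggregate 0-19 discounting score for a complete path."""
    score = (
        titration_category(path.choices_small_gain, "small_gain")
        + titration_category(path.choices_loss, "loss")
        + titration_category(path.choices_large_gain, "large_gain")
        + _anomaly_points(path)
    )
    assert 0 <= score <= 19
    return score


def _check_variant(variant: str) -> None:
    if variant not in _VARIANTS:
        raise ValueError(f"unknown rule variant {variant!r}; choose from {_VARIANTS}")


def classify_anomalies(path: InstrumentPath, variant: str = "example") -> dict[str, bool]:
    """Evaluate the five anomaly rules on a complete path.

    ``variant="example"`` follows the first-item worked examples:
    magnitude = impatient at the first small-gain item yet patient at the
    first large-gain item; gain-loss = earlier option at both first items.
    ``variant="category"`` replaces those two with strict category
    comparisons (small-gain category above large-gain / loss category).
    The framing, present-bias and subadditivity rules are single-item and
    identical across variants.
    """
    _check_variant(variant)
    sg1 = path.choices_small_gain[0]
    lg1 = path.choices_large_gain[0]
    loss1 = path.choices_loss[0]
    if variant == "category":
        c_sg = titration_category(path.choices_small_gain, "small_gain")
        c_lg = titration_category(path.choices_large_gain, "large_gain")
        c_loss = titration_category(path.choices_loss, "loss")
        magnitude = c_sg > c_lg
        gain_loss = c_sg > c_loss
    else:
        magnitude = sg1 == IMMEDIATE and lg1 == DELAYED
        gain_loss = sg1 == IMMEDIATE and loss1 == IMMEDIATE
    return {
        "absolute_magnitude": magnitude,
        "gain_loss": gain_loss,
        "delay_speedup": (
            path.choice_delay_framing == IMMEDIATE
            and path.choice_speedup_framing == DELAYED
        ),
        "present_bias": path.choice_present_bias == DELAYED,
        "subadditivity": (
            path.choice_subadditivity == DELAYED
            and path.choice_present_bias == IMMEDIATE
        ),
    }


def flag_inconsistencies(path: InstrumentPath, variant: str = "example") -> dict[str, bool]:
    """Mirror-image reversal flags for choices opposite to each anomaly."""
    _check_variant(variant)
    sg1 = path.choices_small_gain[0]
    lg1 = path.choices_large_gain[0]
    loss1 = path.choices_loss[0]
    if variant == "category":
        c_sg = titration_category(path.choices_small_gain, "small_gain")
        c_lg = titration_category(path.choices_large_gain, "large_gain")
        c_loss = titration_category(path.choices_loss, "loss")
        rev_magnitude = c_sg < c_lg
        rev_gain_loss = c_sg < c_loss
    else:
        rev_magnitude = sg1 == DELAYED and lg1 == IMMEDIATE
        rev_gain_loss = sg1 == DELAYED and loss1 == DELAYED
    return {
        "reverse_magnitude": rev_magnitude,
        "reverse_gain_loss": rev_gain_loss,
        "reverse_framing": (
            path.choice_delay_framing == DELAYED
            and path.choice_speedup_framing == IMMEDIATE
        ),
        "future_bias": path.choice_present_bias == IMMEDIATE,
        "superadditivity": (
            path.choice_subadditivity == IMMEDIATE
            and path.choice_present_bias == DELAYED
        ),
    }


def score_path(path: InstrumentPath, variant: str = "example") -> ScoredResponse:
    """Score one complete instrument path."""
    flags = classify_anomalies(path, variant)
    mirrors = flag_inconsistencies(path, variant)
    return ScoredResponse(
        participant_id=path.participant_id,
        country_id=path.country_id,
        category_small_gain=titration_category(path.choices_small_gain, "small_gain"),
        category_loss=titration_category(path.choices_loss, "loss"),
        category_large_gain=titration_category(path.choices_large_gain, "large_gain"),
        indifference_value=path.indifference_value,
        indifference_censored=path.indifference_censored,
        discounting_score=discounting_score(path),
        **flags,
        **mirrors,
    )


_ANOMALY_CHOICE_COLUMNS = {
    "present_bias": "choice_present_bias",
    "subadditivity": "choice_subadditivity",
    "delay_framing": "choice_delay_framing",
    "speedup_framing": "choice_speedup_framing",
}


def score_table(responses: pd.DataFrame, variant: str = "example") -> pd.DataFrame:
    """Score a response table (one row per respondent), vectorised.

    Produces the same result as :func:`score_path` row by row; z-scores are
    not filled in here (standardisation happens on the QC-retained pooled
    sample, see :func:`standardize`).
    """
    _check_variant(variant)
    for col in ("choices_small_gain", "choices_loss", "choices_large_gain"):
        bad = ~responses[col].isin(TERMINAL_PATTERNS)
        if bad.any():
            raise ValueError(
                f"column {col} contains incomplete patterns at rows "
                f"{responses.index[bad].tolist()[:5]}"
            )
    out = pd.DataFrame(index=responses.index)
    out["participant_id"] = responses["participant_id"]
    out["country_id"] = responses["country_id"]
    c_sg = responses["choices_small_gain"].map(GAIN_CATEGORY)
    c_loss = responses["choices_loss"].map(LOSS_CATEGORY)
    c_lg = responses["choices_large_gain"].map(GAIN_CATEGORY)
    out["category_small_gain"] = c_sg
    out["category_loss"] = c_loss
    out["category_large_gain"] = c_lg
    out["indifference_value"] = responses["indifference_value"]
    out["indifference_censored"] = responses["indifference_censored"].astype(bool)

    anomaly_immediate = {
        name: responses[col] == IMMEDIATE
        for name, col in _ANOMALY_CHOICE_COLUMNS.items()
    }
    points = sum(s.astype(int) for s in anomaly_immediate.values())
    out["discounting_score"] = c_sg + c_loss + c_lg + points

    sg1 = responses["choices_small_gain"].str[0]
    lg1 = responses["choices_large_gain"].str[0]
    loss1 = responses["choices_loss"].str[0]
    if variant == "category":
        magnitude = c_sg > c_lg
        gain_loss = c_sg > c_loss
        rev_magnitude = c_sg < c_lg
        rev_gain_loss = c_sg < c_loss
    else:
        magnitude = (sg1 == IMMEDIATE) & (lg1 == DELAYED)
        gain_loss = (sg1 == IMMEDIATE) & (loss1 == IMMEDIATE)
        rev_magnitude = (sg1 == DELAYED) & (lg1 == IMMEDIATE)
        rev_gain_loss = (sg1 == DELAYED) & (loss1 == DELAYED)
    pb_delayed = ~anomaly_immediate["present_bias"]
    sub_delayed = ~anomaly_immediate["subadditivity"]
    out["absolute_magnitude"] = magnitude
    out["gain_loss"] = gain_loss
    out["delay_speedup"] = (
        anomaly_immediate["delay_framing"] & ~anomaly_immediate["speedup_framing"]
    )
    out["present_bias"] = pb_delayed
    out["subadditivity"] = sub_delayed & ~pb_delayed
    out["reverse_magnitude"] = rev_magnitude
    out["reverse_gain_loss"] = rev_gain_loss
    out["reverse_framing"] = (
        ~anomaly_immediate["delay_framing"] & anomaly_immediate["speedup_framing"]
    )
    out["future_bias"] = ~pb_delayed
    out["superadditivity"] = ~sub_delayed & pb_delayed
    out["z_score"] = np.nan
    return out


def standardize(scores) -> np.ndarray:
    """Pooled z-transform (sample standard deviation, n-1 denominator)."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize requires at least two scores")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("scores have zero variance; z-scores undefined")
    return (x - x.mean()) / sd


#: column order of the scored CSV
SCORED_COLUMNS = [f.name for f in fields(ScoredResponse)]
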
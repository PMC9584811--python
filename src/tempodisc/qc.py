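"""Pre-registered exclusion pipeline and removal accounting.

Screens run in two stages.  Stage one applies to every record:

1. ``attention`` — failed the attention check (chose to *pay* an amount in
   one year rather than receive the same amount now);
2. ``nonsense`` — flagged for nonsensical free-text answers (the flag is an
   input column; no text processing happens here);
3. ``age`` — claims to be over 100 years old;
4. ``speed`` — responded faster than three median absolute deviations
   below the median response time, or in under 120 seconds;
5. ``completion`` — completed 90% of the survey or less.

Stage two applies only to analyses of income, assets and debt and is
reported separately:

6. ``extreme_value`` — any money field above 1e8;
7. ``income_outlier`` — income more than 100 MADs above the country median;
8. ``assets_outlier`` — assets more than 1000 MADs above the country median;
9. ``zero_income_employed`` — zero income while employed full-time.

A record can fail several rules; every failed rule is attributed, so
per-rule counts can sum to more than the number of removed records.  The
median/MAD reference statistics are computed on records that survive rules
1-3 (so nonsense records cannot contaminate them) and are returned in the
report; passing them back in keeps a second application idempotent.  MAD is
the raw median absolute deviation (no 1.4826 consistency constant) by
default.  Records missing an optional money field pass the money rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STAGE1_RULES",
    "STAGE2_RULES",
    "ReferenceStats",
    "QCReport",
    "apply_exclusions",
]

STAGE1_RULES = ("attention", "nonsense", "age", "speed", "completion")
STAGE2_RULES = (
    "extreme_value",
    "income_outlier",
    "assets_outlier",
    "zero_income_employed",
)
ALL_RULES = STAGE1_RULES + STAGE2_RULES

MAX_AGE = 100
MIN_SECONDS = 120.0
MIN_COMPLETION = 0.9  # strictly more than 90% required
EXTREME_VALUE = 1e8
INCOME_MAD_FACTOR = 100.0
ASSETS_MAD_FACTOR = 1000.0


def _mad(x: pd.Series, constant: float = 1.0) -> float:
    med = x.median()
    return constant * (x - med).abs().median()


@dataclass(frozen=True)
class ReferenceStats:
    """Median/MAD references used by the relative screens."""

    time_median: float
    time_mad: float
    income_median: dict[str, float]
    income_mad: dict[str, float]
    assets_median: dict[str, float]
    assets_mad: dict[str, float]


@dataclass
class QCReport:
    """Per-rule removal accounting for one exclusion run."""

    n_input: int
    n_retained: int
    counts: dict[str, int]
    overlap: pd.DataFrame
    retained_ids: list[str]
    stats: ReferenceStats
    warnings: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "counts": dict(self.counts),
            "overlap": {
                r: {c: int(self.overlap.loc[r, c]) for c in self.overlap.columns}
                for r in self.overlap.index
            },
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _compute_stats(
    records: pd.DataFrame, prefilter: pd.Series, mad_constant: float
) -> ReferenceStats:
    pool = records[~prefilter]
    time_med = float(pool["total_time_seconds"].median())
    time_mad = float(_mad(pool["total_time_seconds"], mad_constant))
    inc_med, inc_mad, ast_med, ast_mad = {}, {}, {}, {}
    for country, grp in pool.groupby("country_id"):
        inc = grp["income"].dropna()
        ast = grp["assets"].dropna()
        if len(inc):
            inc_med[country] = float(inc.median())
            inc_mad[country] = float(_mad(inc, mad_constant))
        if len(ast):
            ast_med[country] = float(ast.median())
            ast_mad[country] = float(_mad(ast, mad_constant))
    return ReferenceStats(time_med, time_mad, inc_med, inc_mad, ast_med, ast_mad)


def _money(records: pd.DataFrame, column: str, warnings: list[str]) -> pd.Series:
    if column not in records.columns:
        warnings.append(f"column {column!r} missing; money rules using it pass")
        return pd.Series(np.nan, index=records.index)
    return pd.to_numeric(records[column], errors="coerce")


def apply_exclusions(
    records: pd.DataFrame,
    stats: ReferenceStats | None = None,
    mad_constant: float = 1.0,
    run_stage2: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the exclusion pipeline and return (retained records, report).

    ``stats`` overrides the median/MAD references (e.g. to re-apply the
    filter with the thresholds of a previous run); by default they are
    computed from the records surviving rules 1-3.  With
    ``run_stage2=False`` only the universal stage-one screens run.
    """
    warnings: list[str] = []
    n = len(records)
    if n == 0:
        empty = pd.DataFrame(
            0, index=list(ALL_RULES), columns=list(ALL_RULES)
        )
        report = QCReport(
            0, 0, {r: 0 for r in ALL_RULES}, empty, [],
            ReferenceStats(np.nan, np.nan, {}, {}, {}, {}),
        )
        return records.copy(), report

    fails: dict[str, pd.Series] = {}
    fails["attention"] = records["attention_choice"].astype(str).eq("pay")
    fails["nonsense"] = records["nonsense_flag"].astype(bool)
    fails["age"] = pd.to_numeric(records["age"], errors="coerce") > MAX_AGE

    prefilter = fails["attention"] | fails["nonsense"] | fails["age"]
    if stats is None:
        stats = _compute_stats(records, prefilter, mad_constant)

    time = pd.to_numeric(records["total_time_seconds"], errors="coerce")
    cutoff = stats.time_median - 3.0 * stats.time_mad
    fails["speed"] = (time < cutoff) | (time < MIN_SECONDS)
    fails["completion"] = (
        pd.to_numeric(records["completion_fraction"], errors="coerce")
        <= MIN_COMPLETION
    )

    income = _money(records, "income", warnings)
    assets = _money(records, "assets", warnings)
    debt = _money(records, "debt", warnings)
    if run_stage2:
        fails["extreme_value"] = (
            (income > EXTREME_VALUE)
            | (assets > EXTREME_VALUE)
            | (debt > EXTREME_VALUE)
        ).fillna(False)
        country = records["country_id"]
        inc_thresh = country.map(
            lambda c: stats.income_median.get(c, np.nan)
            + INCOME_MAD_FACTOR * stats.income_mad.get(c, np.nan)
        )
        ast_thresh = country.map(
            lambda c: stats.assets_median.get(c, np.nan)
            + ASSETS_MAD_FACTOR * stats.assets_mad.get(c, np.nan)
        )
        fails["income_outlier"] = (income > inc_thresh).fillna(False)
        fails["assets_outlier"] = (assets > ast_thresh).fillna(False)
        fails["zero_income_employed"] = (
            income.eq(0.0) & records["employment"].astype(str).eq("full_time")
        ).fillna(False)
    else:
        for rule in STAGE2_RULES:
            fails[rule] = pd.Series(False, index=records.index)

    # missing values never trigger a rule
    fails = {rule: mask.fillna(False) for rule, mask in fails.items()}
    any_fail = np.logical_or.reduce([fails[r].to_numpy() for r in ALL_RULES])
    retained = records.loc[~any_fail].copy()

    fail_matrix = pd.DataFrame({r: fails[r] for r in ALL_RULES}).astype(int)
    overlap = fail_matrix.T @ fail_matrix  # diagonal = per-rule counts
    counts = {r: int(fail_matrix[r].sum()) for r in ALL_RULES}
    report = QCReport(
        n_input=n,
        n_retained=len(retained),
        counts=counts,
        overlap=overlap,
        retained_ids=retained["participant_id"].astype(str).tolist(),
        stats=stats,
        warnings=warnings,
    )
    return retained, report
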
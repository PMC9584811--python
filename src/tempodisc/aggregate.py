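"""Country summaries, random-effects meta-analysis and variance partition.

Country means (and anomaly proportions, pooled on the logit scale) are
combined with the classical DerSimonian-Laird random-effects model:

* between-country variance ``tau^2`` by method of moments,
  ``tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))`` with
  fixed-effect weights ``w_i = 1 / v_i``;
* pooled estimate by inverse-variance weighting with
  ``w*_i = 1 / (v_i + tau^2)``;
* heterogeneity ``I^2 = max(0, (Q - df) / Q)``;
* a 95% prediction interval for the effect in a new country using a
  t quantile with ``k - 2`` degrees of freedom
  (undefined and reported as NaN for k = 2).

Moderator analysis uses weighted least squares with a method-of-moments
residual ``tau^2``; the within- vs. between-country variance split uses
the one-way random-effects ANOVA estimator with the unbalanced-sample
correction ``n0 = (N - sum n_i^2 / N) / (k - 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

from .scoring import ANOMALY_FLAGS

__all__ = [
    "CountrySummary",
    "MetaResult",
    "MetaRegressionResult",
    "VariancePartition",
    "summarize_countries",
    "random_effects_meta",
    "meta_regression",
    "variance_partition",
    "proportion_meta",
    "forest_plot",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate for k country-level effects."""

    estimate: float
    se: float
    tau2: float
    q: float
    df: int
    q_pvalue: float
    i2: float
    ci_low: float
    ci_high: float
    pi_low: float
    pi_high: float
    k: int

    def to_dict(self) -> dict:
        return {k: (v if isinstance(v, int) else float(v)) for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class MetaRegressionResult:
    """Weighted moderator regression with method-of-moments residual tau^2."""

    intercept: float
    slopes: dict[str, float]
    slope_se: dict[str, float]
    slope_ci: dict[str, tuple[float, float]]
    tau2: float
    k: int

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "slopes": {k: float(v) for k, v in self.slopes.items()},
            "slope_se": {k: float(v) for k, v in self.slope_se.items()},
            "slope_ci": {k: [float(a), float(b)] for k, (a, b) in self.slope_ci.items()},
            "tau2": float(self.tau2),
            "k": self.k,
        }


@dataclass(frozen=True)
class VariancePartition:
    """Between- and within-country variance components of a score."""

    between: float
    within: float

    @property
    def intraclass_share(self) -> float:
        total = self.between + self.within
        return self.between / total if total > 0 else 0.0


#: alias kept for symmetry with the rest of the data model
CountrySummary = pd.Series


def summarize_countries(
    scored: pd.DataFrame,
    anchors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-country n, mean/sd of the discounting score, anomaly proportions.

    ``anchors`` may provide country covariates (``country_id`` plus gini,
    log_gdp_pc, inflation_rate) to merge onto the summaries.  Countries
    with no scored respondents simply do not appear; a single-respondent
    country yields sd = NaN and a warning.
    """
    if scored.empty:
        raise ValueError("no scored responses to summarise")
    rows = []
    for country, grp in scored.groupby("country_id", sort=True):
        row = {
            "country_id": country,
            "n": len(grp),
            "mean_score": grp["discounting_score"].mean(),
            "sd_score": grp["discounting_score"].std(ddof=1),
        }
        if len(grp) < 2:
            warnings.warn(
                f"country {country} has a single respondent; sd undefined",
                stacklevel=2,
            )
        for flag in ANOMALY_FLAGS:
            row[f"count_{flag}"] = int(grp[flag].sum())
            row[f"prop_{flag}"] = grp[flag].mean()
        rows.append(row)
    out = pd.DataFrame(rows)
    if anchors is not None:
        keep = [
            c
            for c in ("country_id", "gini", "log_gdp_pc", "inflation_rate")
            if c in anchors.columns
        ]
        out = out.merge(anchors[keep], on="country_id", how="left")
    return out


def _dersimonian_laird(y: np.ndarray, v: np.ndarray) -> tuple[float, float, int]:
    w = 1.0 / v
    y_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fixed) ** 2))
    df = len(y) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, tau2, df


def random_effects_meta(estimates, variances, alpha: float = 0.05) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of country effects."""
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and equal length")
    k = len(y)
    if k < 2:
        raise ValueError("meta-analysis requires at least two countries")
    if np.any(v <= 0):
        raise ValueError("variances must be strictly positive")

    q, tau2, df = _dersimonian_laird(y, v)
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    q_p = float(sps.chi2.sf(q, df))
    z = sps.norm.ppf(1 - alpha / 2)
    ci = (pooled - z * se, pooled + z * se)
    if k >= 3:
        t = sps.t.ppf(1 - alpha / 2, k - 2)
        half = t * np.sqrt(tau2 + se**2)
        pi = (pooled - half, pooled + half)
    else:
        pi = (np.nan, np.nan)
    return MetaResult(
        estimate=pooled,
        se=se,
        tau2=tau2,
        q=q,
        df=df,
        q_pvalue=q_p,
        i2=i2,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        pi_low=float(pi[0]),
        pi_high=float(pi[1]),
        k=k,
    )


def meta_regression(
    estimates, variances, moderators: pd.DataFrame, alpha: float = 0.05
) -> MetaRegressionResult:
    """Moderator meta-regression (weighted least squares, MoM tau^2).

    ``moderators`` holds one column per moderator.  The residual
    between-country variance is estimated from the fixed-effect residual
    heterogeneity statistic, then the fit is re-weighted by
    ``1 / (v_i + tau^2)``.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(moderators, dtype=float)])
    names = list(moderators.columns)
    k, p = X.shape
    if k < p + 1:
        raise ValueError("need more countries than coefficients")
    for j, name in enumerate(names):
        if np.ptp(X[:, j + 1]) == 0:
            raise ValueError(f"moderator {name!r} is constant")

    # method-of-moments residual tau^2 from the fixed-effect fit
    w = 1.0 / v
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta_fe = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta_fe
    q_e = float(np.sum(w * resid**2))
    # trace correction for the weighted projection
    trace = np.trace(np.linalg.solve(xtwx, X.T @ np.diag(w**2) @ X))
    denom = np.sum(w) - trace
    tau2 = max(0.0, (q_e - (k - p)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    xtwx_star = X.T @ np.diag(w_star) @ X
    beta = np.linalg.solve(xtwx_star, X.T @ (w_star * y))
    cov = np.linalg.inv(xtwx_star)
    se = np.sqrt(np.diag(cov))
    z = sps.norm.ppf(1 - alpha / 2)
    slopes = {name: float(beta[j + 1]) for j, name in enumerate(names)}
    slope_se = {name: float(se[j + 1]) for j, name in enumerate(names)}
    slope_ci = {
        name: (beta[j + 1] - z * se[j + 1], beta[j + 1] + z * se[j + 1])
        for j, name in enumerate(names)
    }
    return MetaRegressionResult(
        intercept=float(beta[0]),
        slopes=slopes,
        slope_se=slope_se,
        slope_ci=slope_ci,
        tau2=tau2,
        k=k,
    )


def variance_partition(scores, country_labels) -> VariancePartition:
    """One-way random-effects ANOVA variance components (method of moments).

    A negative between-country component is truncated at zero.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(country_labels)
    if x.shape != labels.shape:
        raise ValueError("scores and labels must align")
    groups = pd.Series(x).groupby(pd.Series(labels))
    sizes = groups.size().to_numpy(dtype=float)
    k = len(sizes)
    if k < 2:
        raise ValueError("variance partition requires at least two countries")
    if not np.any(sizes >= 2):
        raise ValueError("at least one country needs two or more scores")
    n_total = sizes.sum()
    grand = x.mean()
    means = groups.mean().to_numpy()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(np.sum((x - pd.Series(labels).map(groups.mean()).to_numpy()) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k) if n_total > k else 0.0
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    between = max(0.0, (ms_between - ms_within) / n0)
    return VariancePartition(between=between, within=ms_within)


def proportion_meta(counts, ns, alpha: float = 0.05) -> MetaResult:
    """Random-effects pooling of per-country proportions on the logit scale.

    Boundary counts (0 or n) get a 0.5 continuity correction; countries
    with n = 0 are dropped with a warning.  The returned estimate and
    intervals are back-transformed to the proportion scale; ``se``,
    ``tau2``, ``q`` and ``i2`` remain on the logit scale.
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(ns, dtype=float)
    if np.any((x < 0) | (x > n)):
        raise ValueError("counts must satisfy 0 <= count <= n")
    keep = n > 0
    if not np.all(keep):
        warnings.warn("dropping countries with n = 0", stacklevel=2)
        x, n = x[keep], n[keep]
    boundary = (x == 0) | (x == n)
    x_adj = np.where(boundary, x + 0.5, x)
    n_adj = np.where(boundary, n + 1.0, n)
    p = x_adj / n_adj
    y = logit(p)
    v = 1.0 / (n_adj * p) + 1.0 / (n_adj * (1.0 - p))
    res = random_effects_meta(y, v, alpha=alpha)
    return MetaResult(
        estimate=float(expit(res.estimate)),
        se=res.se,
        tau2=res.tau2,
        q=res.q,
        df=res.df,
        q_pvalue=res.q_pvalue,
        i2=res.i2,
        ci_low=float(expit(res.ci_low)),
        ci_high=float(expit(res.ci_high)),
        pi_low=float(expit(res.pi_low)) if np.isfinite(res.pi_low) else np.nan,
        pi_high=float(expit(res.pi_high)) if np.isfinite(res.pi_high) else np.nan,
        k=res.k,
    )


def forest_plot(
    summary: pd.DataFrame,
    meta: MetaResult,
    path: str,
    value_col: str = "mean_score",
    se_col: str | None = None,
) -> None:
    """Write a simple forest-style plot of country effects and the pooled
    estimate (with confidence and prediction intervals) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.sort_values(value_col).reset_index(drop=True)
    if se_col is None:
        se = df["sd_score"] / np.sqrt(df["n"])
    else:
        se = df[se_col]
    fig_height = max(3.0, 0.18 * len(df) + 1.5)
    fig, ax = plt.subplots(figsize=(6, fig_height))
    ypos = np.arange(len(df))
    ax.errorbar(
        df[value_col], ypos, xerr=1.96 * se, fmt="o", ms=3, lw=1, color="tab:blue"
    )
    ax.axvline(meta.estimate, color="tab:red", lw=1, label="pooled")
    ax.axvspan(meta.ci_low, meta.ci_high, color="tab:red", alpha=0.15)
    if np.isfinite(meta.pi_low):
        ax.axvspan(meta.pi_low, meta.pi_high, color="tab:orange", alpha=0.08,
                   label="prediction interval")
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["country_id"], fontsize=6)
    ax.set_xlabel(value_col)
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
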
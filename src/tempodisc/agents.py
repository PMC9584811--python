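"""Parametric discounting agents and the synthetic study generator.

Agents evaluate each binary prospect pair by discounted utility.  The
discount factor for waiting from month ``a`` to month ``b`` (``dt`` years)
is built from a model family plus four behavioural modifiers, each of which
reproduces one intertemporal-choice anomaly when it departs from its
neutral value:

* ``magnitude_exponent`` (gamma >= 0): the effective annual rate is
  ``k * (amount / anchor) ** (-gamma)``, so larger amounts are discounted
  at lower rates (absolute-magnitude effect);
* ``sign_ratio`` (rho >= 0): losses are discounted at ``rho * k``; with
  rho < 1 losses are discounted less than gains (gain-loss asymmetry);
* ``framing_premium`` (phi, in units of the anchor): a utility bonus for
  the earlier option that applies only when the item is framed as a bonus
  for waiting (delay framing), producing delay-speedup asymmetry;
* ``subadditivity_exponent`` (s in (0, 1]): interval length enters the
  exponent as ``dt ** s``, so with s < 1 a single 24-month wait is
  discounted less than two compounded 12-month waits (subadditivity);
* the quasi-hyperbolic family applies the beta penalty to any prospect
  delayed from today, generating present bias when beta < 1.

When both prospects of an item are in the future the later one is
discounted back through the earlier one's date (chained per elapsed
interval), so a beta < 1 cancels between two future prospects — the
standard beta-delta present-bias pattern.

Choices follow a logistic rule in the utility difference scaled by
``temperature * anchor``; temperature 0 gives deterministic choice, with
ties resolved to the earlier option (the delayed prospect must be strictly
better to be chosen).

:func:`simulate_study` walks whole populations through the instrument with
vectorised numpy arithmetic; :func:`agent_chooser` provides the equivalent
scalar route through :mod:`tempodisc.instrument` for cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .instrument import (
    ANOMALY_SETS,
    BASELINE_SETS,
    ChoiceItem,
    CountryAnchor,
    DELAYED,
    IMMEDIATE,
    walk_instrument,
)

__all__ = [
    "RespondentParams",
    "InjectionRates",
    "PopulationConfig",
    "discount_factor",
    "choice_probability",
    "agent_chooser",
    "make_synthetic_anchors",
    "sample_population",
    "simulate_study",
]

_FAMILY_CODES = {"exponential": 0, "hyperbolic": 1, "quasi_hyperbolic": 2}

EMPLOYMENT_LEVELS = ("full_time", "part_time", "unemployed", "student", "retired")
_EMPLOYMENT_PROBS = (0.50, 0.15, 0.10, 0.16, 0.09)


@dataclass(frozen=True)
class RespondentParams:
    """Generative discounting parameters for one agent.

    ``annual_rate`` is the exponential/hyperbolic rate k per year; the
    quasi-hyperbolic family is parameterised by ``beta`` and ``delta``
    (annual), with k taken as ``-ln(delta)``.  ``anchor_value`` is the
    reference amount for magnitude scaling and the framing premium.
    """

    model_family: str = "exponential"
    annual_rate: float = 0.15
    beta: float = 1.0
    delta: float | None = None
    sign_ratio: float = 1.0
    magnitude_exponent: float = 0.0
    framing_premium: float = 0.0
    subadditivity_exponent: float = 1.0
    temperature: float = 0.0
    anchor_value: float = 1.0

    def __post_init__(self) -> None:
        if self.model_family not in _FAMILY_CODES:
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.model_family == "quasi_hyperbolic":
            if self.delta is None or not 0.0 < self.delta <= 1.0:
                raise ValueError("quasi_hyperbolic requires delta in (0, 1]")
            if not 0.0 < self.beta <= 1.0:
                raise ValueError("quasi_hyperbolic requires beta in (0, 1]")
        else:
            if self.annual_rate < 0:
                raise ValueError("annual_rate must be non-negative")
        if self.sign_ratio < 0:
            raise ValueError("sign_ratio must be non-negative")
        if self.magnitude_exponent < 0:
            raise ValueError("magnitude_exponent must be non-negative")
        if not 0.0 < self.subadditivity_exponent <= 1.0:
            raise ValueError("subadditivity_exponent must lie in (0, 1]")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.anchor_value <= 0:
            raise ValueError("anchor_value must be positive")

    @property
    def effective_rate(self) -> float:
        """Annual rate k; for the beta-delta family, -ln(delta)."""
        if self.model_family == "quasi_hyperbolic":
            return -math.log(self.delta)
        return self.annual_rate


def _factor_arrays(family, k, beta, rho, gamma, s, anchor, amount, is_loss, start, end):
    """Vectorised discount factor for the interval [start, end] (months)."""
    dt = (np.asarray(end, dtype=float) - np.asarray(start, dtype=float)) / 12.0
    k_eff = k * (np.asarray(amount, dtype=float) / anchor) ** (-gamma)
    k_eff = np.where(is_loss, k_eff * rho, k_eff)
    x = dt**s
    hyperbolic = 1.0 / (1.0 + k_eff * x)
    exponential = np.exp(-k_eff * x)
    f = np.where(family == _FAMILY_CODES["hyperbolic"], hyperbolic, exponential)
    starts_today = (np.asarray(start) == 0) & (dt > 0)
    f = np.where(
        (family == _FAMILY_CODES["quasi_hyperbolic"]) & starts_today, beta * f, f
    )
    return f


def _params_arrays(params: RespondentParams) -> dict:
    return {
        "family": np.asarray(_FAMILY_CODES[params.model_family]),
        "k": np.asarray(params.effective_rate, dtype=float),
        "beta": np.asarray(params.beta, dtype=float),
        "rho": np.asarray(params.sign_ratio, dtype=float),
        "gamma": np.asarray(params.magnitude_exponent, dtype=float),
        "s": np.asarray(params.subadditivity_exponent, dtype=float),
        "phi": np.asarray(params.framing_premium, dtype=float),
        "T": np.asarray(params.temperature, dtype=float),
        "anchor": np.asarray(params.anchor_value, dtype=float),
    }


def discount_factor(
    params: RespondentParams, amount: float, sign: str, start: float, end: float
) -> float:
    """Present-value multiplier for delaying ``amount`` from ``start`` to
    ``end`` months, applying family, magnitude, sign and subadditivity
    modifiers.  Always in (0, 1]."""
    if not end > start or start < 0:
        raise ValueError("require end > start >= 0 (months)")
    if not amount > 0:
        raise ValueError("amount must be positive")
    if sign not in ("gain", "loss"):
        raise ValueError(f"sign must be 'gain' or 'loss', got {sign!r}")
    p = _params_arrays(params)
    f = _factor_arrays(
        p["family"], p["k"], p["beta"], p["rho"], p["gamma"], p["s"],
        p["anchor"], amount, sign == "loss", start, end,
    )
    return float(f)


def _utility_pair(p: dict, a0, t0, a1, t1, is_loss, framing):
    """Discounted utilities of the earlier (a0@t0) and later (a1@t1) prospect.

    The later prospect is discounted through the elapsed intervals
    [0, t0] and [t0, t1]; under delay framing the earlier option receives
    the framing premium (in anchor units)."""
    args = (p["family"], p["k"], p["beta"], p["rho"], p["gamma"], p["s"], p["anchor"])
    f0_early = _factor_arrays(*args, a0, is_loss, 0, t0)
    f0_late = _factor_arrays(*args, a1, is_loss, 0, t0)
    f_span = _factor_arrays(*args, a1, is_loss, t0, t1)
    sgn = np.where(is_loss, -1.0, 1.0)
    u_early = sgn * np.asarray(a0, dtype=float) * f0_early
    u_late = sgn * np.asarray(a1, dtype=float) * f0_late * f_span
    if framing == "delay":
        u_early = u_early + p["phi"] * p["anchor"]
    return u_early, u_late


def _probability_delayed(p: dict, u_early, u_late):
    diff = (u_late - u_early) / p["anchor"]
    T = p["T"]
    with np.errstate(divide="ignore", over="ignore"):
        soft = expit(np.where(T > 0, diff / np.where(T > 0, T, 1.0), 0.0))
    hard = (diff > 0).astype(float)
    return np.where(T > 0, soft, hard)


def choice_probability(params: RespondentParams, item: ChoiceItem) -> float:
    """Probability that the agent chooses the delayed option of ``item``.

    Logistic in the discounted-utility difference with scale
    ``temperature * anchor``; at temperature 0 this is a step function and
    exact ties go to the earlier option."""
    p = _params_arrays(params)
    u_early, u_late = _utility_pair(
        p,
        item.immediate_amount,
        item.immediate_time,
        item.delayed_amount,
        item.delayed_time,
        item.sign == "loss",
        item.framing,
    )
    return float(_probability_delayed(p, u_early, u_late))


def agent_chooser(params: RespondentParams, rng: np.random.Generator | None = None):
    """Scalar chooser for :func:`tempodisc.instrument.walk_instrument`.

    With a generator, choices are sampled from the logistic rule; without
    one (or at temperature 0) they are deterministic."""

    def choose(item: ChoiceItem) -> str:
        prob = choice_probability(params, item)
        if rng is None or params.temperature == 0:
            return DELAYED if prob > 0.5 else IMMEDIATE
        return DELAYED if rng.random() < prob else IMMEDIATE

    return choose


# ---------------------------------------------------------------------------
# population configuration


@dataclass(frozen=True)
class InjectionRates:
    """Independent per-record probabilities of planted QC violations.

    Defaults approximate the attrition observed in large online
    temporal-discounting surveys, where roughly half of the raw sample
    fails at least one pre-registered screen (failure modes overlap)."""

    attention: float = 0.237
    fast_response: float = 0.227
    incomplete: float = 0.365
    nonsense: float = 0.0027
    overage: float = 0.0005
    extreme_value: float = 0.0015
    income_outlier: float = 0.001
    assets_outlier: float = 0.001
    zero_income_employed: float = 0.004

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"rate {name} must lie in [0, 1]")

    @classmethod
    def none(cls) -> "InjectionRates":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class PopulationConfig:
    """Distribution of agent parameters and country effects.

    The linear predictor of log k combines a grand mean, standardised
    country covariates (Gini, log per-capita GDP, inflation) times their
    coefficients, a residual country effect and individual noise:

    ``log k = mean_log_k + b'z_c + u_c + e_i``,
    ``u_c ~ N(0, sd_log_k_country)``, ``e_i ~ N(0, sd_log_k_individual)``.

    Behavioural mechanisms are drawn around their neutral values so that
    anomalies arise at moderate, heterogeneous rates; a
    ``share_quasi_hyperbolic`` fraction of agents gets a beta < 1.
    """

    n_per_country: int = 200
    mean_log_k: float = math.log(0.15)
    sd_log_k_country: float = 0.3
    sd_log_k_individual: float = 0.8
    coef_gini: float = 0.3
    coef_log_gdp: float = -0.3
    coef_inflation: float = 0.2
    share_quasi_hyperbolic: float = 0.3
    beta_range: tuple[float, float] = (0.6, 1.0)
    magnitude_exponent_scale: float = 0.25
    sign_ratio_log_mean: float = math.log(0.85)
    sign_ratio_log_sd: float = 0.25
    framing_premium_sd: float = 0.05
    subadditivity_sd: float = 0.15
    temperature: float = 0.08
    injection: InjectionRates = field(default_factory=InjectionRates)

    def __post_init__(self) -> None:
        if self.n_per_country < 1:
            raise ValueError("n_per_country must be >= 1")
        if not 0.0 <= self.share_quasi_hyperbolic <= 1.0:
            raise ValueError("share_quasi_hyperbolic must lie in [0, 1]")
        if self.sd_log_k_country < 0 or self.sd_log_k_individual <= 0:
            raise ValueError("log-k dispersions must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def planted_icc(self) -> float:
        """Intraclass share of log-k variance from the residual country
        effect, excluding any covariate-driven component."""
        b = self.sd_log_k_country**2
        return b / (b + self.sd_log_k_individual**2)


def make_synthetic_anchors(
    n_countries: int, rng: np.random.Generator
) -> list[CountryAnchor]:
    """Generate a plausible spread of country contexts.

    Anchor values span small to large currency units (log-uniform),
    Gini is uniform on [0.25, 0.55], log per-capita GDP normal around 9.5
    and annual inflation log-normal with a heavy right tail.  Covariates
    are drawn independently so that moderator effects are identifiable.
    """
    anchors = []
    for i in range(n_countries):
        anchor_value = float(np.round(10 ** rng.uniform(2.0, 4.5)))
        anchors.append(
            CountryAnchor(
                country_id=f"C{i + 1:02d}",
                currency_label=f"CUR{i + 1:02d}",
                anchor_value=anchor_value,
                gini=float(rng.uniform(0.25, 0.55)),
                log_gdp_pc=float(rng.normal(9.5, 1.2)),
                inflation_rate=float(np.exp(rng.normal(math.log(5.0), 0.8))),
            )
        )
    return anchors


def _standardized_covariates(anchors: list[CountryAnchor], config: PopulationConfig):
    cols = {
        "gini": ("coef_gini", [a.gini for a in anchors]),
        "log_gdp_pc": ("coef_log_gdp", [a.log_gdp_pc for a in anchors]),
        "inflation_rate": ("coef_inflation", [a.inflation_rate for a in anchors]),
    }
    z = {}
    for name, (coef_name, values) in cols.items():
        coef = getattr(config, coef_name)
        if any(v is None for v in values):
            if coef != 0.0:
                raise ValueError(
                    f"covariate {name} missing for some countries but "
                    f"{coef_name} is non-zero"
                )
            z[name] = np.zeros(len(anchors))
            continue
        arr = np.asarray(values, dtype=float)
        sd = arr.std()
        z[name] = (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)
    return z


def sample_population(
    config: PopulationConfig,
    anchors: list[CountryAnchor],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw agent parameters for every country.

    Returns one row per agent with identifiers, the country context,
    the latent log k, and all behavioural parameters; reproducible for a
    fixed generator state."""
    if not anchors:
        raise ValueError("at least one country anchor is required")
    ids = {a.country_id for a in anchors}
    if len(ids) != len(anchors):
        raise ValueError("duplicate country_id in anchors")
    z = _standardized_covariates(anchors, config)
    n = config.n_per_country
    total = n * len(anchors)

    country_effect = rng.normal(0.0, config.sd_log_k_country, size=len(anchors))
    rows = {
        "participant_id": [],
        "country_id": [],
        "anchor_value": np.empty(total),
        "large_multiplier": np.empty(total),
        "gini": np.empty(total),
        "log_gdp_pc": np.empty(total),
        "inflation_rate": np.empty(total),
        "country_mean_log_k": np.empty(total),
    }
    for j, anchor in enumerate(anchors):
        sl = slice(j * n, (j + 1) * n)
        rows["participant_id"].extend(
            f"{anchor.country_id}-{i + 1:05d}" for i in range(n)
        )
        rows["country_id"].extend([anchor.country_id] * n)
        rows["anchor_value"][sl] = anchor.anchor_value
        rows["large_multiplier"][sl] = anchor.large_multiplier
        rows["gini"][sl] = np.nan if anchor.gini is None else anchor.gini
        rows["log_gdp_pc"][sl] = (
            np.nan if anchor.log_gdp_pc is None else anchor.log_gdp_pc
        )
        rows["inflation_rate"][sl] = (
            np.nan if anchor.inflation_rate is None else anchor.inflation_rate
        )
        rows["country_mean_log_k"][sl] = (
            config.mean_log_k
            + config.coef_gini * z["gini"][j]
            + config.coef_log_gdp * z["log_gdp_pc"][j]
            + config.coef_inflation * z["inflation_rate"][j]
            + country_effect[j]
        )

    log_k = rows["country_mean_log_k"] + rng.normal(
        0.0, config.sd_log_k_individual, size=total
    )
    is_qh = rng.random(total) < config.share_quasi_hyperbolic
    beta = np.where(is_qh, rng.uniform(*config.beta_range, size=total), 1.0)
    gamma = np.abs(rng.normal(0.0, config.magnitude_exponent_scale, size=total))
    rho = np.exp(
        rng.normal(config.sign_ratio_log_mean, config.sign_ratio_log_sd, size=total)
    )
    phi = rng.normal(0.0, config.framing_premium_sd, size=total)
    s = np.clip(1.0 - np.abs(rng.normal(0.0, config.subadditivity_sd, size=total)), 0.4, 1.0)

    df = pd.DataFrame(
        {
            "participant_id": rows["participant_id"],
            "country_id": rows["country_id"],
            "anchor_value": rows["anchor_value"],
            "large_multiplier": rows["large_multiplier"],
            "gini": rows["gini"],
            "log_gdp_pc": rows["log_gdp_pc"],
            "inflation_rate": rows["inflation_rate"],
            "family": np.where(is_qh, _FAMILY_CODES["quasi_hyperbolic"],
                               _FAMILY_CODES["exponential"]),
            "log_k": log_k,
            "k": np.exp(log_k),
            "beta": beta,
            "sign_ratio": rho,
            "magnitude_exponent": gamma,
            "framing_premium": phi,
            "subadditivity_exponent": s,
            "temperature": np.full(total, config.temperature),
        }
    )
    return df


# ---------------------------------------------------------------------------
# vectorised instrument walk


def _population_param_arrays(pop: pd.DataFrame) -> dict:
    return {
        "family": pop["family"].to_numpy(),
        "k": pop["k"].to_numpy(dtype=float),
        "beta": pop["beta"].to_numpy(dtype=float),
        "rho": pop["sign_ratio"].to_numpy(dtype=float),
        "gamma": pop["magnitude_exponent"].to_numpy(dtype=float),
        "s": pop["subadditivity_exponent"].to_numpy(dtype=float),
        "phi": pop["framing_premium"].to_numpy(dtype=float),
        "T": pop["temperature"].to_numpy(dtype=float),
        "anchor": pop["anchor_value"].to_numpy(dtype=float),
        "large_mult": pop["large_multiplier"].to_numpy(dtype=float),
    }


def _draw_choices(p, u_early, u_late, rng):
    prob = _probability_delayed(p, u_early, u_late)
    draws = rng.random(prob.shape)
    return np.where(p["T"] > 0, draws < prob, u_late > u_early)


def _run_baseline_set(p: dict, set_id: str, rng) -> tuple[np.ndarray, np.ndarray]:
    base = np.rint(p["anchor"])
    if set_id == "large_gain":
        base = np.rint(p["anchor"] * p["large_mult"])
    is_loss = set_id == "loss"

    def respond(mult):
        a1 = np.rint(mult * base)
        u_e, u_l = _utility_pair(p, base, 0, a1, 12, is_loss, "neutral")
        return _draw_choices(p, u_e, u_l, rng)

    d1 = respond(1.10)
    ascending = d1 if is_loss else ~d1
    d2 = respond(np.where(ascending, 1.20, 1.02))
    d3 = respond(np.where(ascending, 1.50, 1.01))
    done_at_two = d2 != d1

    ch = lambda d: np.where(d, DELAYED, IMMEDIATE)
    pattern = np.char.add(np.char.add(ch(d1), ch(d2)),
                          np.where(done_at_two, "", ch(d3)))
    return pattern, np.stack([d1, d2, d3 & ~done_at_two])


def simulate_choices(pop: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Walk every agent through the instrument (vectorised).

    Equivalent to running :func:`tempodisc.instrument.walk_instrument` with
    :func:`agent_chooser` per agent, but in a handful of array operations.
    Returns the choice columns of the response schema."""
    p = _population_param_arrays(pop)

    patterns = {}
    raw = {}
    for set_id in BASELINE_SETS:
        patterns[set_id], raw[set_id] = _run_baseline_set(p, set_id, rng)

    base = np.rint(p["anchor"])
    d1, d2, d3 = raw["small_gain"]
    m_ind = np.select(
        [d1 & d2 & d3, d1 & d2, d1, ~d1 & d2, d3],
        [1.01, 1.02, 1.10, 1.20, 1.50],
        default=1.50,
    )
    censored = ~d1 & ~d2 & ~d3
    v = np.rint(m_ind * base)
    premium = v - base

    def respond(a0, t0, a1, t1, framing):
        u_e, u_l = _utility_pair(p, a0, t0, a1, t1, False, framing)
        d = _draw_choices(p, u_e, u_l, rng)
        return np.where(d, DELAYED, IMMEDIATE)

    out = pd.DataFrame(
        {
            "participant_id": pop["participant_id"].to_numpy(),
            "country_id": pop["country_id"].to_numpy(),
            "choices_small_gain": patterns["small_gain"],
            "choices_loss": patterns["loss"],
            "choices_large_gain": patterns["large_gain"],
            "choice_present_bias": respond(base, 12, v, 24, "neutral"),
            "choice_subadditivity": respond(
                base, 0, np.rint(base + 2 * premium), 24, "neutral"
            ),
            "choice_delay_framing": respond(base, 0, v, 12, "delay"),
            "choice_speedup_framing": respond(base, 0, v, 12, "speedup"),
            "indifference_value": v,
            "indifference_censored": censored,
        }
    )
    return out


# ---------------------------------------------------------------------------
# full study simulation with demographics and planted QC violations


def simulate_study(
    population: pd.DataFrame,
    rng: np.random.Generator,
    injection: InjectionRates | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the raw response table for a sampled population.

    Walks every agent through the instrument, attaches response times,
    demographics and financial variables, and plants QC violations at the
    configured rates.  Returns ``(responses, truth)`` where ``truth``
    carries the generative parameters, the latent log k and one boolean
    ``injected_*`` column per violation type.
    """
    if population.empty:
        raise ValueError("population is empty")
    injection = injection if injection is not None else InjectionRates()
    responses = simulate_choices(population, rng)
    n = len(population)
    anchor = population["anchor_value"].to_numpy(dtype=float)

    # clean demographics; planted violations overwrite below
    monthly_income = 10.0 * anchor  # the anchor is ~10% of monthly income
    income = np.exp(rng.normal(np.log(monthly_income), 0.6))
    assets = np.exp(rng.normal(np.log(30.0 * anchor), 1.0))
    debt = np.exp(rng.normal(np.log(5.0 * anchor), 1.2))
    debt = np.where(rng.random(n) < 0.3, 0.0, debt)
    age = np.clip(np.rint(rng.normal(38.0, 13.0, size=n)), 18, 90)
    employment = rng.choice(EMPLOYMENT_LEVELS, size=n, p=_EMPLOYMENT_PROBS)
    total_time = 120.0 + np.exp(rng.normal(np.log(300.0), 0.5, size=n))
    completion = np.ones(n)
    attention_choice = np.full(n, "receive", dtype=object)
    nonsense = np.zeros(n, dtype=bool)

    flags = {
        name: rng.random(n) < getattr(injection, name)
        for name in (
            "attention",
            "fast_response",
            "incomplete",
            "nonsense",
            "overage",
            "extreme_value",
            "income_outlier",
            "assets_outlier",
            "zero_income_employed",
        )
    }
    attention_choice[flags["attention"]] = "pay"
    total_time = np.where(
        flags["fast_response"], rng.uniform(20.0, 119.0, size=n), total_time
    )
    completion = np.where(
        flags["incomplete"], rng.uniform(0.2, 0.9, size=n), completion
    )
    nonsense |= flags["nonsense"]
    age = np.where(flags["overage"], rng.integers(101, 120, size=n), age)
    debt = np.where(
        flags["extreme_value"], rng.uniform(1.1e8, 9e8, size=n), debt
    )
    income = np.where(flags["income_outlier"], income * 5000.0, income)
    assets = np.where(flags["assets_outlier"], assets * 40000.0, assets)
    income = np.where(flags["zero_income_employed"], 0.0, income)
    employment = np.where(
        flags["zero_income_employed"], "full_time", employment
    )

    responses["attention_choice"] = attention_choice
    responses["nonsense_flag"] = nonsense
    responses["total_time_seconds"] = np.round(total_time, 1)
    responses["completion_fraction"] = np.round(completion, 3)
    responses["age"] = age.astype(int)
    responses["income"] = np.round(income, 2)
    responses["assets"] = np.round(assets, 2)
    responses["debt"] = np.round(debt, 2)
    responses["employment"] = employment

    truth = population.copy()
    for name, mask in flags.items():
        truth[f"injected_{name}"] = mask
    return responses, truth
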
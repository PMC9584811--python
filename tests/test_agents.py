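"""Discounting agents: closed forms, choice rule, determinism, mechanisms."""

import numpy as np
import pandas as pd
import pytest

from tempodisc import (
    CountryAnchor,
    PopulationConfig,
    RespondentParams,
    agent_chooser,
    choice_probability,
    discount_factor,
    make_synthetic_anchors,
    sample_population,
    simulate_study,
)
from tempodisc.agents import InjectionRates, simulate_choices, _FAMILY_CODES
from tempodisc.instrument import ChoiceItem, walk_instrument
from tempodisc.scoring import classify_anomalies, score_path

US = CountryAnchor("US", "USD", 500.0)

#: single-mechanism parameter grid: each agent trips exactly its matching
#: anomaly among the four structural flags (magnitude, gain-loss, framing,
#: subadditivity); the beta agents additionally document the present-bias
#: mechanism.  Rates place the titration switch inside (or, for the
#: subadditive agents, just beyond) the offered multiplier range.
MECHANISM_GRID = [
    *[
        (RespondentParams(annual_rate=0.3, magnitude_exponent=g, anchor_value=500.0),
         "absolute_magnitude")
        for g in (0.8, 1.0, 1.2)
    ],
    *[
        (RespondentParams(annual_rate=0.3, sign_ratio=r, anchor_value=500.0),
         "gain_loss")
        for r in (0.1, 0.2, 0.3)
    ],
    *[
        (RespondentParams(annual_rate=0.15, framing_premium=phi, anchor_value=500.0),
         "delay_speedup")
        for phi in (0.1, 0.2)
    ],
    *[
        (RespondentParams(annual_rate=0.42, subadditivity_exponent=s, anchor_value=500.0),
         "subadditivity")
        for s in (0.5, 0.6)
    ],
    *[
        (RespondentParams(model_family="quasi_hyperbolic", beta=b,
                          delta=float(np.exp(-0.05)), anchor_value=500.0),
         "present_bias")
        for b in (0.6, 0.8)
    ],
]

STRUCTURAL_FLAGS = ("absolute_magnitude", "gain_loss", "delay_speedup", "subadditivity")


class TestDiscountFactor:
    def test_no_discounting_when_rate_zero(self):
        p = RespondentParams(annual_rate=0.0)
        assert discount_factor(p, 100, "gain", 0, 24) == 1.0

    def test_hyperbolic_closed_form(self):
        p = RespondentParams(model_family="hyperbolic", annual_rate=0.5)
        np.testing.assert_allclose(
            discount_factor(p, 100, "gain", 0, 12), 1 / 1.5, rtol=1e-12
        )

    def test_quasi_hyperbolic_closed_form(self):
        p = RespondentParams(model_family="quasi_hyperbolic", beta=0.7, delta=0.9)
        np.testing.assert_allclose(
            discount_factor(p, 100, "gain", 0, 24), 0.7 * 0.81, rtol=1e-12
        )

    def test_beta_not_applied_to_future_start(self):
        p = RespondentParams(model_family="quasi_hyperbolic", beta=0.7, delta=0.9)
        np.testing.assert_allclose(
            discount_factor(p, 100, "gain", 12, 24), 0.9, rtol=1e-12
        )

    def test_sign_ratio_discounts_losses_less(self):
        p = RespondentParams(annual_rate=0.5, sign_ratio=0.5)
        gain = discount_factor(p, 100, "gain", 0, 12)
        loss = discount_factor(p, 100, "loss", 0, 12)
        assert loss > gain

    def test_magnitude_scaling_lowers_rate_for_large_amounts(self):
        p = RespondentParams(annual_rate=0.5, magnitude_exponent=1.0, anchor_value=100)
        assert discount_factor(p, 1000, "gain", 0, 12) > discount_factor(
            p, 100, "gain", 0, 12
        )

    def test_subadditive_exponent_softens_long_intervals(self):
        p1 = RespondentParams(annual_rate=0.5, subadditivity_exponent=1.0)
        p2 = RespondentParams(annual_rate=0.5, subadditivity_exponent=0.5)
        # a single 24-month wait is discounted less than compounded waits
        assert discount_factor(p2, 100, "gain", 0, 24) > discount_factor(
            p1, 100, "gain", 0, 24
        )
        # ...while any 12-month interval is unaffected
        np.testing.assert_allclose(
            discount_factor(p2, 100, "gain", 12, 24),
            discount_factor(p1, 100, "gain", 12, 24),
        )

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(RespondentParams(), 100, "gain", 12, 12)


class TestChoiceRule:
    def test_equal_utilities_give_half(self):
        p = RespondentParams(annual_rate=0.0, temperature=0.5)
        item = ChoiceItem("small_gain", "gain", 500, 0, 500, 12)
        assert choice_probability(p, item) == pytest.approx(0.5)

    def test_zero_temperature_is_a_step_function(self):
        p = RespondentParams(annual_rate=0.0)
        better = ChoiceItem("small_gain", "gain", 500, 0, 550, 12)
        assert choice_probability(p, better) == 1.0
        tie = ChoiceItem("small_gain", "gain", 500, 0, 500, 12)
        assert choice_probability(p, tie) == 0.0  # ties go to the earlier option

    def test_framing_premium_only_affects_delay_framing(self):
        base = dict(annual_rate=0.1, temperature=0.3, anchor_value=500.0)
        plain = RespondentParams(**base)
        framed = RespondentParams(framing_premium=0.2, **base)
        delay = ChoiceItem("delay_framing", "gain", 500, 0, 600, 12, framing="delay")
        speedup = ChoiceItem("speedup_framing", "gain", 500, 0, 600, 12, framing="speedup")
        assert choice_probability(framed, delay) < choice_probability(plain, delay)
        assert choice_probability(framed, speedup) == pytest.approx(
            choice_probability(plain, speedup)
        )

    def test_strongly_impatient_agent_takes_immediate_gains_delayed_losses(self):
        p = RespondentParams(annual_rate=2.0, anchor_value=500.0)
        path = walk_instrument(US, agent_chooser(p))
        assert path.choices_small_gain == "III"
        assert path.choices_loss == "DDD"
        assert score_path(path).discounting_score >= 15


class TestMechanismSpecificity:
    @pytest.mark.parametrize("params, target", MECHANISM_GRID)
    def test_single_mechanism_agent_trips_only_its_flag(self, params, target):
        path = walk_instrument(US, agent_chooser(params))
        flags = classify_anomalies(path)
        assert flags[target], (target, flags)
        for other in STRUCTURAL_FLAGS:
            if other != target:
                assert not flags[other], (target, other, flags)

    def test_subadditive_subpopulation_pattern_in_batch(self):
        # s < 1 agents accept the 24-month offer but reject the shifted
        # 12->24 offer, the defining subadditivity signature
        n = 200
        pop = pd.DataFrame(
            {
                "participant_id": [f"a{i}" for i in range(n)],
                "country_id": "US",
                "anchor_value": 500.0,
                "large_multiplier": 10.0,
                "family": _FAMILY_CODES["exponential"],
                "k": 0.42,
                "beta": 1.0,
                "sign_ratio": 1.0,
                "magnitude_exponent": 0.0,
                "framing_premium": 0.0,
                "subadditivity_exponent": 0.6,
                "temperature": 0.0,
            }
        )
        out = simulate_choices(pop, np.random.default_rng(0))
        assert (out["choice_subadditivity"] == "D").all()
        assert (out["choice_present_bias"] == "I").all()

    def test_score_weakly_increasing_in_rate_at_zero_temperature(self):
        scores = []
        for k in np.linspace(0.01, 1.2, 40):
            p = RespondentParams(annual_rate=float(k), anchor_value=500.0)
            scores.append(score_path(walk_instrument(US, agent_chooser(p))).discounting_score)
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestPopulation:
    def test_seeded_determinism_is_byte_identical(self, demo_anchors):
        def run():
            config = PopulationConfig(n_per_country=40)
            rng = np.random.default_rng(123)
            pop = sample_population(config, demo_anchors, rng)
            return simulate_study(pop, rng, config.injection)

        r1, t1 = run()
        r2, t2 = run()
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_coefficients_give_exchangeable_countries(self, demo_anchors):
        config = PopulationConfig(
            n_per_country=2000,
            coef_gini=0.0,
            coef_log_gdp=0.0,
            coef_inflation=0.0,
            sd_log_k_country=0.0,
        )
        pop = sample_population(config, demo_anchors, np.random.default_rng(5))
        means = pop.groupby("country_id")["log_k"].mean()
        assert means.max() - means.min() < 0.1

    def test_positive_gini_coefficient_raises_log_k(self):
        rng = np.random.default_rng(11)
        anchors = make_synthetic_anchors(30, rng)
        config = PopulationConfig(
            n_per_country=100,
            coef_gini=0.5,
            coef_log_gdp=0.0,
            coef_inflation=0.0,
            sd_log_k_country=0.05,
        )
        pop = sample_population(config, anchors, rng)
        country = pop.groupby("country_id").agg({"log_k": "mean", "gini": "first"})
        assert country["log_k"].corr(country["gini"]) > 0.5

    def test_zero_injection_rates_plant_no_violations(self, small_study):
        _, truth, _ = small_study
        injected = truth.filter(like="injected_")
        assert not injected.to_numpy().any()

    def test_unknown_mechanism_parameters_rejected(self):
        with pytest.raises(ValueError):
            RespondentParams(model_family="quasi_hyperbolic", beta=0.5, delta=1.5)
        with pytest.raises(ValueError):
            RespondentParams(subadditivity_exponent=0.0)
        with pytest.raises(ValueError):
            RespondentParams(temperature=-0.1)

    def test_duplicate_country_ids_rejected(self, us_anchor):
        with pytest.raises(ValueError):
            sample_population(
                PopulationConfig(), [us_anchor, us_anchor], np.random.default_rng(0)
            )


class TestVectorisedAgainstScalar:
    def test_batch_walk_equals_state_machine_at_zero_temperature(self, demo_anchors):
        rng = np.random.default_rng(7)
        config = PopulationConfig(n_per_country=40, temperature=0.0)
        pop = sample_population(config, demo_anchors, rng)
        vec = simulate_choices(pop, np.random.default_rng(0))
        by_id = {a.country_id: a for a in demo_anchors}
        code_to_family = {v: k for k, v in _FAMILY_CODES.items()}
        for i, row in pop.iterrows():
            family = code_to_family[row.family]
            params = RespondentParams(
                model_family=family,
                annual_rate=0.0 if family == "quasi_hyperbolic" else row.k,
                beta=row.beta,
                delta=float(np.exp(-row.k)) if family == "quasi_hyperbolic" else None,
                sign_ratio=row.sign_ratio,
                magnitude_exponent=row.magnitude_exponent,
                framing_premium=row.framing_premium,
                subadditivity_exponent=row.subadditivity_exponent,
                temperature=0.0,
                anchor_value=row.anchor_value,
            )
            path = walk_instrument(by_id[row.country_id], agent_chooser(params))
            got = vec.iloc[i]
            assert path.choices_small_gain == got.choices_small_gain
            assert path.choices_loss == got.choices_loss
            assert path.choices_large_gain == got.choices_large_gain
            assert path.choice_present_bias == got.choice_present_bias
            assert path.choice_subadditivity == got.choice_subadditivity
            assert path.choice_delay_framing == got.choice_delay_framing
            assert path.choice_speedup_framing == got.choice_speedup_framing
            assert path.indifference_value == got.indifference_value
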
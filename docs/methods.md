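# Methods

This note documents the models, conventions and design choices behind
`tempodisc`: the adaptive intertemporal-choice instrument, the behavioural
agent model used to generate synthetic respondents, the quality-control
screens, the 0–19 discounting score with its anomaly flags, and the
country-level meta-analytic machinery.

## The instrument

Each respondent faces three baseline titration (staircase) sets and four
anomaly items, all binary choices between an earlier and a later monetary
prospect.

**Baseline staircases.** A country's *anchor* is roughly 10% of the average
monthly household income in local currency (e.g. US$500).  The first item
offers the anchor now versus 110% of it in 12 months.  Choosing the earlier
option escalates the delayed offer (120%, then 150%); choosing the later
option de-escalates it (102%, then 101%).  A reversal at the second item
ends the set, so a staircase takes two or three items and terminates in one
of six patterns.  The three sets are: a small-magnitude gain, the same
values framed as payments (losses, with the escalation mirrored so that
*delaying payments* escalates), and a large-magnitude gain (anchor ×
`large_multiplier`, default 10).

**Indifference value.** The small-gain staircase yields a coarse
indifference value: the smallest delayed amount the respondent accepted.
The natural-language rule "the largest value at which the respondent chose
the delayed option" is ambiguous for the ascending branch (a respondent who
rejects 550 and accepts 600 has accepted only one value); the
smallest-accepted rule reproduces the canonical worked example — reject
US$550, accept US$600, indifference US$600 — on both branches, so it is the
implemented convention.  A respondent who rejects the delayed option even at
150% is assigned the 150% value with a `censored` flag; anomaly items are
still constructed for them (every respondent answers all four).

**Anomaly items.** With base *b*, indifference *v* and premium *p = v − b*:

| item | earlier | later |
|---|---|---|
| present bias | *b* @ 12 mo | *v* @ 24 mo |
| subadditivity | *b* now | *b + 2p* @ 24 mo |
| delay framing | *b* now | *v* @ 12 mo ("+*p* for waiting") |
| speedup framing | *b* now | *v* @ 12 mo ("−*p* to receive now") |

The subadditivity amount extends the one-year premium *additively* over the
second year (b + 2p), which reproduces the canonical US$700 for
(b, v) = (500, 600); multiplicative compounding would give 720 and is not
used.  Times are fixed at 0/12/24 months; no other horizons are supported.
Amounts are rounded to whole currency units with IEEE round-half-even
(`numpy.rint`), so the scalar state machine and the vectorised simulator
agree bit-for-bit; a custom rounding hook can be passed where a currency
uses coarser denominations.

Every complete path has 10–13 items, and the instrument admits exactly
6³ × 2⁴ = 3456 complete paths, which makes exhaustive enumeration the
natural oracle for every scoring property.

## Scoring

Each staircase pattern maps to a 0–5 *titration category* ordered by
revealed impatience (gains: 0 = accepted the 101% offer, 5 = rejected even
150%; losses mirrored so that always delaying payments scores 5).  The
aggregate **discounting score** is the sum of the three categories (0–15)
plus one point per anomaly item on which the discount-consistent option —
the earlier gain — was chosen (0–4), spanning 0 (always delayed gains /
earlier losses) to 19 (always immediate gains / delayed losses).  This
decomposition is reconstructed from the published score range and the item
structure; it is isolated in `scoring.titration_category` /
`discounting_score` so an alternative weighting can be swapped in.

**Anomaly flags** (default `example` variant, built from the first-item
worked examples):

* *absolute magnitude*: earlier option at the first small-gain item and
  later option at the first large-gain item;
* *gain–loss asymmetry*: earlier option at both the first small-gain item
  (receive now) and the first loss item (pay now);
* *delay–speedup asymmetry*: earlier option under delay framing, later
  option under speedup framing;
* *present bias*: later option at the shifted 12→24-month item;
* *subadditivity*: later option at the 0→24-month item **and** earlier
  option at the shifted 12→24-month item (a strict two-item conjunction —
  deliberately the strictest rule, and empirically the rarest flag).

Each flag has a mirror *inconsistency* flag (reverse magnitude, reverse
gain–loss, reverse framing, future bias, superadditivity) defined as the
choice pattern of the opposite direction; a flag and its mirror can never
hold simultaneously.  A stricter `category` variant replaces the two
staircase-level rules with full category comparisons
(e.g. magnitude = small-gain category > large-gain category).

**A known reconstruction caveat.** The titration overshoots: the recorded
indifference value strictly exceeds the true switch point (a respondent
accepting 120% after rejecting 110% is somewhere in between).  At the
shifted 12→24 item the offer therefore carries a strictly positive premium
relative to the respondent's true one-year discount, so any respondent with
stationary (e.g. exponential) preferences picks the later option and trips
the present-bias flag.  This makes the default present-bias rule the
weakest of the five reconstructions, inflates its prevalence in
simulations, and is the reason the mechanism-specificity analysis below
treats present bias separately.

**Standardisation** uses the pooled sample z-transform with the n−1 sample
standard deviation, computed on the QC-retained sample; zero-variance input
is an error.

## The agent model

Synthetic respondents evaluate prospects by discounted utility.  For an
interval of `dt` years the discount factor is built from a model family and
four modifiers:

* families: exponential `exp(−k·dt^s)`, hyperbolic `1/(1 + k·dt^s)`, and
  quasi-hyperbolic beta–delta, implemented as `beta · delta^(dt^s)` with
  `k = −ln(delta)` and the `beta` penalty applied only to prospects delayed
  from today;
* `magnitude_exponent` γ ≥ 0: effective rate `k·(amount/anchor)^(−γ)` —
  larger amounts discounted at lower rates (absolute-magnitude mechanism);
* `sign_ratio` ρ ≥ 0: losses discounted at `ρ·k`; ρ < 1 means losses are
  discounted less than gains (sign-effect mechanism);
* `framing_premium` φ (in anchor units): a utility bonus for the earlier
  option, applied only under delay framing (framing mechanism);
* `subadditivity_exponent` s ∈ (0, 1]: interval length enters as `dt^s`,
  so a single 24-month wait is discounted less than two compounded
  12-month waits when s < 1 (subadditivity mechanism).

When both prospects are in the future, the later one is discounted through
the earlier one's date (chained per elapsed interval).  Two consequences
matter: the beta penalty cancels between two future prospects (the standard
present-bias pattern), and a 12→24-month interval is discounted exactly
like a 0→12-month one for every stationary agent, so only the `dt^s`
mechanism can separate the whole interval from its parts.

Choices are logistic in the utility difference scaled by
`temperature × anchor`; temperature 0 is a step function with ties resolved
to the earlier option (waiting must be strictly better).  Utilities are
linear in money, so all behaviour is invariant to the currency scale up to
rounding.

**Mechanism → detector specificity.** At temperature 0 the following
documented grid of single-mechanism agents (all other parameters neutral,
anchor 500) trips exactly the matching flag among the four structural
anomalies (magnitude, gain–loss, framing, subadditivity) and no other:

| mechanism | grid | matching flag |
|---|---|---|
| γ | k = 0.30, γ ∈ {0.8, 1.0, 1.2} | absolute magnitude |
| ρ | k = 0.30, ρ ∈ {0.1, 0.2, 0.3} | gain–loss |
| φ | k = 0.15, φ ∈ {0.1, 0.2} | delay–speedup |
| s | k = 0.42, s ∈ {0.5, 0.6} | subadditivity |
| β | δ = e^(−0.05), β ∈ {0.6, 0.8} | present bias |

The subadditive agents necessarily sit just beyond the 150% titration
ceiling (censored indifference): inside the ceiling the overshoot forces a
patient choice at the shifted item, which the strict two-item conjunction
excludes.  This mirrors the deliberately strict published criterion and
explains why the subadditivity flag is the rarest.  Because of the
overshoot caveat above, impatient agents of *any* type also trip the
present-bias flag; the specificity claim therefore covers the four
structural flags, with the beta agents documenting the present-bias
mechanism itself.

## Population generator

`PopulationConfig` defines the study conditions.  The latent log discount
rate is

`log k = mean_log_k + b_gini·z(gini) + b_gdp·z(log GDP pc) +
b_infl·z(inflation) + u_c + e_i`,

with covariates standardised across countries, residual country effect
`u_c ~ N(0, sd_country)` and individual noise `e_i ~ N(0, sd_individual)`.
Defaults: `mean_log_k = ln 0.15` (a median annual discount rate of 15%,
mid-range for hypothetical money questions), `sd_country = 0.3`,
`sd_individual = 0.8` (individual dispersion dominating country dispersion,
keeping the between-country share of score variance under ~0.2),
coefficients `+0.3` (Gini), `−0.3` (log GDP), `+0.2` (inflation) on the
standardised scale — modest effects with the directions reported for
real populations.  Mechanisms are drawn heterogeneously around neutral
values (30% quasi-hyperbolic with β ~ U(0.6, 1); γ half-normal(0.25);
ρ log-normal(ln 0.85, 0.25); φ ~ N(0, 0.05); s = 1 − |N(0, 0.15)| clipped
to [0.4, 1]); choice temperature 0.08.  Under these defaults a 61 × 200
study yields a mean score near 11, anomaly prevalences in the 10–20% range
(present bias higher, per the caveat), and a between-country share of score
variance below 0.2.

Planted QC violations are injected independently per record at the marginal
failure rates of large online surveys of this kind (attention 23.7%, speedy
responses 22.7%, incompleteness 36.5%, plus rare nonsense text, implausible
age, extreme money values, relative outliers and zero-income-employed
contradictions).  Because the draws are independent, total attrition
(~60%) is higher than in surveys where careless respondents fail several
screens at once; the generator makes no attempt to model that correlation.
Response times are log-normal shifted above 120 s, and demographics come
from simple categorical/log-normal placeholders — sufficient to exercise
the QC screens, with no claim of demographic realism.  What passing tests
on these data show is that the pipeline's logic is correct under known
generating mechanisms, not that real populations behave like the agents.

## Quality control

Screens run in two stages with every failed rule attributed per record
(counts can exceed removals).  Stage one: attention failure; nonsense-text
flag (an input column — the package does no text analysis); age > 100;
response time below `median − 3·MAD` or below 120 s; completion ≤ 90%.
Stage two, applied only to money analyses and reported separately: any
money field > 1e8; income > 100 MADs above the country median; assets >
1000 MADs above the country median; zero income while employed full-time.
MAD is the raw median absolute deviation (no 1.4826 constant; configurable).
The median/MAD references are computed on records surviving the first three
rules so nonsense records cannot contaminate them; the report returns the
references so a re-application with fixed thresholds is idempotent.
Missing optional money fields never trigger a rule.

## Aggregation

Country means enter a DerSimonian–Laird random-effects meta-analysis with
within-country variance `sd²/n`; anomaly proportions are pooled on the
logit scale (0.5 continuity correction at boundary counts) and
back-transformed.  `I² = max(0, (Q − df)/Q)`; the 95% prediction interval
uses a t quantile with k − 2 degrees of freedom and is reported as
undefined for k = 2 rather than extrapolated.  Moderator meta-regression is
weighted least squares with a method-of-moments residual τ² (the classical
DL-type estimator; REML is out of scope) — it matches R's `metafor` with
`method="DL"` to eight decimals on shared fixtures.  The within/between
variance split uses the one-way random-effects ANOVA estimator with the
unbalanced-n correction `n0 = (N − Σn_i²/N)/(k − 1)` and truncation of a
negative between-component at zero; full likelihood-based multilevel
estimation is out of scope.

## Problem sizes and numerical conventions

* Exhaustive path enumeration (3456 paths) backs every scoring property.
* Parameter-recovery experiments use 61 countries × 200 agents; the
  moderator sign-recovery experiment runs 100 seeded replicates with fresh
  country covariates per replicate; the intraclass-share recovery uses a
  single replicate with coefficients zeroed and the residual country
  dispersion set for a planted share of 0.15.
* All randomness flows through `numpy.random.Generator`; a fixed seed gives
  byte-identical output tables.
* Ties at temperature 0 go to the earlier option; amounts round half to
  even; the logistic uses `scipy.special.expit`.
* Framing-item order randomisation is a presentation-level detail that does
  not affect scoring and is not modelled; the two framing items are treated
  symmetrically in the score.

## Limitations

* The score decomposition and the anomaly coding are reconstructions from
  the published score range and worked examples; the present-bias rule is
  the weakest (see the overshoot caveat) and its simulated prevalence is
  accordingly inflated.
* The generator's QC violations are independent across rules; real careless
  responding is correlated, so simulated attrition overstates unique
  removals.
* Country covariates are drawn independently in the synthetic country
  generator; real covariates are correlated (richer countries have lower
  inflation), so real moderator analyses face collinearity the recovery
  experiments do not.
* No per-participant discount-rate estimation is attempted: the instrument
  yields categories and flags, not a continuous k.
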
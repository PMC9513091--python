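"""Synthetic participants, ratings, choice sets, choices, and form delays.

The generator emulates the statistical structure of a behavioral study of
procrastination: a cohort of participants who (i) rate the euro-equivalents
of reward/effort/punishment items, (ii) make intertemporal choices between
a sooner/lower and a later/greater quantity of one item, with delays drawn
from a fixed ten-delay design, (iii) choose between doing an effortful
rewarded task now or tomorrow, and (iv) return a set of administrative
forms with some delay before a 30-day deadline.

Choices are stochastic (softmax) under known per-participant discount
rates, so every downstream stage — fitting, model comparison, regression —
can be tested against a known ground truth.  Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .choice_models import ChoiceTrial, NowTomorrowTrial, intertemporal_probs, TrialArrays
from .discounting import AVERSIVE_CATEGORIES, DiscountParams, Option
from .procrastination import (
    ProcrastinationTask,
    dynamic_completion_distribution,
    static_optimal_delay,
    static_softmax_distribution,
)
from .valuation import ItemRating

__all__ = [
    "DELAY_SET",
    "PopulationSpec",
    "SyntheticParticipant",
    "generate_population",
    "generate_ratings",
    "generate_choice_set",
    "simulate_choices",
    "generate_now_tomorrow_trials",
    "simulate_now_tomorrow_choices",
    "simulate_form_delays",
]

#: The ten admissible delays (days) of the intertemporal choice design.
DELAY_SET = (0, 1, 2, 3, 5, 7, 10, 14, 21, 30)

_SUBCATS = {
    "reward": ("food", "goods"),
    "effort": ("cognitive", "motor"),
    "punishment": ("bodily", "abstract"),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Study-level generative settings.

    Discount rates and inverse temperatures are log-normal across
    participants, given as (median, sigma) with sigma the SD of the log.
    Defaults encode the population tendency that effort is discounted more
    steeply than reward (median k_E > median k_R) and the canonical home
    task: a 30-day deadline with reward 40-60 and effort cost 20-40 a.u.
    """

    n_participants: int = 43
    k_R_dist: tuple[float, float] = (0.05, 0.5)
    k_E_dist: tuple[float, float] = (0.12, 0.5)
    k_P_dist: tuple[float, float] = (0.08, 0.5)
    theta_dist: tuple[float, float] = (1.0, 0.3)
    reward_value_range: tuple[float, float] = (40.0, 60.0)
    effort_cost_range: tuple[float, float] = (20.0, 40.0)
    deadline: int = 30
    n_items_per_category: int = 60
    unit_value_dist: tuple[float, float] = (0.5, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.deadline < 1:
            raise ValueError("deadline must be >= 1")
        for name in ("k_R_dist", "k_E_dist", "k_P_dist", "theta_dist",
                     "unit_value_dist"):
            med, sig = getattr(self, name)
            if med <= 0 or sig < 0:
                raise ValueError(f"{name}: median must be > 0 and sigma >= 0")
        for name in ("reward_value_range", "effort_cost_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < low <= high")


@dataclass(frozen=True)
class SyntheticParticipant:
    """One simulated participant with ground-truth parameters.

    unit_values
        category -> {item_id -> euros per unit}.
    form_cost, compensation
        The E_i and R_i of the at-home form-filling task.
    """

    id: str
    true_params: DiscountParams
    unit_values: dict
    age: int
    gender: int
    form_cost: float
    compensation: float
    deadline: int = 30


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int):
    if sigma == 0:
        return np.full(n, median)
    return median * np.exp(rng.normal(0.0, sigma, n))


def generate_population(spec: PopulationSpec) -> list[SyntheticParticipant]:
    """Draw a cohort of participants from the population spec.

    Deterministic given ``spec.seed``.  Age and gender are nuisance
    covariates, independent of the discounting parameters.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    k_R = _lognormal(rng, *spec.k_R_dist, n)
    k_E = _lognormal(rng, *spec.k_E_dist, n)
    k_P = _lognormal(rng, *spec.k_P_dist, n)
    theta = _lognormal(rng, *spec.theta_dist, n)
    ages = rng.integers(18, 41, n)
    genders = rng.integers(0, 2, n)
    compensation = rng.uniform(*spec.reward_value_range, n)
    form_cost = rng.uniform(*spec.effort_cost_range, n)

    out = []
    for i in range(n):
        unit_values = {}
        for cat in ("reward", "effort", "punishment"):
            vals = _lognormal(
                rng, *spec.unit_value_dist, spec.n_items_per_category
            )
            unit_values[cat] = {
                f"{cat[0]}{j:03d}": float(v) for j, v in enumerate(vals)
            }
        out.append(
            SyntheticParticipant(
                id=f"p{i:03d}",
                true_params=DiscountParams(
                    k_R=float(k_R[i]), k_E=float(k_E[i]), k_P=float(k_P[i]),
                    theta=float(theta[i]), family="hyperbolic_specific",
                ),
                unit_values=unit_values,
                age=int(ages[i]),
                gender=int(genders[i]),
                form_cost=float(form_cost[i]),
                compensation=float(compensation[i]),
                deadline=spec.deadline,
            )
        )
    return out


def generate_ratings(
    participant: SyntheticParticipant, seed: int, jitter: float = 0.1
) -> list[ItemRating]:
    """Monetary-equivalence ratings consistent with the true unit values.

    q1 and q5 are the per-euro quantities implied by the unit value, each
    with independent multiplicative log-normal jitter.
    """
    rng = np.random.default_rng(seed)
    out = []
    for cat, items in participant.unit_values.items():
        subcats = _SUBCATS[cat]
        for j, (item_id, v) in enumerate(items.items()):
            q1 = (1.0 / v) * np.exp(rng.normal(0, jitter))
            q5 = (5.0 / v) * np.exp(rng.normal(0, jitter))
            out.append(
                ItemRating(
                    participant_id=participant.id, item_id=item_id,
                    category=cat, subcategory=subcats[j % 2],
                    q1=float(q1), q5=float(q5),
                )
            )
    return out


def generate_choice_set(
    participant: SyntheticParticipant,
    category: str,
    n_trials: int = 60,
    delays: tuple[int, ...] = DELAY_SET,
    a_priori_k: float = 0.1,
    seed: int = 0,
    dv_range: tuple[float, float] = (-2.0, 2.0),
    sooner_value_range: tuple[float, float] = (4.0, 8.0),
) -> list[ChoiceTrial]:
    """Build an intertemporal choice set for one participant (no picks yet).

    Each trial offers a sooner/lower against a later/greater quantity of a
    distinct item.  To sample the decision space evenly, target
    discounted-value differences (signed desirability, under the a-priori
    rate) are taken from a uniform grid over ``dv_range`` and inverted for
    the later quantity, which is then rounded to a positive integer.
    """
    if not delays:
        raise ValueError("empty delay set")
    if a_priori_k <= 0:
        raise ValueError("a_priori_k must be > 0")
    if n_trials == 0:
        return []
    rng = np.random.default_rng(seed)
    items = list(participant.unit_values[category].items())
    if n_trials <= len(items):
        # no item repeats within a block
        idx = rng.choice(len(items), size=n_trials, replace=False)
    else:
        idx = rng.integers(0, len(items), size=n_trials)
    targets = rng.permutation(np.linspace(*dv_range, n_trials))
    aversive = category in AVERSIVE_CATEGORIES
    trials = []
    for t in range(n_trials):
        item_id, unit = items[idx[t]]
        dv = targets[t]
        v_s_disc = rng.uniform(*sooner_value_range)
        # The later option must carry the greater quantity.  For targets
        # where a short delay gap would force a *smaller* later quantity
        # (strongly negative desirability differences under rewards, or
        # positive ones under costs), resample the delay pair until the gap
        # provides enough discounting room, with a margin for rounding.
        d_s, d_l = 0, max(delays)
        for _ in range(30):
            cand = np.sort(rng.choice(delays, size=2, replace=False))
            room = (
                v_s_disc * a_priori_k * (cand[1] - cand[0])
                / (1 + a_priori_k * cand[1])
            )
            shrink = dv if aversive else -dv  # how much smaller later may be
            if room >= max(0.0, shrink) + unit / (1 + a_priori_k * cand[1]):
                d_s, d_l = int(cand[0]), int(cand[1])
                break
        n_s = max(1, round(v_s_disc * (1 + a_priori_k * d_s) / unit))
        v_s_disc = n_s * unit / (1 + a_priori_k * d_s)
        # signed desirability difference (later - sooner): costs enter negated
        v_l_disc = v_s_disc - dv if aversive else v_s_disc + dv
        n_l = round(v_l_disc * (1 + a_priori_k * d_l) / unit)
        n_l = max(n_l, n_s + 1)  # rounding guard; rarely binds
        trials.append(
            ChoiceTrial(
                participant_id=participant.id,
                category=category,
                option_sooner=Option(n_s, unit, float(d_s), category),
                option_later=Option(n_l, unit, float(d_l), category),
            )
        )
    return trials


def simulate_choices(
    trials: list[ChoiceTrial], params: DiscountParams, seed: int = 0
) -> list[ChoiceTrial]:
    """Draw Bernoulli picks from the softmax choice probabilities."""
    if not trials:
        return []
    rng = np.random.default_rng(seed)
    p = intertemporal_probs(TrialArrays(trials), params)
    picks = (rng.random(len(trials)) < p).astype(int)
    return [replace(t, chose_later=int(c)) for t, c in zip(trials, picks)]


def generate_now_tomorrow_trials(
    participant: SyntheticParticipant,
    n_trials: int = 150,
    value_range: tuple[float, float] = (2.0, 10.0),
    seed: int = 0,
) -> list[NowTomorrowTrial]:
    """Offers bundling one reward and one effort item.

    Reward values and effort costs are drawn from the same uniform
    distribution (in euros) and realized as integer quantities of items
    from the participant's rated sets.
    """
    rng = np.random.default_rng(seed)
    r_items = list(participant.unit_values["reward"].values())
    e_items = list(participant.unit_values["effort"].values())
    out = []
    for _ in range(n_trials):
        rv = rng.uniform(*value_range)
        ev = rng.uniform(*value_range)
        r_unit = r_items[rng.integers(len(r_items))]
        e_unit = e_items[rng.integers(len(e_items))]
        n_r = max(1, round(rv / r_unit))
        n_e = max(1, round(ev / e_unit))
        out.append(
            NowTomorrowTrial(
                participant_id=participant.id,
                n_reward=n_r, reward_unit_value=r_unit,
                n_effort=n_e, effort_unit_value=e_unit,
            )
        )
    return out


def simulate_now_tomorrow_choices(
    trials: list[NowTomorrowTrial],
    params: DiscountParams,
    seed: int = 0,
) -> list[NowTomorrowTrial]:
    """Draw now/tomorrow picks from the net-value softmax."""
    from .choice_models import now_tomorrow_probs

    rng = np.random.default_rng(seed)
    p = now_tomorrow_probs(trials, params.k_R, params.k_E, params.theta)
    picks = (rng.random(len(trials)) < p).astype(int)
    return [replace(t, chose_tomorrow=int(c)) for t, c in zip(trials, picks)]


def _task_for(
    participant: SyntheticParticipant, theta: float, normalization: str = "none"
) -> ProcrastinationTask:
    # Simulation operates on raw task values: theta is stated on the raw
    # a.u. scale.  (Normalization is a fitting device for sharing theta
    # across participants and is absorbed into theta here anyway.)
    return ProcrastinationTask(
        R=participant.compensation, E=participant.form_cost,
        deadline=participant.deadline,
        k_R=participant.true_params.k_R, k_E=participant.true_params.k_E,
        theta=theta, normalization=normalization,
    )


def simulate_form_delays(
    participants: list[SyntheticParticipant],
    model: str = "dynamic",
    theta: float = 0.5,
    seed: int = 0,
    normalization: str = "none",
) -> np.ndarray:
    """Per-participant form-return delay in days, in [0, deadline].

    dynamic
        A draw from each participant's dynamic completion distribution.
    static
        The deterministic argmax day of the net-value curve.
    static_softmax
        A draw from the softmax readout over days.
    """
    rng = np.random.default_rng(seed)
    delays = np.empty(len(participants))
    for i, part in enumerate(participants):
        task = _task_for(part, theta, normalization)
        if model == "dynamic":
            dist = dynamic_completion_distribution(task)
            delays[i] = rng.choice(task.days, p=dist.pmf)
        elif model == "static":
            delays[i] = static_optimal_delay(task, mode="argmax")
        elif model == "static_softmax":
            dist = static_softmax_distribution(task)
            delays[i] = rng.choice(task.days, p=dist.pmf)
        else:
            raise ValueError(f"unknown model {model!r}")
    return delays
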
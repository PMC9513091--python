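"""Trial-level likelihoods for intertemporal and now/tomorrow choices.

The intertemporal task offers a sooner/lower against a later/greater
quantity of one item; the now/tomorrow task offers a bundle of one reward
and one effort item to be taken either today (D = 0) or tomorrow (D = 1).
Both are scored with Bernoulli log-likelihoods whose probabilities come
from the softmax over (signed) discounted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .discounting import (
    AVERSIVE_CATEGORIES,
    DiscountParams,
    Option,
    choice_probability,
)

__all__ = [
    "ChoiceTrial",
    "NowTomorrowTrial",
    "TrialArrays",
    "intertemporal_probs",
    "intertemporal_loglik",
    "now_tomorrow_net_value",
    "now_tomorrow_probs",
    "now_tomorrow_loglik",
    "procrastination_level",
]

#: Floor applied to Bernoulli probabilities so log-likelihoods stay finite
#: under extreme inverse temperatures.
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class ChoiceTrial:
    """One intertemporal choice between two dated quantities of one item."""

    participant_id: str
    category: str
    option_sooner: Option
    option_later: Option
    chose_later: int | None = None

    def __post_init__(self) -> None:
        s, l = self.option_sooner, self.option_later
        if s.delay == l.delay and s.quantity == l.quantity:
            raise ValueError("options must differ in delay or quantity")


@dataclass(frozen=True)
class NowTomorrowTrial:
    """One now/tomorrow offer: a reward and an effort bundled together."""

    participant_id: str
    n_reward: float
    reward_unit_value: float
    n_effort: float
    effort_unit_value: float
    chose_tomorrow: int | None = None

    def __post_init__(self) -> None:
        if self.n_reward <= 0 or self.n_effort <= 0:
            raise ValueError("quantities must be positive")


class TrialArrays:
    """Column-major view of a list of intertemporal trials.

    Fitting evaluates the likelihood thousands of times; converting the
    trial objects to flat arrays once makes each evaluation a handful of
    vectorized operations.
    """

    def __init__(self, trials: list[ChoiceTrial]):
        if not trials:
            raise ValueError("empty trial list")
        self.n = len(trials)
        self.amount_s = np.array([t.option_sooner.amount for t in trials])
        self.amount_l = np.array([t.option_later.amount for t in trials])
        self.delay_s = np.array([t.option_sooner.delay for t in trials], float)
        self.delay_l = np.array([t.option_later.delay for t in trials], float)
        self.category = np.array([t.category for t in trials])
        self.aversive = np.isin(self.category, AVERSIVE_CATEGORIES)
        picks = [t.chose_later for t in trials]
        self.chose_later = (
            None if any(p is None for p in picks) else np.array(picks, float)
        )
        self.max_delay = float(max(self.delay_s.max(), self.delay_l.max()))


def _discounted(arrays: TrialArrays, params: DiscountParams, amount, delay):
    fam = params.family
    if fam in ("hyperbolic_specific", "hyperbolic_shared"):
        if fam == "hyperbolic_shared":
            k = np.full(arrays.n, params.k_R)
        else:
            k = np.where(
                arrays.category == "reward", params.k_R,
                np.where(arrays.category == "effort", params.k_E, params.k_P),
            )
        denom = 1.0 + k * delay
        if np.any(denom <= 0):
            raise ValueError("non-positive discounting denominator")
        return amount / denom
    if fam == "present_bias":
        return np.where(delay == 0, amount, params.beta * amount)
    if fam == "quasi_hyperbolic":
        return np.where(
            delay == 0, amount, params.beta * params.delta ** delay * amount
        )
    raise ValueError(f"unknown family {fam!r}")


def intertemporal_probs(arrays: TrialArrays, params: DiscountParams) -> np.ndarray:
    """Vectorized P(choose later) for every trial."""
    v_s = _discounted(arrays, params, arrays.amount_s, arrays.delay_s)
    v_l = _discounted(arrays, params, arrays.amount_l, arrays.delay_l)
    sign = np.where(arrays.aversive, -1.0, 1.0)
    return expit(params.theta * sign * (v_l - v_s))


def intertemporal_loglik(trials, params: DiscountParams) -> float:
    """Sum of Bernoulli log-probabilities of the observed picks.

    ``trials`` may be a list of :class:`ChoiceTrial` or a pre-built
    :class:`TrialArrays` (cheaper when called repeatedly).
    """
    arrays = trials if isinstance(trials, TrialArrays) else TrialArrays(trials)
    if arrays.chose_later is None:
        raise ValueError("trials carry no observed picks")
    p = np.clip(intertemporal_probs(arrays, params), PROB_CLIP, 1 - PROB_CLIP)
    y = arrays.chose_later
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def now_tomorrow_net_value(
    trial: NowTomorrowTrial, k_R: float, k_E: float, D: int
) -> float:
    """Net value of taking the offer at delay D (0 = now, 1 = tomorrow).

    Discounted benefit minus discounted cost; the same one-day delay applies
    to both components (task completion and payoff are effectively
    simultaneous at this time scale).
    """
    if D not in (0, 1):
        raise ValueError(f"delay must be 0 or 1, got {D}")
    gain = trial.n_reward * trial.reward_unit_value / (1.0 + k_R * D)
    cost = trial.n_effort * trial.effort_unit_value / (1.0 + k_E * D)
    return gain - cost


def now_tomorrow_probs(trials, k_R: float, k_E: float, theta: float) -> np.ndarray:
    """Vectorized P(choose tomorrow) under rigidly supplied discount rates."""
    gain = np.array([t.n_reward * t.reward_unit_value for t in trials])
    cost = np.array([t.n_effort * t.effort_unit_value for t in trials])
    v_now = gain - cost
    v_tom = gain / (1.0 + k_R) - cost / (1.0 + k_E)
    return expit(theta * (v_tom - v_now))


def now_tomorrow_loglik(trials, k_R: float, k_E: float, theta: float) -> float:
    """Log-likelihood of observed now/tomorrow picks.

    The discount rates are *rigid inputs* inferred elsewhere (intertemporal
    choices or neural estimates); the inverse temperature is the only free
    parameter, so it can tune stochasticity but never the mean preference.
    """
    if not trials:
        raise ValueError("empty trial list")
    picks = [t.chose_tomorrow for t in trials]
    if any(p is None for p in picks):
        raise ValueError("trials carry no observed picks")
    y = np.array(picks, float)
    p = np.clip(now_tomorrow_probs(trials, k_R, k_E, theta), PROB_CLIP, 1 - PROB_CLIP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def procrastination_level(trials) -> float:
    """Selection frequency of the 'tomorrow' option, in [0, 1]."""
    if not trials:
        raise ValueError("empty trial list")
    picks = [t.chose_tomorrow for t in trials]
    if any(p is None for p in picks):
        raise ValueError("trials carry no observed picks")
    return float(np.mean(picks))
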
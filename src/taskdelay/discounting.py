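"""Delay-discounting functions and the softmax choice rule.

These are the valuation kernels used throughout the package: hyperbolic
discounting ``V = A / (1 + k·D)``, the present-bias and quasi-hyperbolic
(beta-delta) alternatives, and the logistic (softmax) mapping from value
differences to choice probabilities.

Sign convention for aversive categories (effort, punishment): the discounted
cost enters the softmax negated, i.e. the desirability of an option is
``-cost``.  With a positive discount rate a later effort is *less* costly,
so its desirability is higher — delaying a cost is attractive.  This single
convention serves all three categories without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAMILIES",
    "AVERSIVE_CATEGORIES",
    "CATEGORIES",
    "Option",
    "DiscountParams",
    "hyperbolic_value",
    "present_bias_value",
    "quasi_hyperbolic_value",
    "softmax_prob",
    "discounted_value",
    "choice_probability",
]

#: Model families for intertemporal choice.
FAMILIES = (
    "hyperbolic_specific",   # one hyperbolic rate per category (k_R, k_E, k_P)
    "hyperbolic_shared",     # a single hyperbolic rate for all categories
    "present_bias",          # beta applied to any non-immediate outcome
    "quasi_hyperbolic",      # beta * delta**D (the "beta-delta" model)
)

CATEGORIES = ("reward", "effort", "punishment")
AVERSIVE_CATEGORIES = ("effort", "punishment")


@dataclass(frozen=True)
class Option:
    """One side of an intertemporal offer.

    quantity
        Number of units on offer (N).
    unit_value
        Subjective value of one unit, in euros (R_i for rewards, the loss
        equivalent E_j for efforts/punishments).  Always positive; the
        aversive sign is handled by the choice rule, not stored here.
    delay
        Days until delivery (reward) or until the completion deadline
        (effort/punishment).
    """

    quantity: float
    unit_value: float
    delay: float
    category: str = "reward"

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def amount(self) -> float:
        """Undiscounted magnitude N x unit_value, in euros."""
        return self.quantity * self.unit_value


@dataclass
class DiscountParams:
    """Per-participant discounting parameters with a model-family tag.

    Only the parameters active in ``family`` are interpreted; the rest are
    carried along untouched (convenient for serialization).  For
    ``hyperbolic_shared`` the single shared rate is stored in ``k_R``.
    """

    k_R: float = 0.05
    k_E: float = 0.10
    k_P: float = 0.07
    theta: float = 1.0
    beta: float = 1.0
    delta: float = 1.0
    family: str = "hyperbolic_specific"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")

    def rate_for(self, category: str) -> float:
        """The hyperbolic rate active for ``category`` under this family."""
        if self.family == "hyperbolic_shared":
            return self.k_R
        if self.family == "hyperbolic_specific":
            try:
                return {"reward": self.k_R, "effort": self.k_E,
                        "punishment": self.k_P}[category]
            except KeyError:
                raise ValueError(f"unknown category {category!r}") from None
        raise ValueError(
            f"family {self.family!r} has no per-category hyperbolic rate"
        )


def hyperbolic_value(option: Option, k: float) -> float:
    """Hyperbolically discounted magnitude N·R / (1 + k·D).

    ``k`` is the per-day discount rate.  Mildly negative rates are admitted
    (observed when people prefer to expedite dated aversive events) as long
    as the denominator stays positive for this option's delay.
    """
    denom = 1.0 + k * option.delay
    if denom <= 0:
        raise ValueError(
            f"non-positive discounting denominator: 1 + {k}*{option.delay}"
        )
    return option.amount / denom


def present_bias_value(option: Option, beta: float) -> float:
    """Present-bias value: N·R if D == 0, else beta·N·R."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if option.delay == 0:
        return option.amount
    return beta * option.amount


def quasi_hyperbolic_value(option: Option, beta: float, delta: float) -> float:
    """Quasi-hyperbolic (beta-delta) value: N·R if D == 0, else beta·delta^D·N·R."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    if option.delay == 0:
        return option.amount
    return beta * delta ** option.delay * option.amount


def softmax_prob(v_a, v_b, theta: float):
    """P(choose A) = 1 / (1 + exp(-theta·(V_A − V_B))).

    Overflow-safe: returns the 0/1 limits for extreme arguments instead of
    NaN.  Accepts scalars or arrays (broadcast).
    """
    if np.any(np.asarray(theta) < 0):
        raise ValueError("theta must be >= 0")
    x = np.multiply(theta, np.subtract(v_a, v_b))
    # scipy.special.expit is overflow-safe
    from scipy.special import expit

    out = expit(x)
    if np.isscalar(v_a) and np.isscalar(v_b):
        return float(out)
    return out


def discounted_value(option: Option, params: DiscountParams) -> float:
    """Discounted magnitude of ``option`` under the family in ``params``.

    Always positive: this is a value for rewards and a cost for aversive
    categories.  The sign flip happens in :func:`choice_probability`.
    """
    if params.family in ("hyperbolic_specific", "hyperbolic_shared"):
        return hyperbolic_value(option, params.rate_for(option.category))
    if params.family == "present_bias":
        return present_bias_value(option, params.beta)
    if params.family == "quasi_hyperbolic":
        return quasi_hyperbolic_value(option, params.beta, params.delta)
    raise ValueError(f"unknown family {params.family!r}")


def desirability(option: Option, params: DiscountParams) -> float:
    """Signed decision value: +discounted value (reward) or −discounted cost."""
    v = discounted_value(option, params)
    return -v if option.category in AVERSIVE_CATEGORIES else v


def choice_probability(trial, params: DiscountParams) -> float:
    """Probability of choosing the *later* option of an intertemporal trial.

    ``trial`` must expose ``option_sooner`` and ``option_later``
    (see :class:`taskdelay.choice_models.ChoiceTrial`).
    """
    d_later = desirability(trial.option_later, params)
    d_sooner = desirability(trial.option_sooner, params)
    return softmax_prob(d_later, d_sooner, params.theta)
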
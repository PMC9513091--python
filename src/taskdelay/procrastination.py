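"""Static and dynamic models of recurrent task-completion delay.

A person must complete an effortful task (reward R, subjective effort cost
E) at some integer day d in 0..D before a deadline D.  The net value of
completing it after a further delay d is

    V_d = R / (1 + k_R * d)  -  E / (1 + k_E * d)

With a steeper discount rate for effort than for reward (k_E > k_R) the
cost shrinks with delay faster than the benefit, so V_d can peak at d > 0:
doing the task later genuinely looks better from today's standpoint.

The *static* model picks the completion day once, as the argmax of V_d (or
a softmax readout over days).  The *dynamic* model revisits the decision
every day with a shrinking horizon: on each day the agent compares doing
the task now (V_0, values re-discounted from the current day) against every
remaining day, via a softmax.  As the deadline approaches the comparison
set shrinks, the hazard of completing rises, and on the last day it is 1 —
the model's account of the deadline effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax as _softmax

__all__ = [
    "ProcrastinationTask",
    "CompletionDistribution",
    "net_value_curve",
    "static_optimal_delay",
    "static_softmax_distribution",
    "dynamic_daily_prob",
    "dynamic_completion_distribution",
    "delay_loglik",
    "simulate_agents",
    "simulate_duration_grid",
]


@dataclass(frozen=True)
class ProcrastinationTask:
    """One task-completion problem: values, rates and a deadline.

    R and E are in euros (or arbitrary units, as long as theta is scaled to
    match).  ``decisions_per_day`` generalizes the one-decision-per-day
    assumption: the day grid is subdivided accordingly.  Default 1.
    """

    R: float
    E: float
    deadline: int
    k_R: float
    k_E: float
    theta: float = 0.5
    decisions_per_day: int = 1
    normalization: str = "max_abs"  # max_abs | zscore | none

    def __post_init__(self) -> None:
        if self.deadline < 1 or int(self.deadline) != self.deadline:
            raise ValueError("deadline must be a positive integer number of days")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.decisions_per_day < 1:
            raise ValueError("decisions_per_day must be >= 1")
        if self.normalization not in ("max_abs", "zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for k in (self.k_R, self.k_E):
            if 1.0 + k * self.deadline <= 0:
                raise ValueError(
                    f"discount rate {k} makes the denominator non-positive "
                    f"within the {self.deadline}-day horizon"
                )

    @property
    def days(self) -> np.ndarray:
        """Decision-time grid in days: integers 0..D at one decision per day,
        subdivided when ``decisions_per_day`` > 1."""
        n_steps = self.deadline * self.decisions_per_day
        return np.arange(n_steps + 1) / self.decisions_per_day

    @property
    def n_steps(self) -> int:
        return self.deadline * self.decisions_per_day


@dataclass(frozen=True)
class CompletionDistribution:
    """Completion-time distribution of a procrastination model.

    daily_prob[d]
        Hazard: P(complete on day d | not yet completed).  1 at the deadline.
    pmf[d], cdf[d]
        Unconditional completion probabilities; cdf[D] == 1.
    expected_delay
        E[tau] = sum d * pmf[d] — the model's predicted procrastination
        duration in days.
    """

    daily_prob: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray
    expected_delay: float


def net_value_curve(task: ProcrastinationTask) -> np.ndarray:
    """V_d = R/(1+k_R·d) − E/(1+k_E·d) over the decision grid (length D+1
    at the default one decision per day)."""
    d = task.days
    return task.R / (1.0 + task.k_R * d) - task.E / (1.0 + task.k_E * d)


def _normalized_curve(task: ProcrastinationTask) -> np.ndarray:
    """Net-value curve rescaled to a comparable range across people.

    Individual R and E spans differ widely; dividing by the largest
    absolute net value over the horizon (default) keeps a single theta
    meaningful across participants.  The curve's shape and argmax are
    unchanged.
    """
    v = net_value_curve(task)
    if task.normalization == "max_abs":
        scale = np.max(np.abs(v))
        return v / scale if scale > 0 else v
    if task.normalization == "zscore":
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()
    return v


def static_optimal_delay(
    task: ProcrastinationTask, mode: str = "argmax", seed: int | None = None
):
    """Completion day under the static (pre-commitment) model.

    mode="argmax"
        The earliest day maximizing V_d (deterministic; ties break early).
    mode="softmax"
        A draw from the softmax distribution over days (requires seed), or
        the distribution itself if seed is None.
    """
    if mode == "argmax":
        d = task.days[int(np.argmax(net_value_curve(task)))]
        return int(d) if task.decisions_per_day == 1 else float(d)
    if mode == "softmax":
        dist = static_softmax_distribution(task)
        if seed is None:
            return dist
        rng = np.random.default_rng(seed)
        return int(rng.choice(task.days, p=dist.pmf))
    raise ValueError(f"unknown mode {mode!r}")


def static_softmax_distribution(task: ProcrastinationTask) -> CompletionDistribution:
    """Softmax readout of the static model: P(tau = d) ∝ exp(theta·V_d)."""
    pmf = _softmax(task.theta * _normalized_curve(task))
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    surv = np.concatenate(([1.0], 1.0 - cdf[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard = np.where(surv > 0, pmf / surv, 1.0)
    hazard[-1] = 1.0
    return CompletionDistribution(hazard, pmf, cdf, float(np.sum(task.days * pmf)))


def dynamic_daily_prob(task: ProcrastinationTask, d: int) -> float:
    """Hazard of the dynamic model on day d.

    Softmax of completing now (V_0) against completing on any of the D−d
    remaining days, values re-discounted from the current day (the value
    function is time-invariant; only the horizon shrinks).  Returns 1 at
    d = D: the task cannot be postponed past the deadline.
    """
    if not 0 <= d <= task.n_steps:
        raise ValueError(f"decision step {d} outside [0, {task.n_steps}]")
    v = _normalized_curve(task)
    remaining = v[: task.n_steps - d + 1]
    p = _softmax(task.theta * remaining)
    return float(p[0])


def dynamic_completion_distribution(task: ProcrastinationTask) -> CompletionDistribution:
    """Completion-time distribution of the dynamic (iterative) model.

    pmf(d) = hazard(d) * prod_{j<d} (1 − hazard(j));
    cdf(d) = 1 − prod_{j<=d} (1 − hazard(j)); cdf(D) = 1 exactly.
    Expected delay is E[tau] = sum d·pmf(d).
    """
    hazard = np.array(
        [dynamic_daily_prob(task, d) for d in range(task.n_steps + 1)]
    )
    surv_before = np.concatenate(([1.0], np.cumprod(1.0 - hazard[:-1])))
    pmf = hazard * surv_before
    cdf = 1.0 - np.cumprod(1.0 - hazard)
    # hazard[D] == 1 makes these exact up to float rounding; pin them.
    cdf[-1] = 1.0
    pmf[-1] = surv_before[-1]
    return CompletionDistribution(
        hazard, pmf, cdf, float(np.sum(task.days * pmf))
    )


def delay_loglik(
    task: ProcrastinationTask, observed_delay: int, model: str = "dynamic"
) -> float:
    """Log-probability of an observed completion day under a model.

    Discount rates arrive rigidly inside ``task``; only theta (and the
    normalization) shape the pmf.  The static *argmax* readout is refused:
    its pmf is degenerate and cannot score off-optimum observations.
    """
    if not 0 <= observed_delay <= task.deadline:
        raise ValueError(
            f"observed delay {observed_delay} outside [0, {task.deadline}]"
        )
    step = int(round(observed_delay * task.decisions_per_day))
    if model == "dynamic":
        dist = dynamic_completion_distribution(task)
    elif model == "static_softmax":
        dist = static_softmax_distribution(task)
    elif model == "static_argmax":
        raise ValueError(
            "the argmax readout has a degenerate pmf and no likelihood; "
            "use model='static_softmax'"
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    return float(np.log(np.clip(dist.pmf[step], 1e-300, None)))


def simulate_agents(
    task: ProcrastinationTask, n_agents: int, seed: int
) -> np.ndarray:
    """Monte-Carlo completion days from day-by-day dynamic decisions.

    Each agent flips the daily hazard coin until completion; independent of
    the closed-form pmf, so it serves as an oracle for it.
    """
    rng = np.random.default_rng(seed)
    hazard = np.array(
        [dynamic_daily_prob(task, d) for d in range(task.n_steps + 1)]
    )
    delays = np.full(n_agents, float(task.deadline))
    alive = np.ones(n_agents, dtype=bool)
    for d in range(task.n_steps + 1):
        done_today = alive & (rng.random(n_agents) < hazard[d])
        delays[done_today] = task.days[d]
        alive &= ~done_today
    return delays


def simulate_duration_grid(
    k_R_range: tuple[float, float] = (0.0, 0.5),
    k_E_range: tuple[float, float] = (0.0, 0.5),
    R_range: tuple[float, float] = (40.0, 60.0),
    E_range: tuple[float, float] = (20.0, 40.0),
    theta: float = 0.5,
    deadline: int = 30,
    model: str = "dynamic",
    n_grid: int = 50,
    n_samples: int = 400,
    seed: int = 0,
    normalization: str = "none",
):
    """Mean expected delay over the (k_R, k_E) plane, marginalizing R and E.

    For each cell of an ``n_grid`` x ``n_grid`` grid of discount-rate pairs,
    ``n_samples`` (R, E) pairs are drawn uniformly from their ranges and the
    model's expected delay computed; the cell stores the mean.  theta applies
    to the raw (unnormalized) net values by default, matching how it is
    stated for these simulation conditions.  Defaults
    reproduce the canonical simulation design (10^6 evaluations: 50x50x400,
    30-day deadline, theta = 0.5, R in 40-60, E in 20-40 a.u.).

    Returns (k_R_values, k_E_values, grid) with grid[i, j] the mean duration
    at k_R_values[i], k_E_values[j].
    """
    if n_samples < 1 or n_grid < 1:
        raise ValueError("n_grid and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    k_R_vals = np.linspace(*k_R_range, n_grid)
    k_E_vals = np.linspace(*k_E_range, n_grid)
    grid = np.empty((n_grid, n_grid))
    for i, k_R in enumerate(k_R_vals):
        for j, k_E in enumerate(k_E_vals):
            R = rng.uniform(*R_range, n_samples)
            E = rng.uniform(*E_range, n_samples)
            total = 0.0
            for r, e in zip(R, E):
                task = ProcrastinationTask(
                    R=r, E=e, deadline=deadline, k_R=k_R, k_E=k_E,
                    theta=theta, normalization=normalization,
                )
                if model == "dynamic":
                    total += dynamic_completion_distribution(task).expected_delay
                elif model == "static":
                    total += static_optimal_delay(task, mode="argmax")
                elif model == "static_softmax":
                    total += static_softmax_distribution(task).expected_delay
                else:
                    raise ValueError(f"unknown model {model!r}")
            grid[i, j] = total / n_samples
    return k_R_vals, k_E_vals, grid
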
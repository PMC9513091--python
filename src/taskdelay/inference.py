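"""MAP estimation, Laplace-approximated model evidence, and fit diagnostics.

Models are scored by their log evidence, approximated at the posterior mode
(Laplace):

    log p(y) ~= log p(y|x*) + log p(x*) + (p/2)·log 2*pi − 0.5·log det H

with x* the MAP estimate and H the Hessian of the negative log joint at
x*.  The evidence trades goodness of fit against complexity: an inert
extra parameter buys no likelihood but pays a determinant/prior price.

Bounded parameters are optimized on an unconstrained transformed scale
(log for positive parameters, logit for unit-interval ones); their priors,
stated on the native scale, are mapped through the transform with the
Jacobian correction, so the Laplace integral is over a well-defined density
on the fitting scale.  Unbounded parameters (the hyperbolic rates) keep
their literal Gaussian priors, with box bounds guarding the discounting
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm

from .choice_models import (
    TrialArrays,
    intertemporal_loglik,
    intertemporal_probs,
    now_tomorrow_loglik,
)
from .discounting import DiscountParams

__all__ = [
    "ParamSpec",
    "PriorSpec",
    "FitResult",
    "fit_map",
    "log_evidence",
    "compare_models",
    "balanced_accuracy",
    "calibration_bins",
    "fit_intertemporal",
    "fit_now_tomorrow",
    "fit_delay_model",
    "default_priors",
]


@dataclass(frozen=True)
class ParamSpec:
    """Prior and transform for one scalar parameter.

    mean, sd
        Gaussian prior on the *native* scale.
    transform
        "identity", "log" or "logit" — the scale on which the optimizer
        works.  The prior density is pushed through the transform (with the
        log-Jacobian term), so it remains the stated native-scale prior.
    bounds
        Optional native-scale box constraints (identity transform only).
    """

    name: str
    mean: float
    sd: float
    transform: str = "identity"
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"prior sd for {self.name!r} must be > 0")
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")

    # --- native <-> fitting scale -------------------------------------
    def to_native(self, z: float) -> float:
        if self.transform == "log":
            return float(np.exp(np.clip(z, -700, 700)))
        if self.transform == "logit":
            return float(expit(z))
        return z

    def to_fitting(self, x: float) -> float:
        if self.transform == "log":
            return math.log(x)
        if self.transform == "logit":
            return float(logit(x))
        return x

    def log_prior(self, z: float) -> float:
        """Log prior density *on the fitting scale* at z."""
        x = self.to_native(z)
        with np.errstate(over="ignore"):
            lp = norm.logpdf(x, self.mean, self.sd)
        if self.transform == "log":
            lp += z  # |dx/dz| = e^z
        elif self.transform == "logit":
            p = expit(z)
            lp += math.log(max(p * (1 - p), 1e-300))
        return float(lp)


@dataclass(frozen=True)
class PriorSpec:
    """Ordered collection of :class:`ParamSpec` defining a model's parameters."""

    params: tuple[ParamSpec, ...]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def to_native(self, z: np.ndarray) -> dict[str, float]:
        return {p.name: p.to_native(zi) for p, zi in zip(self.params, z)}

    def to_fitting(self, x: dict[str, float]) -> np.ndarray:
        return np.array([p.to_fitting(x[p.name]) for p in self.params])

    def log_prior(self, z: np.ndarray) -> float:
        return sum(p.log_prior(zi) for p, zi in zip(self.params, z))


@dataclass
class FitResult:
    """Outcome of one MAP fit."""

    params: dict[str, float]          # native scale
    loglik: float                     # data log-likelihood at the MAP
    log_evidence: float               # Laplace approximation
    log_joint: float                  # loglik + log prior (fitting scale)
    hessian: np.ndarray | None
    converged: bool
    flags: list[str] = field(default_factory=list)
    n_params: int = 0


def _finite_diff_hessian(f, z: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate adaptive step."""
    p = len(z)
    h = rel_step * np.maximum(np.abs(z), 1.0)
    H = np.empty((p, p))
    f0 = f(z)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(z + ei) - 2 * f0 + f(z - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_map(
    loglik_fn,
    priors: PriorSpec,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Multi-start MAP estimation with a Laplace evidence.

    loglik_fn
        Maps a dict of native-scale parameters to a log-likelihood.  May
        return -inf outside its domain.
    n_restarts
        Number of starts: the prior mean first, then draws from the prior.
        The best converged optimum wins.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = len(priors.params)

    def neg_log_joint(z: np.ndarray) -> float:
        lp = priors.log_prior(z)
        ll = loglik_fn(priors.to_native(z))
        if not np.isfinite(ll) or not np.isfinite(lp):
            return 1e12
        return -(ll + lp)

    # native-scale box bounds mapped to the fitting scale
    bounds = []
    for ps in priors.params:
        lo, hi = ps.bounds
        if ps.transform != "identity":
            bounds.append((None, None))
        else:
            bounds.append((lo, hi))

    starts = [np.array([ps.to_fitting(ps.mean) if ps.transform == "identity"
                        else 0.0 for ps in priors.params])]
    for _ in range(max(0, n_restarts - 1)):
        z0 = []
        for ps in priors.params:
            draw = rng.normal(ps.mean, ps.sd)
            lo, hi = ps.bounds
            if ps.transform == "identity":
                if lo is not None:
                    draw = max(draw, lo + 1e-6)
                if hi is not None:
                    draw = min(draw, hi - 1e-6)
                z0.append(draw)
            elif ps.transform == "log":
                z0.append(math.log(max(draw, 1e-3)))
            else:  # logit
                z0.append(float(logit(min(max(draw, 1e-3), 1 - 1e-3))))
        starts.append(np.array(z0))

    best = None
    any_converged = False
    for z0 in starts:
        res = optimize.minimize(
            neg_log_joint, z0, method="L-BFGS-B", bounds=bounds,
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    flags: list[str] = []
    if not any_converged:
        flags.append("no_restart_converged")

    z_map = np.asarray(best.x, float)
    native = priors.to_native(z_map)
    ll = float(loglik_fn(native))
    log_joint = -float(best.fun)

    if p > 0:
        H = _finite_diff_hessian(neg_log_joint, z_map)
        evidence, ev_flags = _laplace_evidence(log_joint, H)
        flags += ev_flags
    else:
        H = None
        evidence = ll
    return FitResult(
        params=native,
        loglik=ll,
        log_evidence=evidence,
        log_joint=log_joint,
        hessian=H,
        converged=any_converged,
        flags=flags,
        n_params=p,
    )


def _laplace_evidence(log_joint: float, H: np.ndarray) -> tuple[float, list[str]]:
    flags: list[str] = []
    p = H.shape[0]
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        # jitter-regularize a non-PD numerical Hessian
        jitter = 1e-6 * max(1.0, float(np.abs(np.diag(H)).max()))
        for _ in range(12):
            sign, logdet = np.linalg.slogdet(H + jitter * np.eye(p))
            if sign > 0 and np.isfinite(logdet):
                break
            jitter *= 10
        flags.append("hessian_regularized")
    return log_joint + 0.5 * p * math.log(2 * math.pi) - 0.5 * logdet, flags


def log_evidence(fit: FitResult) -> float:
    """Laplace log model evidence of a fit (zero-parameter models: the
    log-likelihood itself)."""
    return fit.log_evidence


def compare_models(fits: dict[str, dict]) -> dict:
    """Group-level model comparison across families.

    fits
        ``{family: {participant_id: FitResult}}``; every family must cover
        the same participant set (same data per participant).

    Returns a dict with per-family summed log evidence and the matrix of
    pairwise log group Bayes factors (row minus column).
    """
    families = list(fits)
    pid_sets = [frozenset(fits[f]) for f in families]
    if len(set(pid_sets)) != 1:
        raise ValueError("participant sets differ across families")
    total = {
        f: float(sum(r.log_evidence for r in fits[f].values())) for f in families
    }
    log_bf = {
        a: {b: total[a] - total[b] for b in families} for a in families
    }
    best = max(total, key=total.get)
    return {"total_log_evidence": total, "log_group_bayes_factor": log_bf,
            "best_family": best}


def balanced_accuracy(predicted_probs, choices) -> float:
    """Mean of per-class accuracies at a 0.5 threshold.

    A predicted probability of exactly 0.5 counts as half correct for
    either class (unbiased under chance).  If only one class is present the
    single-class accuracy is returned.
    """
    p = np.asarray(predicted_probs, float)
    y = np.asarray(choices, float)
    if p.size == 0:
        raise ValueError("empty input")
    correct = np.where(p == 0.5, 0.5, ((p > 0.5) == (y == 1)).astype(float))
    accs = [float(correct[y == c].mean()) for c in (0, 1) if np.any(y == c)]
    return float(np.mean(accs))


def calibration_bins(predicted_probs, choices, n_bins: int = 8):
    """Per-bin (mean modeled, mean observed) over equal-count probability bins.

    Trials are ranked by modeled probability and split into ``n_bins``
    near-equal-count bins.  With fewer trials than bins, every trial gets
    its own bin.  Returns (mean_modeled, mean_observed, counts).
    """
    p = np.asarray(predicted_probs, float)
    y = np.asarray(choices, float)
    if p.size == 0:
        raise ValueError("empty input")
    n_bins = min(n_bins, p.size)
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_bins)
    modeled = np.array([p[s].mean() for s in splits])
    observed = np.array([y[s].mean() for s in splits])
    counts = np.array([len(s) for s in splits])
    return modeled, observed, counts


# --------------------------------------------------------------------------
# convenience fitting front-ends for this package's models
# --------------------------------------------------------------------------

#: guard for the hyperbolic denominator: k > -1/D_max + margin
_K_MARGIN = 1e-3


def default_priors(
    family: str,
    categories: tuple[str, ...] = ("reward", "effort", "punishment"),
    max_delay: float = 30.0,
) -> PriorSpec:
    """Default priors per model family.

    Hyperbolic rates: N(0, 1) on the native scale (bounded below by the
    denominator guard).  Inverse temperature: N(1, 1) native, fitted on the
    log scale.  beta, delta: N(0, 1) mapped from the logit scale (i.e.,
    centered mid-interval), mirroring the rate priors after transformation.
    """
    k_lo = -1.0 / max_delay + _K_MARGIN
    specs: list[ParamSpec] = []
    if family == "hyperbolic_specific":
        key = {"reward": "k_R", "effort": "k_E", "punishment": "k_P"}
        for c in categories:
            specs.append(ParamSpec(key[c], 0.0, 1.0, "identity", (k_lo, None)))
    elif family == "hyperbolic_shared":
        specs.append(ParamSpec("k", 0.0, 1.0, "identity", (k_lo, None)))
    elif family == "present_bias":
        specs.append(ParamSpec("beta", 0.5, 1.0, "logit"))
    elif family == "quasi_hyperbolic":
        specs.append(ParamSpec("beta", 0.5, 1.0, "logit"))
        specs.append(ParamSpec("delta", 0.5, 1.0, "logit"))
    else:
        raise ValueError(f"unknown family {family!r}")
    specs.append(ParamSpec("theta", 1.0, 1.0, "log"))
    return PriorSpec(tuple(specs))


def _params_from_dict(x: dict[str, float], family: str) -> DiscountParams:
    kw = dict(family=family)
    if family == "hyperbolic_shared":
        kw["k_R"] = x["k"]
    else:
        for name in ("k_R", "k_E", "k_P", "beta", "delta"):
            if name in x:
                kw[name] = x[name]
    kw["theta"] = x.get("theta", 1.0)
    return DiscountParams(**kw)


def fit_intertemporal(
    trials,
    family: str = "hyperbolic_specific",
    priors: PriorSpec | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit one participant's intertemporal choices under a model family."""
    arrays = trials if isinstance(trials, TrialArrays) else TrialArrays(trials)
    cats = tuple(c for c in ("reward", "effort", "punishment")
                 if np.any(arrays.category == c))
    if priors is None:
        priors = default_priors(family, cats, max_delay=max(arrays.max_delay, 1.0))

    def ll(x: dict[str, float]) -> float:
        try:
            return intertemporal_loglik(arrays, _params_from_dict(x, family))
        except ValueError:
            return -np.inf

    fit = fit_map(ll, priors, n_restarts=n_restarts, seed=seed)
    fit.params["family"] = family
    return fit


def fit_now_tomorrow(
    trials,
    k_R: float,
    k_E: float,
    priors: PriorSpec | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit the inverse temperature of the now/tomorrow model.

    The discount rates are rigidly incorporated — theta is the single free
    parameter and cannot shift the mean preference, only its stochasticity.
    """
    if priors is None:
        priors = PriorSpec((ParamSpec("theta", 1.0, 1.0, "log"),))

    def ll(x: dict[str, float]) -> float:
        return now_tomorrow_loglik(trials, k_R, k_E, x["theta"])

    return fit_map(ll, priors, n_restarts=n_restarts, seed=seed)


def fit_delay_model(
    task_builder,
    observed_delay: int,
    model: str = "dynamic",
    priors: PriorSpec | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit theta of a home-task delay model to one observed delay.

    task_builder
        Callable theta -> ProcrastinationTask with that inverse temperature
        and this participant's rigid (R, E, k_R, k_E, deadline).
    """
    from .procrastination import delay_loglik

    if priors is None:
        priors = PriorSpec((ParamSpec("theta", 1.0, 1.0, "log"),))

    def ll(x: dict[str, float]) -> float:
        return delay_loglik(task_builder(x["theta"]), observed_delay, model)

    return fit_map(ll, priors, n_restarts=n_restarts, seed=seed)
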
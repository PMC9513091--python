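"""Regression layer: per-participant choice factors and cross-participant
regressions of procrastination on time preferences.

Per-participant logistic regressions quantify the weight of value/cost and
delay differences on intertemporal choices, and of reward value and effort
cost on now/tomorrow choices; coefficients are then tested against zero
across participants with one-sample t tests.  Cross-participant OLS
regresses a procrastination measure (tomorrow-choice frequency in the lab,
or form-return delay at home) on discount-rate estimates plus age and
gender.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .choice_models import ChoiceTrial, NowTomorrowTrial
from .discounting import AVERSIVE_CATEGORIES

__all__ = [
    "ParticipantSummary",
    "intertemporal_design",
    "now_tomorrow_design",
    "logistic_choice_factors",
    "regress_procrastination",
    "measure_correlations",
]


@dataclass(frozen=True)
class ParticipantSummary:
    """Cross-participant analysis row.

    form_delay is None for participants who never returned the forms; they
    are excluded from home-outcome regressions.
    """

    id: str
    k_R: float
    k_E: float
    k_P: float | None
    procrastination_level: float
    form_delay: float | None
    age: float
    gender: int
    questionnaire_score: float | None = None


def intertemporal_design(trials: list[ChoiceTrial]) -> pd.DataFrame:
    """Per-trial regressors for the intertemporal logistic model.

    dv_value: later minus sooner undiscounted value (euros); for aversive
    categories this is a cost difference.  dv_delay: later minus sooner
    delay (days).  y: chose_later.
    """
    rows = []
    for t in trials:
        rows.append(
            {
                "participant_id": t.participant_id,
                "category": t.category,
                "dv_value": t.option_later.amount - t.option_sooner.amount,
                "dv_delay": t.option_later.delay - t.option_sooner.delay,
                "y": t.chose_later,
            }
        )
    return pd.DataFrame(rows)


def now_tomorrow_design(trials: list[NowTomorrowTrial]) -> pd.DataFrame:
    """Per-trial regressors for the now/tomorrow logistic model."""
    rows = []
    for t in trials:
        rv = t.n_reward * t.reward_unit_value
        ec = t.n_effort * t.effort_unit_value
        rows.append(
            {
                "participant_id": t.participant_id,
                "reward_value": rv,
                "effort_cost": ec,
                "net_value": rv - ec,
                "y": t.chose_tomorrow,
            }
        )
    return pd.DataFrame(rows)


def _logistic_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """ML logistic fit; falls back to a small-ridge fit under separation."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 50:
            return np.asarray(res.params), False
    except Exception:
        pass
    res = sm.Logit(y, Xc).fit_regularized(
        method="l1", alpha=np.r_[0.0, np.full(X.shape[1], 1e-3)],
        disp=0, maxiter=500,
    )
    return np.asarray(res.params), True


def logistic_choice_factors(
    design: pd.DataFrame,
    factors: list[str],
    standardize: bool = True,
) -> dict:
    """Per-participant logistic coefficients and group-level t statistics.

    design
        Long-format table with columns ``participant_id``, ``y`` and the
        factor columns (see :func:`intertemporal_design` /
        :func:`now_tomorrow_design`).
    standardize
        z-score each factor within participant so coefficients are
        comparable across value scales.

    Returns ``{"coefficients": DataFrame (participant x factor),
    "group": DataFrame with mean beta, t, p per factor, "flagged": [...]}``.
    """
    missing = [f for f in factors if f not in design.columns]
    if missing:
        raise ValueError(f"unknown factors: {missing}")
    coef_rows = {}
    flagged = []
    for pid, sub in design.groupby("participant_id", sort=True):
        X = sub[factors].to_numpy(float)
        if standardize:
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        params, was_ridge = _logistic_fit(X, sub["y"].to_numpy(float))
        if was_ridge:
            flagged.append(pid)
        coef_rows[pid] = dict(zip(["intercept"] + factors, params))
    coefs = pd.DataFrame.from_dict(coef_rows, orient="index")
    group = []
    for f in factors:
        t, p = stats.ttest_1samp(coefs[f], 0.0)
        group.append({"factor": f, "beta_mean": coefs[f].mean(),
                      "t": float(t), "p": float(p), "df": len(coefs) - 1})
    return {
        "coefficients": coefs,
        "group": pd.DataFrame(group).set_index("factor"),
        "flagged": flagged,
    }


def regress_procrastination(
    summaries: list[ParticipantSummary] | pd.DataFrame,
    outcome: str = "lab",
    log_rates: bool = True,
) -> dict:
    """Cross-participant OLS of a procrastination measure on time preferences.

    outcome="lab"
        Tomorrow-choice frequency.
    outcome="home"
        Form-return delay in days; never-returners (missing delay) are
        excluded.

    Predictors: discount rates (log scale by default, given their right
    skew), age (centered) and gender, all z-scored, so coefficients are
    standardized effect sizes.  Raises on rank deficiency, naming the
    collinear columns.
    """
    df = (
        summaries
        if isinstance(summaries, pd.DataFrame)
        else pd.DataFrame([vars(s) for s in summaries])
    )
    if outcome == "lab":
        y = df["procrastination_level"].to_numpy(float)
        keep = np.ones(len(df), bool)
    elif outcome == "home":
        keep = df["form_delay"].notna().to_numpy()
        y = df.loc[keep, "form_delay"].to_numpy(float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    sub = df.loc[keep]
    cols = {}
    for k in ("k_R", "k_E", "k_P"):
        if k in sub.columns and sub[k].notna().all():
            vals = sub[k].to_numpy(float)
            cols[k] = np.log(vals) if log_rates else vals
    cols["age"] = sub["age"].to_numpy(float)
    cols["gender"] = sub["gender"].to_numpy(float)
    X = np.column_stack([v for v in cols.values()])
    sd = X.std(axis=0, ddof=0)
    zero = [name for name, s in zip(cols, sd) if s == 0]
    X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # identify offending columns by pairwise correlation
        names = list(cols)
        corr = np.corrcoef(X, rowvar=False)
        dup = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {dup or zero}")
    res = sm.OLS(y, Xc).fit()
    table = pd.DataFrame(
        {
            "beta": res.params[1:],
            "t": res.tvalues[1:],
            "p": res.pvalues[1:],
        },
        index=list(cols),
    )
    return {"table": table, "r_squared": float(res.rsquared),
            "df_resid": int(res.df_resid), "n": int(len(y))}


def measure_correlations(
    df: pd.DataFrame,
    pairs: list[tuple[str, str]],
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Pearson correlations between summary measures.

    tail
        "two-sided", or "greater"/"less" for directional tests (used when
        two measures of the same construct can only agree in one
        direction).  Rows with a missing value in either column are dropped
        pairwise; fewer than 3 complete pairs is an error.
    """
    rows = []
    for a, b in pairs:
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
        r, p = stats.pearsonr(sub[a], sub[b], alternative=tail)
        rows.append({"x": a, "y": b, "r": float(r), "p": float(p),
                     "n": len(sub), "tail": tail})
    return pd.DataFrame(rows)
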
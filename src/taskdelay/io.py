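"""CSV schemas, run configuration, and manifests.

Tabular data travel as UTF-8 CSV with declared headers; parameters and
run manifests as JSON; configuration as YAML.  Readers validate row by
row and report every offending line, not just the first.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .choice_models import ChoiceTrial, NowTomorrowTrial
from .discounting import Option
from .group_analysis import ParticipantSummary
from .valuation import ItemRating

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_config",
    "read_ratings",
    "write_ratings",
    "read_choice_trials",
    "write_choice_trials",
    "read_now_tomorrow",
    "write_now_tomorrow",
    "read_summaries",
    "write_summaries",
    "write_manifest",
]


class SchemaError(ValueError):
    """A CSV or config file failed validation; ``errors`` lists offenders."""

    def __init__(self, message: str, errors: list[str]):
        super().__init__(message + "\n" + "\n".join(errors[:20]))
        self.errors = errors


_CONFIG_KEYS = {
    "ratings_csv", "trials_csv", "now_tomorrow_csv", "summaries_csv",
    "families", "deadline", "seed", "outdir", "n_restarts",
    "unit_value_convention", "value_normalization", "log_rate_regression",
    "grid_n_grid", "grid_n_samples", "theta_home",
}


@dataclass
class RunConfig:
    """Pipeline configuration; every flagged alternative convention lives here."""

    ratings_csv: str | None = None
    trials_csv: str | None = None
    now_tomorrow_csv: str | None = None
    summaries_csv: str | None = None
    families: list[str] = field(default_factory=lambda: [
        "hyperbolic_specific", "hyperbolic_shared",
        "present_bias", "quasi_hyperbolic",
    ])
    deadline: int = 30
    seed: int = 0
    outdir: str = "out"
    n_restarts: int = 10
    unit_value_convention: str = "quantity"
    value_normalization: str = "max_abs"
    log_rate_regression: bool = True
    grid_n_grid: int = 50
    grid_n_samples: int = 400
    theta_home: float = 0.5


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(
            "unknown config keys", [f"unknown key: {k}" for k in sorted(unknown)]
        )
    cfg = RunConfig(**raw)
    for key in ("ratings_csv", "trials_csv", "now_tomorrow_csv", "summaries_csv"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise SchemaError("missing input file", [f"{key}: {p} does not exist"])
    return cfg


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns", [f"missing column: {c}" for c in missing]
        )


def _numeric(df: pd.DataFrame, cols: list[str], path) -> list[str]:
    errors = []
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        errors += [f"{path}: line {i + 2}: non-numeric {c}={df.at[i, c]!r}"
                   for i in bad]
        df[c] = coerced
    return errors


# --- ratings ---------------------------------------------------------------

RATINGS_COLUMNS = ["participant_id", "item_id", "category", "subcategory", "q1", "q5"]


def read_ratings(path: str | Path) -> list[ItemRating]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RATINGS_COLUMNS, path)
    errors = _numeric(df, ["q1", "q5"], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(ItemRating(
                str(row.participant_id), str(row.item_id), str(row.category),
                str(row.subcategory), float(row.q1), float(row.q5),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"{path}: line {i + 2}: {e}")
    if errors:
        raise SchemaError(f"{path}: invalid rows", errors)
    return out


def write_ratings(ratings: list[ItemRating], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in ratings]).to_csv(path, index=False)


# --- intertemporal trials --------------------------------------------------

TRIALS_COLUMNS = [
    "participant_id", "category",
    "quantity_sooner", "unit_value_sooner", "delay_sooner",
    "quantity_later", "unit_value_later", "delay_later", "chose_later",
]


def read_choice_trials(path: str | Path, max_delay: float | None = None):
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRIALS_COLUMNS, path)
    errors = _numeric(
        df, [c for c in TRIALS_COLUMNS if c not in ("participant_id", "category")],
        path,
    )
    out = []
    for i, row in df.iterrows():
        try:
            for d in (row.delay_sooner, row.delay_later):
                if max_delay is not None and d > max_delay:
                    raise ValueError(f"delay {d} exceeds maximum {max_delay}")
            cat = str(row.category)
            pick = row.chose_later
            out.append(ChoiceTrial(
                str(row.participant_id), cat,
                Option(row.quantity_sooner, row.unit_value_sooner,
                       row.delay_sooner, cat),
                Option(row.quantity_later, row.unit_value_later,
                       row.delay_later, cat),
                None if pd.isna(pick) else int(pick),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"{path}: line {i + 2}: {e}")
    if errors:
        raise SchemaError(f"{path}: invalid rows", errors)
    return out


def write_choice_trials(trials: list[ChoiceTrial], path: str | Path) -> None:
    rows = [
        {
            "participant_id": t.participant_id,
            "category": t.category,
            "quantity_sooner": t.option_sooner.quantity,
            "unit_value_sooner": t.option_sooner.unit_value,
            "delay_sooner": t.option_sooner.delay,
            "quantity_later": t.option_later.quantity,
            "unit_value_later": t.option_later.unit_value,
            "delay_later": t.option_later.delay,
            "chose_later": t.chose_later,
        }
        for t in trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- now/tomorrow trials ---------------------------------------------------

NOW_TOMORROW_COLUMNS = [
    "participant_id", "n_reward", "reward_unit_value",
    "n_effort", "effort_unit_value", "chose_tomorrow",
]


def read_now_tomorrow(path: str | Path) -> list[NowTomorrowTrial]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, NOW_TOMORROW_COLUMNS, path)
    errors = _numeric(
        df, [c for c in NOW_TOMORROW_COLUMNS if c != "participant_id"], path
    )
    out = []
    for i, row in df.iterrows():
        try:
            pick = row.chose_tomorrow
            out.append(NowTomorrowTrial(
                str(row.participant_id),
                float(row.n_reward), float(row.reward_unit_value),
                float(row.n_effort), float(row.effort_unit_value),
                None if pd.isna(pick) else int(pick),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"{path}: line {i + 2}: {e}")
    if errors:
        raise SchemaError(f"{path}: invalid rows", errors)
    return out


def write_now_tomorrow(trials: list[NowTomorrowTrial], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in trials]).to_csv(path, index=False)


# --- participant summaries -------------------------------------------------

SUMMARY_COLUMNS = [
    "id", "k_R", "k_E", "k_P", "procrastination_level", "form_delay",
    "age", "gender",
]


def read_summaries(path: str | Path, deadline: int = 30) -> list[ParticipantSummary]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SUMMARY_COLUMNS, path)
    errors = _numeric(df, [c for c in SUMMARY_COLUMNS if c != "id"], path)
    out = []
    for i, row in df.iterrows():
        try:
            fd = None if pd.isna(row.form_delay) else float(row.form_delay)
            if fd is not None and not (0 <= fd <= deadline):
                raise ValueError(f"form_delay {fd} outside [0, {deadline}]")
            out.append(ParticipantSummary(
                str(row.id), float(row.k_R), float(row.k_E),
                None if pd.isna(row.k_P) else float(row.k_P),
                float(row.procrastination_level), fd,
                float(row.age), int(row.gender),
                None if "questionnaire_score" not in df.columns
                or pd.isna(row.get("questionnaire_score"))
                else float(row.questionnaire_score),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"{path}: line {i + 2}: {e}")
    if errors:
        raise SchemaError(f"{path}: invalid rows", errors)
    return out


def write_summaries(summaries: list[ParticipantSummary], path: str | Path) -> None:
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(path, index=False)


# --- manifests -------------------------------------------------------------

def write_manifest(outdir: str | Path, config: dict, seed: int) -> Path:
    """JSON manifest (config hash, seed, package version) next to outputs."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    path = Path(outdir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
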
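"""Reading and writing choice datasets, session dumps, and configuration.

The canonical dataset is a long-format, comma-separated, UTF-8 table with
one row per participant x round (the schema in
:data:`cuelens.agents.CHOICE_COLUMNS`). Deposited datasets with a foreign
layout are adapted through a :class:`ColumnMap` that renames columns and
recodes values; the reader recomputes the derived predictivity statistics
from the raw flags and cross-checks them against any provided columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .agents import CHOICE_COLUMNS
from .environment import (
    OptionSpec,
    RoundKind,
    Session,
    SessionConfig,
    Trial,
)

__all__ = [
    "ColumnMap",
    "PredictivityMismatch",
    "write_dataset",
    "read_study_data",
    "session_to_frame",
    "session_to_json",
    "session_from_json",
    "load_config",
    "save_config",
]

#: Columns the analysis cannot run without (directly or by derivation).
REQUIRED_COLUMNS = (
    "participant_id",
    "condition",
    "round_index",
    "round_kind",
    "chose_cue_option",
)


class PredictivityMismatch(UserWarning):
    """Provided predictivity columns disagree with values recomputed from
    the raw cue-predictive flags."""


@dataclass(slots=True)
class ColumnMap:
    """Mapping from the canonical schema to a deposited file's layout.

    ``columns`` maps canonical names to source column names (canonical
    names absent from the map are assumed to already match). ``recode``
    maps a canonical column name to a {source value -> canonical value}
    dictionary applied after renaming, e.g. to translate condition labels.
    """

    columns: dict[str, str] = field(default_factory=dict)
    recode: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "ColumnMap":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            columns=dict(raw.get("columns", {})),
            recode={k: dict(v) for k, v in raw.get("recode", {}).items()},
        )


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical long-format choice dataset as CSV."""
    data.to_csv(path, index=False)


def _recompute_historical(data: pd.DataFrame) -> pd.Series:
    """Expanding share of past cue-predictive flags within participant,
    ordered by round index (NaN on each participant's first round)."""

    def one(group: pd.DataFrame) -> pd.Series:
        g = group.sort_values("round_index")
        h = g["cue_predictive"].expanding().mean().shift(1)
        return h.reindex(group.index)

    return (
        data.groupby("participant_id", group_keys=False, sort=False)
        .apply(one, include_groups=False)
        .astype(float)
    )


def read_study_data(
    path: str | Path, column_map: Optional[ColumnMap] = None
) -> pd.DataFrame:
    """Read a (possibly foreign-schema) choice dataset into canonical form.

    After renaming and recoding through ``column_map``, the reader:

    - errors if any required analysis column is missing, naming it;
    - derives ``cue_predictive`` from ``cue_position``/``superior_position``
      when absent;
    - recomputes ``historical_predictivity`` from the cue-predictive flags
      when absent, and when it *is* present cross-checks it against the
      recomputation, emitting a :class:`PredictivityMismatch` warning with
      the number of disagreeing rows.
    """
    column_map = column_map or ColumnMap.identity()
    data = pd.read_csv(path)
    rename = {src: canon for canon, src in column_map.columns.items()}
    missing_sources = [s for s in rename if s not in data.columns]
    if missing_sources:
        raise ValueError(
            f"mapped source columns not found in {path}: {missing_sources}"
        )
    data = data.rename(columns=rename)
    for col, mapping in column_map.recode.items():
        if col in data.columns:
            data[col] = data[col].map(lambda v: mapping.get(v, v))

    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")

    if "cue_predictive" not in data.columns:
        if not {"cue_position", "superior_position"} <= set(data.columns):
            raise ValueError(
                "dataset needs either cue_predictive or both "
                "cue_position and superior_position"
            )
        data["cue_predictive"] = (
            data["cue_position"] == data["superior_position"]
        ).astype(int)

    recomputed = _recompute_historical(data)
    if "historical_predictivity" in data.columns:
        provided = data["historical_predictivity"].astype(float)
        both = provided.notna() & recomputed.notna()
        n_bad = int(
            (~np.isclose(provided[both], recomputed[both], atol=1e-6)).sum()
        )
        if n_bad:
            warnings.warn(
                f"historical_predictivity disagrees with recomputation from "
                f"cue_predictive flags on {n_bad} of {int(both.sum())} rows; "
                f"keeping the provided values",
                PredictivityMismatch,
                stacklevel=2,
            )
    else:
        data["historical_predictivity"] = recomputed
    return data


# -- session serialisation ---------------------------------------------------

_OPTION_FIELDS = (
    "shape",
    "area",
    "price",
    "position",
    "has_decoy",
    "is_decoy",
    "is_default",
    "is_indicator",
)


def session_to_frame(session: Session) -> pd.DataFrame:
    """Long-format view of a session: one row per trial x option."""
    rows = []
    for trial in session.trials:
        for opt in trial.options:
            row = {
                "participant_id": session.participant_id,
                "condition": session.config.condition.value,
                "assigned_predictivity": session.config.assigned_predictivity,
                "round_index": trial.round_index,
                "round_kind": trial.round_kind.value,
            }
            row.update({f: getattr(opt, f) for f in _OPTION_FIELDS})
            row.update(
                cue_position=trial.cue_position,
                superior_position=trial.superior_position,
                cue_predictive=trial.cue_predictive,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def session_to_json(session: Session, path: Optional[str | Path] = None) -> str:
    """Compact JSON dump of a session, suitable for exact round-tripping."""
    payload = {
        "participant_id": session.participant_id,
        "indicator_shape": session.indicator_shape,
        "config": {**asdict(session.config), "condition": session.config.condition.value},
        "trials": [
            {
                "round_index": t.round_index,
                "round_kind": t.round_kind.value,
                "cue_position": t.cue_position,
                "superior_position": t.superior_position,
                "cue_predictive": t.cue_predictive,
                "decoy_proportion": t.decoy_proportion,
                "options": [
                    {f: getattr(o, f) for f in _OPTION_FIELDS} for o in t.options
                ],
            }
            for t in session.trials
        ],
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def session_from_json(source: str | Path) -> Session:
    """Inverse of :func:`session_to_json`; accepts a path or a JSON string."""
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    payload = json.loads(text)
    config = SessionConfig(**payload["config"])
    trials = tuple(
        Trial(
            round_index=t["round_index"],
            round_kind=RoundKind(t["round_kind"]),
            options=tuple(OptionSpec(**o) for o in t["options"]),
            cue_position=t["cue_position"],
            superior_position=t["superior_position"],
            cue_predictive=t["cue_predictive"],
            decoy_proportion=t["decoy_proportion"],
        )
        for t in payload["trials"]
    )
    return Session(
        participant_id=payload["participant_id"],
        config=config,
        trials=trials,
        indicator_shape=payload["indicator_shape"],
    )


def load_config(path: str | Path) -> SessionConfig:
    """Load a session configuration from a flat YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return SessionConfig(**raw)


def save_config(config: SessionConfig, path: str | Path) -> None:
    payload = {**asdict(config), "condition": config.condition.value}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
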
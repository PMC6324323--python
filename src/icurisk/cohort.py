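"""Cohort selection, 24-hour windowing, and table I/O.

Three long-format tables flow through the pipeline:

* stays — ``patient_id, site, age, sex, icu_type, icu_admit_rank,
  icu_los_hours, died_in_hospital, death_time_hours``
* observations — ``patient_id, variable, t, value`` (t in hours since ICU
  admission)
* notes — ``patient_id, t, text``

Cohort rules: adults (age >= 18), ICU stay of at least 4 hours (inclusive),
first ICU admission only. The analysis window is the half-open interval
[0, window_hours) so a boundary event is never double-counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CohortWindow",
    "SchemaError",
    "DataError",
    "ParseError",
    "select_cohort",
    "clip_window",
    "read_events",
    "write_events",
    "STAY_COLUMNS",
    "OBSERVATION_COLUMNS",
    "NOTE_COLUMNS",
]

STAY_COLUMNS = ["patient_id", "site", "age", "sex", "icu_type", "icu_admit_rank",
                "icu_los_hours", "died_in_hospital", "death_time_hours"]
OBSERVATION_COLUMNS = ["patient_id", "variable", "t", "value"]
NOTE_COLUMNS = ["patient_id", "t", "text"]

_NUMERIC = {"age", "icu_admit_rank", "icu_los_hours", "death_time_hours", "t", "value"}


class SchemaError(ValueError):
    """Required column missing from a table."""


class DataError(ValueError):
    """A row violates a data invariant (e.g. negative event time)."""


class ParseError(ValueError):
    """A file row could not be parsed; carries the 1-based row number."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class CohortWindow:
    """Cohort-selection and windowing rules."""

    window_hours: float = 24.0
    min_stay_hours: float = 4.0
    min_age_years: float = 18.0

    def __post_init__(self):
        if self.window_hours <= 0 or self.min_stay_hours <= 0 or self.min_age_years <= 0:
            raise ValueError("all CohortWindow fields must be positive")


def _require(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")


def select_cohort(stays: pd.DataFrame, rules: CohortWindow = CohortWindow()) -> pd.DataFrame:
    """Apply the cohort filters; input row order is preserved.

    Retains adults (age >= min_age_years), stays of at least min_stay_hours
    (boundary inclusive: a 4.0-hour stay qualifies), and first ICU
    admissions (icu_admit_rank == 1). Idempotent.
    """
    _require(stays, ["age", "icu_los_hours", "icu_admit_rank"])
    keep = (
        (stays["age"] >= rules.min_age_years)
        & (stays["icu_los_hours"] >= rules.min_stay_hours)
        & (stays["icu_admit_rank"] == 1)
    )
    return stays.loc[keep].copy()


def clip_window(
    observations: pd.DataFrame,
    notes: pd.DataFrame,
    rules: CohortWindow = CohortWindow(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep events with t in the half-open window [0, window_hours).

    Original row ordering is preserved; a negative event time raises
    DataError.
    """
    out = []
    for table in (observations, notes):
        _require(table, ["t"])
        if len(table) and (table["t"] < 0).any():
            bad = int(table.index[table["t"] < 0][0])
            raise DataError(f"negative event time at index {bad}")
        out.append(table.loc[table["t"] < rules.window_hours].copy())
    return out[0], out[1]


# --------------------------------------------------------------------------
# I/O. CSV and JSONL serializations round-trip values to 12 significant
# digits, so write-then-read is an identity for practical purposes.
# --------------------------------------------------------------------------

def _validate_numeric(table: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in table.columns:
        if col not in _NUMERIC:
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna() & (table[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ParseError(f"non-numeric value {table[col].iloc[row - 1]!r} "
                             f"in column {col!r} of {source}", row)
        table[col] = coerced
    return table


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a stays/observations/notes table from CSV or JSONL.

    The format is inferred from the extension (.jsonl/.ndjson vs anything
    else treated as CSV). Malformed rows raise ParseError with the 1-based
    data-row number.
    """
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as e:
                    raise ParseError(f"invalid JSON in {path.name}: {e.msg}", i) from e
        table = pd.DataFrame(rows)
    else:
        table = pd.read_csv(path, dtype=str, keep_default_na=True)
    table = table.reset_index(drop=True)
    table = _validate_numeric(table, path.name)
    if "died_in_hospital" in table.columns:
        table["died_in_hospital"] = table["died_in_hospital"].map(
            lambda v: v if isinstance(v, bool) else str(v).strip().lower() in {"true", "1", "1.0"})
    return table


def write_events(path: str | Path, table: pd.DataFrame) -> None:
    """Write a table as CSV or JSONL (by extension), 12 significant digits."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with open(path, "w") as fh:
            for rec in table.to_dict(orient="records"):
                clean = {}
                for k, v in rec.items():
                    if isinstance(v, float):
                        v = float(f"{v:.12g}") if v == v else None
                    clean[k] = v
                fh.write(json.dumps(clean) + "\n")
    else:
        table.to_csv(path, index=False, float_format="%.12g")
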
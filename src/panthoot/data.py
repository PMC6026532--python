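"""Domain tables, transformations and descriptive summaries.

The analysis operates on two tabular inputs:

* a **call table** — one row per pant hoot, carrying the caller identity,
  the hierarchy-instability period (before / during / after the alpha
  takeover), the caller's standardized dominance rank, whether the call was
  directly preceded by leaf clipping, whether the recording captured the
  complete call, and up to 18 acoustic measurements (durations, element
  counts, fundamental and peak frequencies), any of which may be missing;
* a **focal-day table** — one row per focal-follow day, carrying the focal
  male, observation hours (the exposure for rate models) and daily counts
  of pant hoots and aggressive interactions.

Both are held as :class:`pandas.DataFrame` with fixed canonical column
names; CSV readers accept a user-supplied column map so deposited files
with arbitrary headers can be ingested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PERIODS",
    "MEASUREMENT_COLUMNS",
    "CALL_CORE_COLUMNS",
    "FOCAL_COLUMNS",
    "TRANSFORMS",
    "SchemaError",
    "TableParseError",
    "DescriptiveSummary",
    "standardize_rank",
    "apply_transform",
    "inverse_transform",
    "period_from_date",
    "load_column_map",
    "read_call_table",
    "write_call_table",
    "read_focal_table",
    "write_focal_table",
    "summarize_observation",
]

#: Hierarchy-instability periods, in temporal order; "before" is the
#: reference level in every model.
PERIODS = ("before", "during", "after")

#: First observed fight between the alpha and beta male, and the deposed
#: alpha's first pant grunt to the new alpha.  "during" is the closed
#: interval between them.
TAKEOVER_START = pd.Timestamp("2011-10-16")
TAKEOVER_END = pd.Timestamp("2011-11-19")

#: The 18 acoustic response variables, in registry order.
MEASUREMENT_COLUMNS = (
    "total_duration_s",
    "n_intro_calls",
    "intro_duration_s",
    "intro_last_call_f0_hz",
    "intro_last_call_duration_s",
    "intro_last_call_pf_hz",
    "n_buildup_calls",
    "buildup_duration_s",
    "buildup_mid_call_f0_hz",
    "buildup_mid_call_duration_s",
    "buildup_mid_call_pf_hz",
    "n_climax_elements",
    "climax_duration_s",
    "climax_f0_hz",
    "climax_call_duration_s",
    "climax_pf_hz",
    "drumming_duration_s",
    "n_drum_beats",
)

CALL_CORE_COLUMNS = (
    "caller_id",
    "date",
    "period",
    "rank_std",
    "leaf_clip",
    "complete_recording",
)

FOCAL_COLUMNS = (
    "focal_id",
    "date",
    "period",
    "rank_std",
    "hours_observed",
    "n_pant_hoots",
    "n_aggression",
    "leaf_clip_day",
)

TRANSFORMS = ("none", "sqrt", "log", "log_x1000")

_COUNT_COLUMNS = frozenset(
    c for c in MEASUREMENT_COLUMNS if c.startswith("n_")
)


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class TableParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"{message} (row {row})")
        self.row = row


def standardize_rank(rank_raw: int, n_males: int, *, alpha_high: bool = True) -> float:
    """Map an ordinal dominance rank (1 = alpha) onto [0, 1].

    With ``alpha_high`` (the default) the alpha male maps to 1 and the
    lowest-ranking male to 0, so positive model coefficients read as
    "greater for higher-ranking males".  Set ``alpha_high=False`` to flip
    the convention.

    Parameters
    ----------
    rank_raw : int
        Ordinal rank, 1 (alpha) to ``n_males``.
    n_males : int
        Number of males in the hierarchy at the time; must be >= 2.
    """
    if n_males < 2:
        raise ValueError(f"n_males must be >= 2, got {n_males}")
    if not 1 <= rank_raw <= n_males:
        raise ValueError(f"rank_raw {rank_raw} outside 1..{n_males}")
    x = (n_males - rank_raw) / (n_males - 1)
    return x if alpha_high else 1.0 - x


def apply_transform(value, transform: str):
    """Apply a response transformation (scalar or array).

    ``none`` is the identity, ``sqrt`` the square root, ``log`` the natural
    log, and ``log_x1000`` the natural log of 1000 x value (used for short
    durations measured in seconds so the transformed scale is comfortably
    positive).
    """
    x = np.asarray(value, dtype=float)
    with np.errstate(invalid="ignore"):
        if transform == "none":
            out = x
        elif transform == "sqrt":
            if np.any(x[np.isfinite(x)] < 0):
                raise ValueError("sqrt transform requires non-negative input")
            out = np.sqrt(x)
        elif transform == "log":
            if np.any(x[np.isfinite(x)] <= 0):
                raise ValueError("log transform requires positive input")
            out = np.log(x)
        elif transform == "log_x1000":
            if np.any(x[np.isfinite(x)] <= 0):
                raise ValueError("log_x1000 transform requires positive input")
            out = np.log(1000.0 * x)
        else:
            raise ValueError(f"unknown transform {transform!r}")
    return out if out.shape else float(out)


def inverse_transform(value, transform: str):
    """Invert :func:`apply_transform` (maps the model scale back to data)."""
    x = np.asarray(value, dtype=float)
    if transform == "none":
        out = x
    elif transform == "sqrt":
        out = np.square(x)
    elif transform == "log":
        out = np.exp(x)
    elif transform == "log_x1000":
        out = np.exp(x) / 1000.0
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return out if out.shape else float(out)


def period_from_date(date) -> str:
    """Assign the instability period from a calendar date.

    Boundaries are the first observed alpha/beta fight (2011-10-16) and the
    deposed alpha's pant-grunt concession (2011-11-19); "during" is the
    closed interval between them.
    """
    d = pd.Timestamp(date)
    if d < TAKEOVER_START:
        return "before"
    if d <= TAKEOVER_END:
        return "during"
    return "after"


# ---------------------------------------------------------------------------
# CSV ingestion


def load_column_map(path) -> dict:
    """Load a YAML or JSON column map ``{source column -> canonical field}``."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise SchemaError("column map must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    def conv(v, i):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise TableParseError(f"cannot parse boolean {v!r} in column {name}", i)

    return pd.Series(
        [conv(v, i) for i, v in enumerate(series)], index=series.index, dtype=bool
    )


def _parse_numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise TableParseError(
            f"non-numeric value {series.iloc[row]!r} in column {name}", row
        )
    return out.astype(float)


def _apply_column_map(raw: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        missing = [c for c in column_map if c not in raw.columns]
        if missing:
            raise SchemaError(f"column map names absent from file: {missing}")
        raw = raw.rename(columns=column_map)
    return raw


def read_call_table(path, column_map=None, **read_csv_kwargs) -> pd.DataFrame:
    """Read a per-call CSV into the canonical call table.

    Parameters
    ----------
    path : path-like
        CSV file: UTF-8, comma-separated, period decimal mark, ISO-8601
        dates, empty cell = missing (override via ``read_csv_kwargs``).
    column_map : dict or path-like, optional
        ``{source column -> canonical field}`` mapping, or a path to a
        YAML/JSON file with one, for files whose headers differ from the
        canonical names.

    Returns
    -------
    pandas.DataFrame
        One row per call with :data:`CALL_CORE_COLUMNS` followed by the 18
        :data:`MEASUREMENT_COLUMNS` (missing measurements are NaN).
    """
    if column_map is not None and not isinstance(column_map, dict):
        column_map = load_column_map(column_map)
    raw = pd.read_csv(path, **read_csv_kwargs)
    raw = _apply_column_map(raw, column_map)

    required = ["caller_id", "period", "rank_std", "leaf_clip", "complete_recording"]
    has_date = "date" in raw.columns
    if not has_date and "period" not in raw.columns:
        raise SchemaError("need either a 'period' or a 'date' column")
    for col in required:
        if col == "period" and has_date:
            continue
        if col == "rank_std" and "rank_raw" in raw.columns:
            continue
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing or unmapped")

    out = pd.DataFrame(index=raw.index)
    out["caller_id"] = raw["caller_id"].astype(str)
    if has_date:
        out["date"] = pd.to_datetime(raw["date"])
    else:
        out["date"] = pd.NaT
    if "period" in raw.columns:
        per = raw["period"].astype(str).str.strip().str.lower()
        bad = ~per.isin(PERIODS)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise TableParseError(f"unknown period label {per.iloc[row]!r}", row)
        out["period"] = per
    else:
        out["period"] = out["date"].map(period_from_date)
    if "rank_std" in raw.columns:
        out["rank_std"] = _parse_numeric(raw["rank_std"], "rank_std")
    else:
        out["rank_std"] = np.nan
    if "rank_raw" in raw.columns:
        out["rank_raw"] = _parse_numeric(raw["rank_raw"], "rank_raw")
    if len(out) and (
        (out["rank_std"] < 0).any() or (out["rank_std"] > 1).any()
    ):
        raise ValueError("rank_std values outside [0, 1]")
    out["leaf_clip"] = (
        _parse_bool(raw["leaf_clip"], "leaf_clip")
        if len(raw)
        else pd.Series(dtype=bool)
    )
    out["complete_recording"] = (
        _parse_bool(raw["complete_recording"], "complete_recording")
        if len(raw)
        else pd.Series(dtype=bool)
    )
    if "activity" in raw.columns:
        out["activity"] = raw["activity"].astype("string")

    for col in MEASUREMENT_COLUMNS:
        if col in raw.columns:
            vals = _parse_numeric(raw[col], col)
            if col in _COUNT_COLUMNS:
                ok = vals.dropna()
                if ((ok < 0) | (ok != np.round(ok))).any():
                    raise ValueError(f"{col} must hold non-negative integers")
            out[col] = vals
        else:
            out[col] = np.nan
    return out.reset_index(drop=True)


def write_call_table(calls: pd.DataFrame, path) -> None:
    """Write a canonical call table to CSV (inverse of :func:`read_call_table`)."""
    df = calls.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_focal_table(path, column_map=None, **read_csv_kwargs) -> pd.DataFrame:
    """Read a per-focal-day CSV into the canonical focal-day table."""
    if column_map is not None and not isinstance(column_map, dict):
        column_map = load_column_map(column_map)
    raw = pd.read_csv(path, **read_csv_kwargs)
    raw = _apply_column_map(raw, column_map)
    has_date = "date" in raw.columns
    for col in FOCAL_COLUMNS:
        if col in ("date", "period") and has_date:
            continue
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing or unmapped")

    out = pd.DataFrame(index=raw.index)
    out["focal_id"] = raw["focal_id"].astype(str)
    out["date"] = pd.to_datetime(raw["date"]) if has_date else pd.NaT
    if "period" in raw.columns:
        out["period"] = raw["period"].astype(str).str.strip().str.lower()
    else:
        out["period"] = out["date"].map(period_from_date)
    out["rank_std"] = _parse_numeric(raw["rank_std"], "rank_std")
    out["hours_observed"] = _parse_numeric(raw["hours_observed"], "hours_observed")
    if (out["hours_observed"] <= 0).any():
        raise ValueError("hours_observed must be strictly positive")
    for col in ("n_pant_hoots", "n_aggression"):
        vals = _parse_numeric(raw[col], col)
        if ((vals < 0) | (vals != np.round(vals))).any():
            raise ValueError(f"{col} must hold non-negative integers")
        out[col] = vals.astype(int)
    out["leaf_clip_day"] = (
        _parse_bool(raw["leaf_clip_day"], "leaf_clip_day")
        if len(raw)
        else pd.Series(dtype=bool)
    )
    return out.reset_index(drop=True)


def write_focal_table(days: pd.DataFrame, path) -> None:
    df = days.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive summaries


@dataclass(frozen=True)
class DescriptiveSummary:
    """Observation-effort and leaf-clip descriptives for a study period."""

    total_hours: float
    n_focal_days: int
    mean_day_hours: float
    n_leafclips: int
    n_leafclip_before_panthoot: int
    n_leafclip_recorded: int
    pct_audience_present: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_observation(
    focal_days: pd.DataFrame, leafclip_log: pd.DataFrame | None = None
) -> DescriptiveSummary:
    """Summarize observation effort and the leaf-clip event log.

    Parameters
    ----------
    focal_days : DataFrame
        Canonical focal-day table (``hours_observed`` per day).
    leafclip_log : DataFrame, optional
        One row per leaf-clip event with boolean columns
        ``preceded_panthoot`` (the clip came < 3 s before a pant hoot),
        ``recorded`` (that pant hoot was recorded for acoustic analysis)
        and ``audience_present`` (any conspecific in sight).

    Returns
    -------
    DescriptiveSummary
        Totals; the audience percentage is rounded half-up to an integer
        percent.
    """
    if focal_days is None or len(focal_days) == 0:
        raise ValueError("focal-day table is empty")
    total_hours = float(focal_days["hours_observed"].sum())
    n_days = int(len(focal_days))
    if leafclip_log is None or len(leafclip_log) == 0:
        n_lc = n_pre = n_rec = 0
        pct = 0
    else:
        n_lc = int(len(leafclip_log))
        n_pre = int(leafclip_log["preceded_panthoot"].sum())
        n_rec = int(leafclip_log["recorded"].sum())
        pct = _round_half_up(100.0 * leafclip_log["audience_present"].sum() / n_lc)
    return DescriptiveSummary(
        total_hours=total_hours,
        n_focal_days=n_days,
        mean_day_hours=total_hours / n_days,
        n_leafclips=n_lc,
        n_leafclip_before_panthoot=n_pre,
        n_leafclip_recorded=n_rec,
        pct_audience_present=pct,
    )
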
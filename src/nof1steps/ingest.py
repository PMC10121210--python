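"""Reading device records and classifying wear status.

A minute is classified from the (heart rate present, step count) pair:

* heart rate present            -> WORN     (count trusted)
* heart rate absent, steps > 0  -> CARRIED  (device off-wrist but moving; count trusted)
* heart rate absent, steps == 0 -> MISSING  (true activity unknown)

Day-level adherence is the fraction of non-MISSING minutes; the baseline
filter requires a minimum number of adherent baseline days.
"""

from __future__ import annotations

from typing import Iterable, Tuple, Union

import numpy as np
import pandas as pd

from .design import MINUTES_PER_DAY, TrialDesign

WORN = "WORN"
CARRIED = "CARRIED"
MISSING = "MISSING"
WEAR_STATUSES = (WORN, CARRIED, MISSING)

MINUTE_CSV_COLUMNS = ["participant_id", "date", "minute", "steps", "heart_rate"]


class ParseError(ValueError):
    """A CSV row failed validation; the message names the offending line."""


class IntegrityError(ValueError):
    """Duplicate (participant, day, minute) keys in the input."""


class StructuralError(ValueError):
    """Input shape violates the trial structure (e.g. wrong minute count)."""


def classify_minute(steps: int, heart_rate_present: bool) -> Tuple[str, Union[float, None]]:
    """Classify one minute; returns ``(wear_status, resolved_steps)``.

    ``resolved_steps`` is ``None`` when the minute is MISSING (the true
    count is not determinable from the record).
    """
    if steps < 0:
        raise ValueError(f"negative step count: {steps}")
    if heart_rate_present:
        return WORN, float(steps)
    if steps > 0:
        return CARRIED, float(steps)
    return MISSING, None


def classify_minutes(minutes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_minute` over a minute-record frame.

    Expects a ``heart_rate`` column (NA = absent) or a boolean
    ``heart_rate_present`` column. Adds ``wear`` and ``resolved_steps``
    (float, NaN where MISSING).
    """
    out = minutes.copy()
    if "heart_rate_present" in out.columns:
        present = out["heart_rate_present"].to_numpy(dtype=bool)
    else:
        present = out["heart_rate"].notna().to_numpy()
    steps = out["steps"].to_numpy()
    if np.any(steps < 0):
        raise ValueError("negative step count in records")
    wear = np.where(present, WORN, np.where(steps > 0, CARRIED, MISSING))
    resolved = np.where(wear == MISSING, np.nan, steps.astype(float))
    out["wear"] = wear
    out["resolved_steps"] = resolved
    return out


def day_wear_fraction(wear: Iterable[str]) -> float:
    """Fraction of a day's minutes that are non-MISSING (device on body)."""
    wear = np.asarray(list(wear) if not isinstance(wear, np.ndarray) else wear)
    if wear.shape[0] != MINUTES_PER_DAY:
        raise StructuralError(
            f"expected {MINUTES_PER_DAY} minutes, got {wear.shape[0]}"
        )
    return float(np.mean(wear != MISSING))


def wear_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, day) wear fraction table.

    Days are counted over the full 1440-minute grid: minutes absent from the
    input contribute as MISSING.
    """
    grp = classified.groupby(["participant_id", "day_index"], sort=True)
    frac = grp["wear"].apply(lambda w: np.sum(w.to_numpy() != MISSING) / MINUTES_PER_DAY)
    out = frac.rename("wear_fraction").reset_index()
    return out


def baseline_adherence_pass(
    baseline_day_fractions: Iterable[float],
    min_adherent_days: int = 11,
    day_threshold: float = 0.8,
) -> bool:
    """Baseline filter: enough baseline days with enough wear.

    A day is adherent when its wear fraction is at least ``day_threshold``;
    the participant passes when at least ``min_adherent_days`` baseline days
    are adherent.
    """
    fractions = np.asarray(list(baseline_day_fractions), dtype=float)
    return int(np.sum(fractions >= day_threshold)) >= min_adherent_days


def _column_to_numeric(raw: pd.Series, name: str, path) -> pd.Series:
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: line {line}: invalid {name!r} value {raw[bad.idxmax()]!r}")
    return converted


def read_minute_csv(path) -> pd.DataFrame:
    """Read the minute CSV dialect into a validated record frame.

    Empty heart-rate fields parse as absent. Adds ``day_index`` (0-based
    from each participant's first recorded date) and ``heart_rate_present``.
    Rows come back sorted by (participant, day, minute).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(MINUTE_CSV_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    raw = raw.replace({"": None})

    dates = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        line = int(dates.isna().idxmax()) + 2
        raise ParseError(f"{path}: line {line}: invalid date {raw['date'][dates.isna().idxmax()]!r}")
    minute = _column_to_numeric(raw["minute"], "minute", path).astype(int)
    steps = _column_to_numeric(raw["steps"], "steps", path)
    if steps.isna().any():
        line = int(steps.isna().idxmax()) + 2
        raise ParseError(f"{path}: line {line}: empty steps field")
    steps = steps.astype(int)
    heart = _column_to_numeric(raw["heart_rate"], "heart_rate", path)

    if ((minute < 0) | (minute >= MINUTES_PER_DAY)).any():
        idx = int(((minute < 0) | (minute >= MINUTES_PER_DAY)).idxmax())
        raise ParseError(f"{path}: line {idx + 2}: minute out of range [0, 1439]")
    if (steps < 0).any():
        idx = int((steps < 0).idxmax())
        raise ParseError(f"{path}: line {idx + 2}: negative step count")

    df = pd.DataFrame(
        {
            "participant_id": raw["participant_id"],
            "date": dates.dt.date,
            "minute": minute,
            "steps": steps,
            "heart_rate": heart.astype("Int64"),
        }
    )
    dup = df.duplicated(subset=["participant_id", "date", "minute"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate record for participant {row['participant_id']!r} "
            f"date {row['date']} minute {int(row['minute'])}"
        )
    first_date = df.groupby("participant_id")["date"].transform("min")
    df["day_index"] = (
        pd.to_datetime(df["date"]) - pd.to_datetime(first_date)
    ).dt.days.astype(int)
    df["heart_rate_present"] = df["heart_rate"].notna().to_numpy(dtype=bool)
    df = df.sort_values(["participant_id", "day_index", "minute"], ignore_index=True)
    return df


def read_covariate_csv(path) -> pd.DataFrame:
    """Read the day-level covariate table; derives the weekday indicator."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})
    missing_cols = {"date", "temperature_f"} - set(raw.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    dates = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        line = int(dates.isna().idxmax()) + 2
        raise ParseError(f"{path}: line {line}: invalid date")
    temp = _column_to_numeric(raw["temperature_f"], "temperature_f", path)
    if temp.isna().any():
        line = int(temp.isna().idxmax()) + 2
        raise ParseError(f"{path}: line {line}: empty temperature_f field")
    df = pd.DataFrame(
        {
            "date": dates.dt.date,
            "temperature_f": temp.astype(float),
            "weekday": (dates.dt.weekday < 5).astype(int),
        }
    )
    if df["date"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate covariate dates")
    return df.sort_values("date", ignore_index=True)
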
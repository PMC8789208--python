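"""Event registry data model: delimited-text I/O, outcome construction and
predictor categorization.

The unit of analysis is one *edition* of a mass gathering (MG).  Patient
encounter forms (PEFs) are pooled per edition to yield two outcomes, both
expressed per 10,000 attendees:

* PPR  — patient presentation rate: every encounter registered on an official
  event day counts, regardless of missing fields; encounters dated the day
  before or after an official day (typical for camping festivals) are excluded.
* TTHR — transfer to hospital rate: only dismissals ``hospital_by_ambulance``
  count; transport by own means, and missing dismissal, count as non-transfer.

Candidate predictors are categorical by construction: attendance, number of
days and patient age are binned a priori (see :func:`classify_attendance`,
:func:`classify_days`, :func:`classify_age`); category, timing, alcohol,
indoor, bounded and camping enter in their original form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ClassificationError,
    OutcomeUndefinedError,
    SchemaError,
    UnresolvableMissingError,
)

# ---------------------------------------------------------------------------
# enumerations

CATEGORIES = (
    "city_festival",
    "indoor_edm",
    "indoor_dance",
    "outdoor_edm",
    "outdoor_music",
    "sports_event",
)
TIMING_LEVELS = ("day", "night", "day_and_night")
ALCOHOL_LEVELS = ("none", "limited", "unlimited")
DISMISSAL_LEVELS = ("back_to_event", "hospital_by_ambulance", "own_means", "other")

ATTENDANCE_CLASSES = ("lt10k", "a10_20k", "a20_30k", "a30_100k", "a100k_1M", "gt1M")
AGE_CLASSES = ("children", "young_adults", "middle_adults", "mixed_family")
DAYS_CLASSES = ("d1", "d2", "d3plus")

#: the nine dichotomous/categorical predictors entered in the PPR tree
PPR_PREDICTORS = (
    "category",
    "attendance_class",
    "age_class",
    "days_class",
    "timing",
    "indoor",
    "bounded",
    "camping",
    "alcohol",
)

#: predictors with a natural order (split search restricted to contiguous cuts)
ORDERED_PREDICTORS: dict[str, tuple[str, ...]] = {
    "attendance_class": ATTENDANCE_CLASSES,
    "days_class": DAYS_CLASSES,
    "alcohol": ALCOHOL_LEVELS,
}

EVENT_COLUMNS = (
    "event_id",
    "series_name",
    "year",
    "category",
    "attendance",
    "first_day",
    "n_days",
    "timing",
    "indoor",
    "bounded",
    "camping",
    "alcohol",
    "hospital_distance_km",
    "hospital_time_min",
    "sold_out",
)
ENCOUNTER_COLUMNS = ("event_id", "day", "age", "dismissal", "triage")
TEMPERATURE_COLUMNS = ("day", "t_av_c", "t_max_c")


def round_rate(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching how the rates are reported."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# official event days and encounter filtering


def official_days(edition: Mapping) -> pd.DatetimeIndex:
    """The consecutive calendar dates on which the edition officially ran."""
    first = pd.Timestamp(edition["first_day"])
    n = int(edition["n_days"])
    if n < 1:
        raise SchemaError(f"n_days must be >= 1, got {n}")
    return pd.date_range(first, periods=n, freq="D")


def _edition_encounters(encounters: pd.DataFrame, edition: Mapping) -> pd.DataFrame:
    if "event_id" in encounters.columns and "event_id" in edition:
        encounters = encounters[encounters["event_id"] == edition["event_id"]]
    return encounters


def filter_encounters(
    encounters: pd.DataFrame, edition: Mapping
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an edition's encounters into (on official days, outside them).

    Inclusion is by calendar date, not 24 h windows.
    """
    enc = _edition_encounters(encounters, edition)
    days = official_days(edition)
    day = pd.to_datetime(enc["day"]).dt.normalize()
    inside = day.isin(days)
    return enc[inside], enc[~inside]


def _resolved_attendance(edition: Mapping) -> float:
    att = edition.get("attendance") if isinstance(edition, dict) else edition["attendance"]
    if att is None or (isinstance(att, float) and np.isnan(att)):
        raise OutcomeUndefinedError(
            f"attendance unresolved for edition {edition.get('event_id', '?')}"
        )
    att = float(att)
    if att <= 0:
        raise OutcomeUndefinedError(f"attendance must be > 0, got {att}")
    return att


def compute_ppr(encounters: pd.DataFrame, edition: Mapping) -> float:
    """Patient presentation rate per 10,000 attendees for one edition."""
    att = _resolved_attendance(edition)
    included, _ = filter_encounters(encounters, edition)
    return 10_000.0 * len(included) / att


def compute_tthr(encounters: pd.DataFrame, edition: Mapping) -> float:
    """Transfer-to-hospital rate per 10,000 attendees for one edition.

    Missing dismissal counts as non-transfer (conservative reading: the
    dominant "back to the event" destination is the one most easily left
    blank, so TTHR may be slightly overestimated in the source registry,
    not underestimated here).
    """
    att = _resolved_attendance(edition)
    included, _ = filter_encounters(encounters, edition)
    n_transfers = int((included["dismissal"] == "hospital_by_ambulance").sum())
    return 10_000.0 * n_transfers / att


# ---------------------------------------------------------------------------
# predictor categorization

_ATTENDANCE_EDGES = (10_000, 20_000, 30_000, 100_000, 1_000_000)


def classify_attendance(attendance: float) -> str:
    """Bin attendance into the six classes; bins are half-open on the right:
    [0, 10k), [10k, 20k), [20k, 30k), [30k, 100k), [100k, 1M), [1M, inf)."""
    if not attendance > 0:
        raise ClassificationError(f"attendance must be > 0, got {attendance}")
    idx = int(np.searchsorted(_ATTENDANCE_EDGES, attendance, side="right"))
    return ATTENDANCE_CLASSES[idx]


def classify_age(age_median: float, age_q1: float, age_iqr: float) -> str:
    """Assign the audience age class from encounter-age summary statistics.

    The mixed/family class is an override: Q1 < 21 y with IQR > 20 y, or
    Q1 < 18 y with IQR > 15 y.  Otherwise the median decides: < 16 children,
    16–30 young adults, > 30 middle adults.
    """
    for v in (age_median, age_q1, age_iqr):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ClassificationError("age statistics unavailable (all ages missing?)")
    if (age_q1 < 21 and age_iqr > 20) or (age_q1 < 18 and age_iqr > 15):
        return "mixed_family"
    if age_median < 16:
        return "children"
    if age_median <= 30:
        return "young_adults"
    return "middle_adults"


def classify_days(days: Iterable) -> str:
    """1 day -> d1, 2 -> d2, 3 or more -> d3plus."""
    n = len(list(days))
    if n < 1:
        raise ClassificationError("official_days must be non-empty")
    return DAYS_CLASSES[min(n, 3) - 1]


def age_summary(ages: pd.Series) -> tuple[float, float, float]:
    """(median, Q1, IQR) of non-missing ages, inclusive linear interpolation."""
    obs = pd.to_numeric(ages, errors="coerce").dropna().to_numpy(dtype=float)
    if obs.size == 0:
        return (float("nan"),) * 3
    q1, med, q3 = np.quantile(obs, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3 - q1)


# ---------------------------------------------------------------------------
# missing-attendance imputation


def impute_attendance(series: pd.DataFrame) -> pd.DataFrame:
    """Resolve missing attendance within one MG series (rows sorted by year).

    Two rules only, mirroring how the registry gaps were closed:

    1. a single interior gap between two observed editions is filled with the
       arithmetic mean of the adjacent editions;
    2. sold-out editions following an observed sold-out first edition copy the
       first edition's attendance.

    Anything else raises :class:`UnresolvableMissingError`; no other
    imputation is attempted.  The returned frame carries a provenance column
    ``attendance_source`` in {"observed", "interpolated", "sold_out_copy"}.
    """
    out = series.sort_values("year").reset_index(drop=True).copy()
    att = out["attendance"].to_numpy(dtype=float)
    source = np.where(np.isnan(att), "", "observed").astype(object)
    sold = out["sold_out"].astype(bool).to_numpy()

    first_sold_out = sold[0] and not np.isnan(att[0])
    for i in np.flatnonzero(np.isnan(att)):
        if 0 < i < len(att) - 1 and not np.isnan(att[i - 1]) and not np.isnan(att[i + 1]):
            att[i] = 0.5 * (att[i - 1] + att[i + 1])
            source[i] = "interpolated"
        elif first_sold_out and i > 0 and sold[i]:
            att[i] = att[0]
            source[i] = "sold_out_copy"
        else:
            raise UnresolvableMissingError(
                f"attendance for {out.loc[i, 'event_id']} matches neither the "
                "interior-gap nor the sold-out rule"
            )
    out["attendance"] = att
    out["attendance_source"] = source
    return out


def impute_attendance_table(events: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`impute_attendance` per MG series and reassemble."""
    parts = [impute_attendance(g) for _, g in events.groupby("series_name", sort=False)]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# events-per-variable


@dataclass(frozen=True)
class Epv:
    """Events-per-variable ratio, the usual overfitting heuristic."""

    n_events: int
    n_candidates: int

    @property
    def epv(self) -> float:
        return round_rate(self.n_events / self.n_candidates)


def compute_epv(n_events: int, n_candidates: int) -> Epv:
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    return Epv(n_events, n_candidates)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_events(events: pd.DataFrame, encounters: pd.DataFrame) -> pd.DataFrame:
    """Build the regression table: one row per edition with outcomes and
    categorized predictors.

    Attendance must already be resolved (see :func:`impute_attendance_table`).
    Events with no age-carrying encounters get a missing ``age_class``.
    """
    rows = []
    enc_by_event = dict(tuple(encounters.groupby("event_id", sort=False)))
    empty = encounters.iloc[0:0]
    for _, ev in events.iterrows():
        enc = enc_by_event.get(ev["event_id"], empty)
        included, _ = filter_encounters(enc, ev)
        att = _resolved_attendance(ev)
        n_patients = len(included)
        n_transfers = int((included["dismissal"] == "hospital_by_ambulance").sum())
        med, q1, iqr = age_summary(included["age"]) if n_patients else (np.nan,) * 3
        try:
            age_class = classify_age(med, q1, iqr)
        except ClassificationError:
            age_class = np.nan
        row = dict(ev)
        row.update(
            n_patients=n_patients,
            n_transfers=n_transfers,
            ppr=10_000.0 * n_patients / att,
            tthr=10_000.0 * n_transfers / att,
            attendance_class=classify_attendance(att),
            age_class=age_class,
            days_class=classify_days(official_days(ev)),
            age_median=med,
            age_q1=q1,
            age_iqr=iqr,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _check_levels(df: pd.DataFrame, column: str, levels: tuple[str, ...], allow_na=False):
    col = df[column]
    bad = ~col.isin(levels)
    if allow_na:
        bad &= col.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unknown {column} label {col.iloc[i]!r} in row {i} (column {column!r})"
        )


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"events table missing columns: {sorted(missing)}")
    _check_levels(df, "category", CATEGORIES)
    _check_levels(df, "timing", TIMING_LEVELS)
    _check_levels(df, "alcohol", ALCOHOL_LEVELS)
    df["first_day"] = pd.to_datetime(df["first_day"])
    for col in ("indoor", "bounded", "camping", "sold_out"):
        df[col] = df[col].astype(bool)
    return df


def read_encounters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ENCOUNTER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"encounters table missing columns: {sorted(missing)}")
    _check_levels(df, "dismissal", DISMISSAL_LEVELS, allow_na=True)
    df["day"] = pd.to_datetime(df["day"])
    bad_age = df["age"].notna() & ((df["age"] < 0) | (df["age"] > 120))
    if bad_age.any():
        i = int(np.flatnonzero(bad_age.to_numpy())[0])
        raise SchemaError(f"age out of [0, 120] in row {i} (column 'age')")
    return df


def read_temperatures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TEMPERATURE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"temperatures table missing columns: {sorted(missing)}")
    df["day"] = pd.to_datetime(df["day"])
    return df


def write_aggregated(aggregated: pd.DataFrame, path: str | Path) -> None:
    out = aggregated.copy()
    if "first_day" in out.columns:
        out["first_day"] = pd.to_datetime(out["first_day"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_aggregated(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "first_day" in df.columns:
        df["first_day"] = pd.to_datetime(df["first_day"])
    return df
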
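"""Body-condition-score records: domain types, long-format I/O, filtering,
scale conversion and aggregation.

The in-memory container is a :class:`pandas.DataFrame` with one scored
observation per row (the *record frame*); :class:`BcsRecord` gives a typed
view of a single row.  Columns of a record frame:

``animal_id``    cow identifier (string)
``week``         1-based experiment week (int)
``day_in_week``  1..7 within the experiment week (int)
``milking``      "AM"/"PM" for camera records, missing for visual records
``method``       "camera" or "visual"
``device_id``    camera unit or scorer identifier (string)
``value``        BCS on the 1-8 scale (float)
``scale``        provenance tag, "s8" or "s10"

Week/day indices are experiment-relative, not calendar weeks: the crossed
random-effects model is indexed by position within the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CAMERA = "camera"
VISUAL = "visual"
AM = "AM"
PM = "PM"
SCALE_8 = "s8"
SCALE_10 = "s10"

#: columns every record table must carry, in canonical order
RECORD_COLUMNS = [
    "animal_id",
    "week",
    "day_in_week",
    "milking",
    "method",
    "device_id",
    "value",
    "scale",
]


class BcsFormatError(ValueError):
    """Raised when a record table violates the long-format contract."""


@dataclass(frozen=True)
class BcsRecord:
    """One BCS observation with its full design indexing."""

    animal_id: str
    week: int
    day_in_week: int
    milking: str | None  # AM/PM for camera, None for visual
    method: str
    device_id: str
    value: float
    scale: str = SCALE_8


@dataclass(frozen=True)
class ScaleTransform:
    """Affine map from one BCS scale to another: new = intercept + slope*old.

    Order-preserving, so ``slope`` must be positive.  The coefficients for a
    particular pair of published scales (e.g. the 1-10 camera scale to the
    1-8 scale) are configuration inputs; no default is assumed.
    """

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"scale transform slope must be > 0, got {self.slope}")

    def apply(self, value):
        return self.intercept + self.slope * np.asarray(value, dtype=float)

    def inverse(self) -> "ScaleTransform":
        return ScaleTransform(-self.intercept / self.slope, 1.0 / self.slope)


def records_to_frame(records: Iterable[BcsRecord]) -> pd.DataFrame:
    """Build a canonical record frame from typed records."""
    rows = [
        (r.animal_id, r.week, r.day_in_week, r.milking, r.method, r.device_id, r.value, r.scale)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return _normalise(df)


def frame_to_records(df: pd.DataFrame) -> list[BcsRecord]:
    return [
        BcsRecord(
            animal_id=str(row.animal_id),
            week=int(row.week),
            day_in_week=int(row.day_in_week),
            milking=None if pd.isna(row.milking) else str(row.milking),
            method=str(row.method),
            device_id=str(row.device_id),
            value=float(row.value),
            scale=str(row.scale),
        )
        for row in df.itertuples(index=False)
    ]


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["animal_id"] = out["animal_id"].astype(str)
    out["week"] = out["week"].astype(int)
    out["day_in_week"] = out["day_in_week"].astype(int)
    out["milking"] = out["milking"].astype(object).where(out["milking"].notna(), None)
    out["method"] = out["method"].astype(str)
    out["device_id"] = out["device_id"].astype(str)
    out["value"] = out["value"].astype(float)
    out["scale"] = out["scale"].astype(str)
    return out[RECORD_COLUMNS]


def validate_frame(df: pd.DataFrame) -> None:
    """Check structural invariants of a record frame; raise BcsFormatError."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise BcsFormatError(f"missing required column(s): {', '.join(missing)}")
    bad_method = set(df["method"].unique()) - {CAMERA, VISUAL}
    if bad_method:
        raise BcsFormatError(f"unknown method value(s): {sorted(bad_method)}")
    for method, sub in df.groupby("method"):
        key = ["animal_id", "week", "day_in_week", "milking", "device_id"]
        dup = sub.duplicated(subset=key)
        if dup.any():
            raise BcsFormatError(
                f"{int(dup.sum())} duplicate (animal, week, day, milking, device) "
                f"key(s) in {method} records"
            )


def read_bcs_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format BCS CSV into a record frame.

    The header must contain all :data:`RECORD_COLUMNS`.  Rows with a
    non-numeric or missing ``value``, or missing ``device_id``, are rejected
    with a :class:`BcsFormatError` naming the offending row numbers
    (1-based, counting the header as row 1).
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise BcsFormatError(f"{path}: empty file") from exc
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise BcsFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    values = pd.to_numeric(raw["value"], errors="coerce")
    bad_rows: list[int] = []
    for i in range(len(raw)):
        if math.isnan(values.iloc[i]) or pd.isna(raw["device_id"].iloc[i]):
            bad_rows.append(i + 2)  # +1 header, +1 to 1-based
    if bad_rows:
        shown = ", ".join(map(str, bad_rows[:20]))
        more = "" if len(bad_rows) <= 20 else f" (+{len(bad_rows) - 20} more)"
        raise BcsFormatError(
            f"{path}: {len(bad_rows)} malformed row(s) "
            f"(non-numeric value or missing device_id) at row(s) {shown}{more}"
        )

    df = raw.copy()
    df["value"] = values
    df["week"] = pd.to_numeric(df["week"], errors="raise").astype(int)
    df["day_in_week"] = pd.to_numeric(df["day_in_week"], errors="raise").astype(int)
    df = _normalise(df)
    validate_frame(df)
    return df


def write_bcs_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a record frame as a canonical long-format CSV."""
    out = _normalise(df)
    out.to_csv(path, index=False)


def filter_valid(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (kept, rejected) by score validity.

    Camera units occasionally report zero or negative scores (failed depth
    reconstruction); those are physically meaningless and excluded before any
    analysis.  ``kept`` holds records with value > 0, ``rejected`` the rest;
    together they are the input, disjointly.
    """
    mask = df["value"].to_numpy() > 0
    return df[mask].reset_index(drop=True), df[~mask].reset_index(drop=True)


def convert_scale(df: pd.DataFrame, transform: ScaleTransform) -> pd.DataFrame:
    """Apply an affine scale conversion to every value; retag scale as s8."""
    out = df.copy()
    out["value"] = transform.apply(out["value"].to_numpy())
    out["scale"] = SCALE_8
    return out


def weekly_animal_means(df: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean score per (animal, week), the analysis unit.

    All comparisons between methods are made on cow-by-week means so that a
    twice-daily camera and a once-weekly scorer panel are summarised at a
    common temporal scale.

    Returns a frame with columns animal_id, week, method, mean_value,
    n_contributing.
    """
    if df.empty:
        return pd.DataFrame(
            columns=["animal_id", "week", "method", "mean_value", "n_contributing"]
        )
    grouped = (
        df.groupby(["animal_id", "week", "method"], sort=True)["value"]
        .agg(mean_value="mean", n_contributing="size")
        .reset_index()
    )
    grouped["n_contributing"] = grouped["n_contributing"].astype(int)
    return grouped


def vendor_rolling_average(
    times: Sequence[float],
    values: Sequence[float],
    window_days: float = 7.0,
    trim_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing trimmed rolling mean as produced by the camera vendor software.

    For each distinct observation day ``d`` the window covers the
    ``window_days`` whole days ending with day ``d`` (times in
    ``[d - window_days + 1, d + 1)``); the lowest and highest
    ``floor(trim_fraction * n)`` values in the window are discarded from
    each tail before averaging.  Provided for
    comparison with the loess-based refinement; it trims a fixed share of
    data regardless of whether they are outlying and ignores any trend
    within the window.

    Returns (days, averages), one entry per day with at least one window
    observation.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have the same length")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    days = np.unique(np.floor(t))
    out_days, out_vals = [], []
    for d in days:
        in_window = (t >= d - window_days + 1) & (t < d + 1)
        w = np.sort(v[in_window])
        n = w.size
        if n == 0:
            continue
        ntrim = int(math.floor(trim_fraction * n))
        kept = w[ntrim : n - ntrim] if ntrim > 0 else w
        out_days.append(d)
        out_vals.append(float(np.mean(kept)))
    return np.asarray(out_days), np.asarray(out_vals)


def observation_times(df: pd.DataFrame) -> np.ndarray:
    """Fractional day-from-start for each record.

    Day 0 is week 1 / day 1.  AM and PM milkings on the same day are offset
    to 0.25 and 0.75 of a day so that per-cow time series have strictly
    distinct abscissae; visual records (no milking) sit at 0.5.
    """
    base = (df["week"].to_numpy() - 1) * 7 + (df["day_in_week"].to_numpy() - 1)
    milking = df["milking"].to_numpy(dtype=object)
    frac = np.where(milking == AM, 0.25, np.where(milking == PM, 0.75, 0.5))
    return base + frac
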
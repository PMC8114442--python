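"""Event and environment containers, file dialects, binning and day/phase bookkeeping.

Eclosion monitors emit timestamped counts at a native cadence (typically 10 min
or 1 min). All rhythm statistics operate on 1-h bins; circular summaries and
Winfree's R operate on the 24-h daily pool. Timestamps are local standard time
throughout — an experiment must not cross a daylight-saving transition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventSeries",
    "HourlyProfile",
    "DailyProfile",
    "EnvironmentSeries",
    "FormatError",
    "ValidationError",
    "read_events",
    "write_events",
    "read_environment",
    "write_environment",
    "bin_hourly",
    "pool_daily",
]


class FormatError(ValueError):
    """A file could not be interpreted under the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


DEFAULT_DIALECT = {"timestamp": "timestamp", "count": "count"}


def _check_no_dst(timestamps: pd.DatetimeIndex, allow_dst: bool) -> None:
    # Naive stamps are local standard time by convention and cannot encode a
    # transition; only tz-aware input can be checked.
    if timestamps.tz is None:
        return
    offsets = {ts.utcoffset() for ts in timestamps}
    if len(offsets) > 1 and not allow_dst:
        raise ValidationError(
            "series crosses a UTC-offset (daylight-saving) transition; "
            "pass allow_dst=True to override"
        )


@dataclass(frozen=True)
class EventSeries:
    """Raw timestamped eclosion counts for one experiment.

    Parameters
    ----------
    experiment_id, genotype : str
        Identifiers carried through every downstream table.
    timestamps : DatetimeIndex
        Strictly increasing, local standard time.
    counts : ndarray of int
        Non-negative eclosion counts per native interval.
    cadence_minutes : int
        Native recording cadence (10 or 1 for the common monitors).
    """

    experiment_id: str
    genotype: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    cadence_minutes: int
    allow_dst: bool = False

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        _check_no_dst(ts, self.allow_dst)
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(ts) != len(counts):
            raise ValidationError("timestamps and counts differ in length")
        if len(ts) == 0:
            raise ValidationError("empty event series")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            bad = np.where(np.diff(ts.asi8) <= 0)[0] + 1
            raise ValidationError(
                f"timestamps not strictly increasing at rows {bad[:10].tolist()}"
            )
        if (counts < 0).any():
            raise ValidationError("negative counts")
        if self.cadence_minutes <= 0:
            raise ValidationError("cadence_minutes must be positive")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def missing_fraction(self) -> float:
        """Fraction of expected native intervals with no record at all."""
        span = self.timestamps[-1] - self.timestamps[0]
        expected = int(span / pd.Timedelta(minutes=self.cadence_minutes)) + 1
        return 1.0 - len(self.timestamps) / max(expected, 1)


@dataclass(frozen=True)
class HourlyProfile:
    """1-h-binned counts; the unit of all rhythm statistics.

    Bins are half-open [t, t+1h) labeled by their start hour.
    """

    experiment_id: str
    start: pd.Timestamp
    counts: np.ndarray
    genotype: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        start = pd.Timestamp(self.start)
        if start != start.floor("h"):
            raise ValidationError("profile start must fall on a whole hour")
        if len(counts) < 24:
            raise ValidationError("profile must span at least 24 h")
        if (counts < 0).any():
            raise ValidationError("negative bin counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "start", start)

    @property
    def n_flies(self) -> int:
        return int(self.counts.sum())

    @property
    def hours(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.counts), freq="h")

    @property
    def hour_of_day(self) -> np.ndarray:
        return (self.start.hour + np.arange(len(self.counts))) % 24


@dataclass(frozen=True)
class DailyProfile:
    """Counts pooled by hour of day (0..23) across all days of an experiment."""

    counts_by_hour: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts_by_hour, dtype=np.int64)
        if counts.shape != (24,):
            raise ValidationError("daily profile needs exactly 24 hourly entries")
        if (counts < 0).any():
            raise ValidationError("negative pooled counts")
        object.__setattr__(self, "counts_by_hour", counts)

    @property
    def total(self) -> int:
        return int(self.counts_by_hour.sum())


@dataclass(frozen=True)
class EnvironmentSeries:
    """Hourly temperature (°C), light intensity and RH (%), plus per-day nautical dawn."""

    hourly: pd.DataFrame  # columns: timestamp, temperature_c, light, rh_percent
    dawn_by_date: Mapping[date, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.hourly
        missing = {"timestamp", "temperature_c", "light", "rh_percent"} - set(df.columns)
        if missing:
            raise ValidationError(f"environment table missing columns {sorted(missing)}")
        ts = pd.DatetimeIndex(df["timestamp"])
        if len(ts) and not (ts == ts.floor("h")).all():
            raise ValidationError("environment timestamps must fall on whole hours")
        gaps = np.diff(ts.asi8)
        if len(gaps) and not (gaps == 3_600_000_000_000).all():
            raise ValidationError("environment series must have one entry per hour")
        rh = df["rh_percent"].to_numpy(float)
        if ((rh < 0) | (rh > 100)).any():
            raise ValidationError("RH outside [0, 100]")
        object.__setattr__(self, "hourly", df.reset_index(drop=True))
        object.__setattr__(self, "dawn_by_date", dict(self.dawn_by_date))

    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        ts = pd.DatetimeIndex(self.hourly["timestamp"])
        return ts[0], ts[-1]


def _infer_cadence_minutes(ts: pd.DatetimeIndex) -> int:
    if len(ts) < 2:
        return 10
    gaps = np.diff(ts.asi8) / 60e9
    return max(int(round(float(np.median(gaps)))), 1)


def read_events(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    experiment_id: str | None = None,
    genotype: str = "",
    allow_dst: bool = False,
) -> EventSeries:
    """Read a delimited event file into an :class:`EventSeries`.

    ``dialect`` maps the canonical column roles (``timestamp``, ``count``) to
    the file's own header names; the default expects those literal names.
    Malformed rows are reported with their line numbers (header = line 1).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path)
    for role in ("timestamp", "count"):
        if dialect[role] not in df.columns:
            raise FormatError(
                f"column {dialect[role]!r} (role {role}) not found in {path}; "
                f"have {list(df.columns)}"
            )
    ts = pd.to_datetime(df[dialect["timestamp"]], errors="coerce")
    counts = pd.to_numeric(df[dialect["count"]], errors="coerce")
    bad = np.where(ts.isna() | counts.isna() | (counts < 0) | (counts % 1 != 0))[0]
    if len(bad):
        lines = (bad + 2).tolist()  # +1 header, +1 one-based
        raise FormatError(f"malformed rows at lines {lines[:20]} in {path}")
    idx = pd.DatetimeIndex(ts)
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        bad = np.where(np.diff(idx.asi8) <= 0)[0] + 1
        raise ValidationError(
            f"non-monotone timestamps at data rows {(bad + 1).tolist()[:20]}"
        )
    return EventSeries(
        experiment_id=experiment_id or str(path),
        genotype=genotype,
        timestamps=idx,
        counts=counts.to_numpy(np.int64),
        cadence_minutes=_infer_cadence_minutes(idx),
        allow_dst=allow_dst,
    )


def write_events(events: EventSeries, path) -> None:
    pd.DataFrame(
        {"timestamp": events.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
         "count": events.counts}
    ).to_csv(path, index=False)


def read_environment(path, dawn_path=None) -> EnvironmentSeries:
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise FormatError(f"environment file {path} lacks a 'timestamp' column")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    dawn: dict[date, float] = {}
    if dawn_path is not None:
        dtab = pd.read_csv(dawn_path)
        for _, row in dtab.iterrows():
            dawn[pd.Timestamp(row["date"]).date()] = float(row["nautical_dawn_hour"])
    return EnvironmentSeries(hourly=df, dawn_by_date=dawn)


def write_environment(env: EnvironmentSeries, path, dawn_path=None) -> None:
    out = env.hourly.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6g")
    if dawn_path is not None:
        pd.DataFrame(
            {"date": [d.isoformat() for d in env.dawn_by_date],
             "nautical_dawn_hour": list(env.dawn_by_date.values())}
        ).to_csv(dawn_path, index=False)


def bin_hourly(
    events: EventSeries,
    *,
    max_missing_fraction: float = 0.2,
    missing_policy: str = "zero_fill",
) -> HourlyProfile:
    """Assign each native record to the 1-h bin containing its timestamp.

    Totals are conserved. Hours with no native record are zero-filled by
    default; ``missing_policy='error'`` refuses instead. Regardless of policy
    the run refuses when more than ``max_missing_fraction`` of the expected
    native intervals are absent.
    """
    if events.total == 0 and len(events.timestamps) == 0:
        raise ValidationError("no events")
    miss = events.missing_fraction()
    if miss > max_missing_fraction:
        raise ValidationError(
            f"{miss:.1%} of native intervals missing exceeds the "
            f"{max_missing_fraction:.0%} threshold"
        )
    if missing_policy not in ("zero_fill", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if missing_policy == "error" and miss > 0:
        raise ValidationError(f"{miss:.1%} of native intervals missing")
    start = events.timestamps[0].floor("h")
    end = events.timestamps[-1].floor("h")
    n_hours = max(int((end - start) / pd.Timedelta(hours=1)) + 1, 24)
    idx = ((events.timestamps.asi8 - start.value) // 3_600_000_000_000).astype(int)
    counts = np.bincount(idx, weights=events.counts, minlength=n_hours).astype(np.int64)
    return HourlyProfile(
        experiment_id=events.experiment_id,
        start=start,
        counts=counts,
        genotype=events.genotype,
    )


def pool_daily(profile: HourlyProfile) -> DailyProfile:
    """Pool an hourly profile into the 24-h daily distribution."""
    pooled = np.bincount(profile.hour_of_day, weights=profile.counts, minlength=24)
    return DailyProfile(counts_by_hour=pooled.astype(np.int64))


def pool_profiles(profiles: Sequence[HourlyProfile]) -> DailyProfile:
    """Pool several experiments into one daily distribution."""
    total = np.zeros(24, dtype=np.int64)
    for p in profiles:
        total += pool_daily(p).counts_by_hour
    return DailyProfile(counts_by_hour=total)
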
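"""Data model and assembly of annotated exposure records.

A monitored work day yields one :class:`ShiftSeries` per size fraction —
the time-stamped concentration records of a complete shift — plus one
:class:`Logbook` of station/environment intervals and event annotations
kept by the job-shadowing technicians.  :func:`annotate` joins the two,
applies the log10 transform, and :func:`build_design` turns the result
into the reference-coded categorical design matrices consumed by the
hierarchical model.

Conventions
-----------
* Logbook intervals are half-open ``[start, end)``: a record exactly on a
  boundary belongs to the later interval.
* A record falling in a gap between two intervals with *different*
  stations is labelled ``Tunnel`` (travelling underground between
  stations); its environment is carried over from the preceding interval.
* Records with a timestamp inside an event interval get flag 1 for that
  event; overlapping events set multiple flags.
* The within-shift time covariate t is minutes since the first record of
  the shift.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigurationError, EmptySeriesError

logger = logging.getLogger(__name__)

TUNNEL = "Tunnel"

JOBS = ("station_agent", "locomotive_operator", "security_guard")

MASS_FRACTIONS = ("PM0.3", "PM1", "PM2.5", "PM10")


@dataclass
class ShiftSeries:
    """One work day's time-stamped concentration records for one channel.

    ``records`` has a ``timestamp`` column (datetime64) and a ``value``
    column (µg/m³ for mass fractions, #/cm³ for number concentrations);
    ``temperature`` (°C) and ``rh`` (%) columns are optional.
    """

    day_id: str
    job: str
    fraction: str
    records: pd.DataFrame
    units: str = "ug/m3"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"timestamp", "value"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {req}")
        ts = self.records["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.Series:
        return self.records["timestamp"]

    def time_weighted_mean(self) -> float:
        """Mean concentration weighted by the duration of each record.

        Each record is taken to represent the interval up to the next
        record; the last record gets the median spacing.  On a regular
        grid this is the plain arithmetic mean.
        """
        v = self.values
        if len(v) == 1:
            return float(v[0])
        dt = np.diff(self.timestamps.to_numpy().astype("datetime64[s]").astype(float))
        w = np.append(dt, np.median(dt))
        return float(np.average(v, weights=w))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(
        cls, path: str | Path, day_id: str, job: str, fraction: str, **kw
    ) -> "ShiftSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(day_id=day_id, job=job, fraction=fraction, records=df, **kw)


@dataclass
class Logbook:
    """Activity logbook of one shift.

    ``intervals``: columns start, end (datetime), station, environment —
    contiguous, non-overlapping, covering the shift.
    ``events``: columns start, end, event — point (start == end) or
    interval annotations; may overlap each other and the intervals.
    """

    day_id: str
    intervals: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"start", "end", "station", "environment"}.issubset(
            self.intervals.columns
        ):
            raise ValueError("intervals need start/end/station/environment")
        if not {"start", "end", "event"}.issubset(self.events.columns):
            raise ValueError("events need start/end/event")

    @property
    def shift_start(self) -> pd.Timestamp:
        return self.intervals["start"].iloc[0]

    @property
    def shift_end(self) -> pd.Timestamp:
        return self.intervals["end"].iloc[-1]

    def environment_coverage_minutes(self) -> float:
        """Total minutes covered by environment intervals."""
        d = (self.intervals["end"] - self.intervals["start"]).dt.total_seconds()
        return float(d.sum() / 60.0)

    def to_csv(self, path: str | Path) -> None:
        ivs = self.intervals.copy()
        ivs["event"] = ""
        evs = self.events.copy()
        evs["station"] = ""
        evs["environment"] = ""
        out = pd.concat([ivs, evs], ignore_index=True)[
            ["start", "end", "station", "environment", "event"]
        ]
        out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path: str | Path, day_id: str) -> "Logbook":
        df = pd.read_csv(path, parse_dates=["start", "end"], keep_default_na=False)
        is_event = df["event"].astype(str) != ""
        ivs = df.loc[~is_event, ["start", "end", "station", "environment"]]
        evs = df.loc[is_event, ["start", "end", "event"]]
        return cls(day_id=day_id, intervals=ivs.reset_index(drop=True),
                   events=evs.reset_index(drop=True))


def clean_series(series: ShiftSeries, floor: float = 1e-9) -> ShiftSeries:
    """Drop missing and sub-floor records so the log10 transform is defined.

    Raises :class:`EmptySeriesError` if nothing survives.  The number of
    dropped records is logged and stored in ``meta['n_dropped']``.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    rec = series.records
    keep = rec["value"].notna() & (rec["value"] >= floor)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("clean_series(%s/%s): dropped %d of %d records",
                    series.day_id, series.fraction, n_drop, len(rec))
    out = rec.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptySeriesError(
            f"all {len(rec)} records of {series.day_id}/{series.fraction} "
            f"are missing or below {floor}"
        )
    meta = dict(series.meta, n_dropped=n_drop)
    return ShiftSeries(series.day_id, series.job, series.fraction, out,
                       units=series.units, meta=meta)


def annotate(series: ShiftSeries, logbook: Logbook) -> pd.DataFrame:
    """Join instrument records to the activity logbook.

    Returns a frame with one row per retained record and columns
    ``timestamp, log10_value, station, environment, day_id, job, t`` plus
    one 0/1 column ``event:<name>`` per event type seen in the logbook.
    ``t`` is minutes from the first record of the shift.  Records outside
    logbook coverage (before the first interval or after the last) are
    dropped; the count is logged and stored in ``df.attrs['n_dropped']``.
    """
    rec = series.records
    ivs = logbook.intervals.sort_values("start").reset_index(drop=True)
    if rec.empty:
        raise AnnotationError("empty series")

    ts = rec["timestamp"]
    lo, hi = ivs["start"].iloc[0], ivs["end"].iloc[-1]
    inside = (ts >= lo) & (ts < hi)
    n_drop = int((~inside).sum())
    if inside.sum() == 0:
        raise AnnotationError(
            f"no overlap between records ({ts.iloc[0]}..{ts.iloc[-1]}) "
            f"and logbook ({lo}..{hi})"
        )
    if n_drop:
        logger.info("annotate(%s): dropped %d records outside logbook coverage",
                    series.day_id, n_drop)
    rec = rec.loc[inside].reset_index(drop=True)
    ts = rec["timestamp"]

    # half-open interval join: idx of last interval with start <= t
    starts = ivs["start"].to_numpy()
    idx = np.searchsorted(starts, ts.to_numpy(), side="right") - 1
    station = ivs["station"].to_numpy(dtype=object)[idx].copy()
    environment = ivs["environment"].to_numpy(dtype=object)[idx].copy()

    # gap handling: record at/after its interval's end but before the next
    # start sits between two intervals -> Tunnel if the stations differ
    ends = ivs["end"].to_numpy()
    in_gap = ts.to_numpy() >= ends[idx]
    if in_gap.any():
        nxt = np.minimum(idx + 1, len(ivs) - 1)
        differs = ivs["station"].to_numpy(dtype=object)[nxt] != station
        station[in_gap & differs] = TUNNEL
        # environment carried over from the preceding interval (unchanged)

    vals = rec["value"].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise AnnotationError("non-positive concentrations: run clean_series first")

    out = pd.DataFrame(
        {
            "timestamp": ts.to_numpy(),
            "log10_value": np.log10(vals),
            "station": station,
            "environment": environment,
            "day_id": series.day_id,
            "job": series.job,
        }
    )
    t0 = ts.iloc[0]
    out["t"] = (ts - t0).dt.total_seconds().to_numpy() / 60.0

    event_types = sorted(logbook.events["event"].unique())
    tsv = ts.to_numpy()
    for ev in event_types:
        flag = np.zeros(len(out), dtype=int)
        for _, row in logbook.events[logbook.events["event"] == ev].iterrows():
            if row["start"] == row["end"]:  # point event: flag nearest record
                j = int(np.argmin(np.abs(tsv - np.datetime64(row["start"]))))
                flag[j] = 1
            else:
                flag[(tsv >= np.datetime64(row["start"]))
                     & (tsv < np.datetime64(row["end"]))] = 1
        out[f"event:{ev}"] = flag
    out.attrs["n_dropped"] = n_drop
    return out


@dataclass
class DesignMatrices:
    """Reference-coded design blocks for the hierarchical model.

    One-hot blocks omit the reference column, so a reference-category
    record is an all-zero row.  Columns are ordered lexicographically by
    category id.  ``day_idx``/``job_idx`` index into ``day_ids``/``jobs``;
    ``day_jobs`` maps each day to its job index.
    """

    y: np.ndarray                # log10 concentrations, shape (n,)
    X_station: np.ndarray        # (n, n_stations - 1)
    X_environment: np.ndarray    # (n, n_environments - 1)
    X_event: np.ndarray          # (n, n_events)
    t: np.ndarray                # within-shift minutes, (n,)
    day_idx: np.ndarray          # (n,) ints
    job_idx: np.ndarray          # (n,) ints
    stations: list[str]          # reference first, then lexicographic
    environments: list[str]
    events: list[str]
    day_ids: list[str]
    jobs: list[str]
    day_jobs: np.ndarray         # (n_days,) job index per day
    reference_station: str
    reference_environment: str

    @property
    def n(self) -> int:
        return len(self.y)

    def validate(self) -> None:
        n = self.n
        for name in ("X_station", "X_environment", "X_event", "t",
                     "day_idx", "job_idx"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} row count != {n}")
        for X in (self.X_station, self.X_environment):
            if X.size and X.max(initial=0) > 1 or np.any(X.sum(axis=1) > 1):
                raise ValueError("one-hot rows must sum to <= 1")

    def level_dicts(self) -> dict:
        return {
            "stations": self.stations,
            "environments": self.environments,
            "events": self.events,
            "day_ids": self.day_ids,
            "jobs": self.jobs,
            "day_jobs": self.day_jobs.tolist(),
            "reference_station": self.reference_station,
            "reference_environment": self.reference_environment,
        }

    def save_levels(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.level_dicts(), indent=1))


def _one_hot(codes: np.ndarray, n_levels: int, drop_first: bool) -> np.ndarray:
    X = np.zeros((len(codes), n_levels), dtype=float)
    X[np.arange(len(codes)), codes] = 1.0
    return X[:, 1:] if drop_first else X


def build_design(
    records: pd.DataFrame,
    reference_station: str,
    reference_environment: str,
) -> DesignMatrices:
    """Build reference-coded design matrices from annotated records.

    ``records`` is the (possibly concatenated over days) output of
    :func:`annotate`.  Rows are re-sorted by (day_id, timestamp) so the
    result is invariant to input row order.
    """
    df = records.sort_values(["day_id", "timestamp"]).reset_index(drop=True)

    for ref, col in ((reference_station, "station"),
                     (reference_environment, "environment")):
        if ref not in set(df[col]):
            raise ConfigurationError(f"reference {col} {ref!r} not observed")

    def levels(col: str, ref: str) -> list[str]:
        others = sorted(set(df[col]) - {ref})
        return [ref] + others

    stations = levels("station", reference_station)
    environments = levels("environment", reference_environment)
    st_code = df["station"].map({s: i for i, s in enumerate(stations)}).to_numpy()
    env_code = df["environment"].map(
        {e: i for i, e in enumerate(environments)}).to_numpy()

    event_cols = sorted(c for c in df.columns if c.startswith("event:"))
    events = [c.split(":", 1)[1] for c in event_cols]
    # days without a given event type have no flag column; absent == 0
    X_event = (df[event_cols].fillna(0.0).to_numpy(dtype=float)
               if event_cols else np.zeros((len(df), 0)))

    day_ids = sorted(df["day_id"].unique())
    jobs = sorted(df["job"].unique())
    day_idx = df["day_id"].map({d: i for i, d in enumerate(day_ids)}).to_numpy()
    job_idx = df["job"].map({j: i for i, j in enumerate(jobs)}).to_numpy()
    day_jobs = np.array(
        [job_idx[day_idx == i][0] for i in range(len(day_ids))], dtype=int
    )

    dm = DesignMatrices(
        y=df["log10_value"].to_numpy(dtype=float),
        X_station=_one_hot(st_code, len(stations), drop_first=True),
        X_environment=_one_hot(env_code, len(environments), drop_first=True),
        X_event=X_event,
        t=df["t"].to_numpy(dtype=float),
        day_idx=day_idx,
        job_idx=job_idx,
        stations=stations,
        environments=environments,
        events=events,
        day_ids=day_ids,
        jobs=jobs,
        day_jobs=day_jobs,
        reference_station=reference_station,
        reference_environment=reference_environment,
    )
    dm.validate()
    return dm
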
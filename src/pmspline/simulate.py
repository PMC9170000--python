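"""Synthetic personal-exposure campaign generator with known ground truth.

Emulates the structure of a subway-worker monitoring campaign: three jobs
(station agent, locomotive operator, security guard) monitored for eight
work days each, yielding 24 day-series.  Every day has an activity
logbook (station/environment intervals, event annotations), four
mass-concentration series (PM0.3, PM1, PM2.5, PM10) on a 5-minute grid,
a channelized number-concentration series (31 log-spaced channels,
0.25–20 µm), a wide-range counter series (10–700 nm analogue) at 6-second
resolution, and shift-level gravimetric PM2.5/PM10 values.

Mass concentrations are generated from the same hierarchical model the
package fits: on the log10 scale, a day-specific intercept drawn around a
job-level mean, additive station/environment/event effects with the
reference categories pinned at zero, a smooth per-day B-spline trend, and
day-specific Gaussian residual noise.  The realized parameters are stored
in :class:`GroundTruth` so parameter recovery can be verified exactly.

Schedule templates are qualitative: the station agent mans one ticket
counter, the locomotive operator traverses the whole line in the cabin
(with ``Tunnel`` intervals between stations), and the security guard
patrols a window of adjacent stations on foot and by train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .devices import ChannelSeries, band_weights, default_channel_edges
from .errors import ConfigurationError
from .logbook import JOBS, MASS_FRACTIONS, TUNNEL, Logbook, ShiftSeries
from .splines import bspline_basis

__all__ = ["SimConfig", "GroundTruth", "DayData", "Dataset",
           "make_ground_truth", "simulate_logbook", "simulate_mass_series",
           "simulate_number_series", "simulate_gravimetric",
           "generate_dataset", "check_design_completeness"]

#: canonical environment types, reference ("sampling room" analogue) first
ENVIRONMENTS = (
    "sampling_room", "ticket_counter", "platform", "cabin",
    "train", "underground_corridor", "cloakroom", "outdoor",
)

#: canonical event types
EVENTS = (
    "train_passing", "tobacco_smoke", "ticket_machine_intervention",
    "cabin_heater", "door_blocking", "platform_cleaning", "crowd_surge",
    "braking_dust", "maintenance_works", "public_announcement",
)

_BASE_DATE = pd.Timestamp("2019-10-07 06:00:00")

# fixed stream tags so every random draw has its own reproducible stream
_STREAM = {"truth": 0, "logbook": 1, "mass": 2, "number": 3, "grav": 4}


@dataclass
class SimConfig:
    """Study-design and data-generating parameters.

    Defaults mirror the structure of a two-week-per-job underground
    campaign: 3 jobs x 8 monitored days, 6-hour shifts, mass records
    every 5 min, number records every 6 s, and a categorical design of
    45 station categories (44 named stations + Tunnel), 8 environments
    and 10 event types.  Effects are on the log10 scale; station effects
    are small (fold changes rarely beyond ~10%), environment and event
    effects larger.
    """

    n_jobs: int = 3
    days_per_job: int = 8
    shift_minutes: int = 360
    mass_dt: int = 300               # seconds between mass records
    number_dt: int = 6               # seconds between counter records
    n_stations: int = 45             # categories incl. Tunnel
    n_environments: int = 8
    n_events: int = 10
    true_alpha: np.ndarray | None = None   # station effects, ref first = 0
    true_beta: np.ndarray | None = None    # environment effects, ref first = 0
    true_gamma: np.ndarray | None = None   # event effects
    alpha_scale: float = 0.04        # SD of drawn station effects (log10)
    beta_scale: float = 0.15
    gamma_scale: float = 0.20
    mu_job: tuple = (0.55, 0.65, 0.60)     # job-level mean intercepts (log10 ug/m3)
    tau2_job: tuple = (0.04, 0.04, 0.04)   # job-level intercept variances
    sigma2_day_range: tuple = (0.01, 0.09)  # per-day residual variance (log10^2)
    trend_amplitude: float = 0.10    # SD of spline trend coefficients (log10)
    n_trend_knots: int = 8           # interior knots of the generating trend
    fraction_offsets: dict = field(default_factory=lambda: {
        "PM0.3": -1.05, "PM1": 0.0, "PM2.5": 0.09, "PM10": 0.17})
    # number-concentration channel
    n_channels: int = 31
    channel_lo_um: float = 0.25
    channel_hi_um: float = 20.0
    counter_band_um: tuple = (0.25, 0.70)
    number_factor: float = 1.0e3     # counter total / OPC band total
    number_base_total: float = 50.0  # OPC full-range total, #/cm3
    number_noise_sd: float = 0.15    # log10-scale multiplicative noise SD
    spectrum_mode_um: float = 0.30   # mode of the number size spectrum
    spectrum_sigma_log10: float = 0.35
    # gravimetric truth: gravimetric = a * (shift mean raw)^b * noise
    grav_a: float = 2.5
    grav_b: float = 1.05
    grav_noise_sd: float = 0.10      # natural-log scale SD
    event_decay_minutes: float = 0.0  # effect persistence past the event end
    n_missing_days: int = 0          # drop real-time mass records of k days
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_jobs, self.days_per_job, self.n_stations,
               self.n_environments, self.shift_minutes) < 1 or self.n_events < 0:
            raise ConfigurationError("counts must be positive")
        if self.n_jobs > len(JOBS):
            raise ConfigurationError(f"at most {len(JOBS)} job templates")
        if (self.shift_minutes * 60) % self.mass_dt != 0:
            raise ConfigurationError("mass_dt must divide the shift evenly")
        if not (300 <= self.shift_minutes <= 600):
            raise ConfigurationError("shift_minutes outside plausible 5-10 h")
        if min(self.tau2_job[: self.n_jobs]) <= 0 or min(self.sigma2_day_range) <= 0:
            raise ConfigurationError("variances must be > 0")
        for name in ("true_alpha", "true_beta", "true_gamma"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                n_expect = {"true_alpha": self.n_stations,
                            "true_beta": self.n_environments,
                            "true_gamma": self.n_events}[name]
                if len(v) != n_expect:
                    raise ConfigurationError(f"{name} must have length {n_expect}")
                if name != "true_gamma" and v[0] != 0.0:
                    raise ConfigurationError(
                        f"{name}[0] is the reference effect and must be 0")
                setattr(self, name, v)

    # -- category labels -------------------------------------------------
    @property
    def stations(self) -> list[str]:
        named = [f"station_{i:02d}" for i in range(1, self.n_stations)]
        return named + [TUNNEL]

    @property
    def environments(self) -> list[str]:
        if self.n_environments > len(ENVIRONMENTS):
            return list(ENVIRONMENTS) + [
                f"environment_{i}" for i in range(len(ENVIRONMENTS) + 1,
                                                  self.n_environments + 1)]
        return list(ENVIRONMENTS[: self.n_environments])

    @property
    def events(self) -> list[str]:
        if self.n_events > len(EVENTS):
            return list(EVENTS) + [f"event_{i}" for i in
                                   range(len(EVENTS) + 1, self.n_events + 1)]
        return list(EVENTS[: self.n_events])

    @property
    def n_days(self) -> int:
        return self.n_jobs * self.days_per_job

    @property
    def jobs(self) -> list[str]:
        return list(JOBS[: self.n_jobs])

    def day_ids(self) -> list[str]:
        return [f"d{k:02d}" for k in range(1, self.n_days + 1)]

    def day_job(self, day_index: int) -> str:
        return self.jobs[day_index // self.days_per_job]

    def rng(self, stream: str, *indices: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAM[stream], *indices]))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("true_alpha", "true_beta", "true_gamma"):
            if d[k] is not None:
                d[k] = list(d[k])
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        for k in ("mu_job", "tau2_job", "sigma2_day_range", "counter_band_um"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized generating parameters of one synthetic campaign."""

    stations: list[str]
    environments: list[str]
    events: list[str]
    alpha: np.ndarray                # per station (ref first, = 0)
    beta: np.ndarray                 # per environment (ref first, = 0)
    gamma: np.ndarray                # per event
    day_ids: list[str]
    day_jobs: list[str]
    mu_day: np.ndarray               # (n_days,) log10 intercepts
    sigma2_day: np.ndarray           # (n_days,)
    trend_coefs: np.ndarray          # (n_days, n_basis)
    n_trend_knots: int
    shift_minutes: float
    fraction_offsets: dict
    m_job: list[float]
    tau2_job: list[float]
    grav_a: float
    grav_b: float
    seed: int

    def trend(self, day_index: int, t_minutes: np.ndarray) -> np.ndarray:
        """Smooth within-shift trend, centred to zero mean over the mass grid."""
        z = self.trend_coefs[day_index]
        B = bspline_basis(t_minutes, 0.0, self.shift_minutes, self.n_trend_knots)
        # centre against the same regular grid the mass series uses
        grid = np.asarray(self._grid_minutes(), dtype=float)
        Bg = bspline_basis(grid, 0.0, self.shift_minutes, self.n_trend_knots)
        return B @ z - float(np.mean(Bg @ z))

    def _grid_minutes(self) -> np.ndarray:
        return np.arange(0.0, self.shift_minutes, 5.0)

    def effect(self, kind: str, name: str) -> float:
        levels, vec = {
            "station": (self.stations, self.alpha),
            "environment": (self.environments, self.beta),
            "event": (self.events, self.gamma),
        }[kind]
        return float(vec[levels.index(name)])

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        for k in ("alpha", "beta", "gamma", "mu_day", "sigma2_day",
                  "trend_coefs"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def make_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Draw (or adopt) the generating parameters for a campaign."""
    rng = cfg.rng("truth")
    if cfg.true_alpha is not None:
        alpha = np.asarray(cfg.true_alpha, dtype=float)
    else:
        alpha = rng.normal(0.0, cfg.alpha_scale, cfg.n_stations)
        alpha[0] = 0.0
    if cfg.true_beta is not None:
        beta = np.asarray(cfg.true_beta, dtype=float)
    else:
        beta = rng.normal(0.0, cfg.beta_scale, cfg.n_environments)
        beta[0] = 0.0
    if cfg.true_gamma is not None:
        gamma = np.asarray(cfg.true_gamma, dtype=float)
    else:
        # events are exposure peaks: positive on average
        gamma = np.abs(rng.normal(0.0, cfg.gamma_scale, cfg.n_events))

    n_days = cfg.n_days
    job_of_day = [cfg.day_job(i) for i in range(n_days)]
    m = np.array(cfg.mu_job[: cfg.n_jobs])
    tau = np.sqrt(np.array(cfg.tau2_job[: cfg.n_jobs]))
    job_idx = np.repeat(np.arange(cfg.n_jobs), cfg.days_per_job)
    mu_day = rng.normal(m[job_idx], tau[job_idx])
    lo, hi = cfg.sigma2_day_range
    sigma2_day = rng.uniform(lo, hi, n_days)
    nb = cfg.n_trend_knots + 4
    trend_coefs = rng.normal(0.0, cfg.trend_amplitude, (n_days, nb))

    return GroundTruth(
        stations=cfg.stations, environments=cfg.environments,
        events=cfg.events, alpha=alpha, beta=beta, gamma=gamma,
        day_ids=cfg.day_ids(), day_jobs=job_of_day,
        mu_day=mu_day, sigma2_day=sigma2_day, trend_coefs=trend_coefs,
        n_trend_knots=cfg.n_trend_knots, shift_minutes=float(cfg.shift_minutes),
        fraction_offsets=dict(cfg.fraction_offsets),
        m_job=list(m), tau2_job=list(np.array(cfg.tau2_job[: cfg.n_jobs])),
        grav_a=cfg.grav_a, grav_b=cfg.grav_b, seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# logbook schedules
# ---------------------------------------------------------------------------

def _segments_station_agent(cfg, rng, day_index):
    """One fixed station; ticket counter most of the shift."""
    named = cfg.stations[:-1] if cfg.n_stations > 1 else cfg.stations
    home = named[(day_index * 5) % len(named)]
    segs = [(15, home, "sampling_room"), (10, home, "cloakroom")]
    fillers = ["underground_corridor", "platform", "outdoor"]
    remaining = cfg.shift_minutes - 40  # reserve 15 end + 25 start
    k = 0
    while remaining > 0:
        block = min(float(rng.integers(40, 70)), remaining)
        segs.append((block, home, "ticket_counter"))
        remaining -= block
        if remaining > 10:
            pause = float(rng.integers(5, 11))
            segs.append((pause, home, fillers[k % len(fillers)]))
            remaining -= pause
            k += 1
    segs.append((15, home, "sampling_room"))
    return segs


def _segments_locomotive_operator(cfg, rng, day_index):
    """Cabin traversal of the whole line, Tunnel between stations."""
    named = cfg.stations[:-1] if cfg.n_stations > 1 else cfg.stations
    segs = [(10, named[0], "sampling_room"), (5, named[0], "cloakroom")]
    budget = cfg.shift_minutes - 15 - 10 - 5  # reserve end segments
    route = list(named) + list(reversed(named))
    i = 0
    while budget > 3:
        st = route[i % len(route)]
        stop = min(1.0 + float(rng.integers(0, 2)), budget)
        segs.append((stop, st, "cabin"))
        budget -= stop
        if budget <= 2:
            break
        run = min(2.0, budget)
        segs.append((run, TUNNEL, "cabin"))
        budget -= run
        i += 1
    if budget > 0:
        segs.append((budget, named[0], "cabin"))
    segs.append((5, named[0], "platform"))
    segs.append((10, named[0], "sampling_room"))
    return segs


def _segments_security_guard(cfg, rng, day_index):
    """Foot/train patrol over a window of adjacent stations."""
    named = cfg.stations[:-1] if cfg.n_stations > 1 else cfg.stations
    w = min(5, len(named))
    start = (day_index * 7) % max(1, len(named) - w + 1)
    window = named[start: start + w]
    segs = [(10, window[0], "sampling_room"), (5, window[0], "cloakroom")]
    budget = cfg.shift_minutes - 15 - 10
    k = 0
    while budget > 5:
        st = window[k % len(window)]
        plat = min(float(rng.integers(12, 25)), budget)
        segs.append((plat, st, "platform"))
        budget -= plat
        if budget <= 5:
            break
        corr = min(float(rng.integers(6, 14)), budget)
        env = "outdoor" if k % 4 == 3 else "underground_corridor"
        segs.append((corr, st, env))
        budget -= corr
        if budget <= 5:
            break
        ride = min(3.0, budget)
        segs.append((ride, TUNNEL, "train"))
        budget -= ride
        k += 1
    if budget > 0:
        segs.append((budget, window[0], "underground_corridor"))
    segs.append((10, window[0], "sampling_room"))
    return segs


_TEMPLATES = {
    "station_agent": _segments_station_agent,
    "locomotive_operator": _segments_locomotive_operator,
    "security_guard": _segments_security_guard,
}


def simulate_logbook(cfg: SimConfig, day_index: int,
                     retry: int = 0) -> Logbook:
    """Generate one day's activity logbook from the job's schedule template.

    Environment intervals are contiguous, non-overlapping and cover the
    shift exactly; the shift starts and ends in the reference environment
    (sampling room analogue).  Event types follow a day-wise round-robin
    so every type occurs somewhere in a full campaign, with random extras.
    """
    if not 0 <= day_index < cfg.n_days:
        raise ConfigurationError(
            f"day_index {day_index} outside 0..{cfg.n_days - 1}")
    rng = cfg.rng("logbook", day_index, retry)
    job = cfg.day_job(day_index)
    segs = _TEMPLATES[job](cfg, rng, day_index)

    allowed = set(cfg.environments)
    ref_env = cfg.environments[0]
    segs = [(d, st, env if env in allowed else ref_env) for d, st, env in segs]

    day_start = _BASE_DATE + pd.Timedelta(days=day_index)
    rows, t = [], 0.0
    for dur, st, env in segs:
        rows.append({
            "start": day_start + pd.Timedelta(minutes=t),
            "end": day_start + pd.Timedelta(minutes=t + dur),
            "station": st, "environment": env,
        })
        t += dur
    # normalise rounding drift so coverage equals the shift exactly
    scale = cfg.shift_minutes / t
    if abs(scale - 1.0) > 1e-12:
        t = 0.0
        for r, (dur, _, _) in zip(rows, segs):
            r["start"] = day_start + pd.Timedelta(minutes=t)
            t += dur * scale
            r["end"] = day_start + pd.Timedelta(minutes=t)
    intervals = pd.DataFrame(rows)

    ev_rows = []
    base = [(day_index * 3 + j) % cfg.n_events for j in range(3)] \
        if cfg.n_events else []
    extra = list(rng.integers(0, cfg.n_events, rng.integers(1, 3))) \
        if cfg.n_events else []
    for ev_i in base + extra:
        dur = float(rng.integers(0, 11))      # 0 = point event
        start = float(rng.uniform(20, cfg.shift_minutes - 25 - dur))
        ev_rows.append({
            "start": day_start + pd.Timedelta(minutes=start),
            "end": day_start + pd.Timedelta(minutes=start + dur),
            "event": cfg.events[ev_i],
        })
    events = pd.DataFrame(ev_rows, columns=["start", "end", "event"])
    return Logbook(day_id=cfg.day_ids()[day_index], intervals=intervals,
                   events=events)


# ---------------------------------------------------------------------------
# instrument series
# ---------------------------------------------------------------------------

def _lookup(logbook: Logbook, times: pd.DatetimeIndex):
    """Station/environment/event-matrix at given times (half-open join)."""
    ivs = logbook.intervals
    starts = ivs["start"].to_numpy()
    idx = np.clip(np.searchsorted(starts, times.to_numpy(), side="right") - 1,
                  0, len(ivs) - 1)
    station = ivs["station"].to_numpy(dtype=object)[idx]
    env = ivs["environment"].to_numpy(dtype=object)[idx]
    return station, env, idx


def _event_matrix(logbook: Logbook, times: pd.DatetimeIndex,
                  event_levels: list[str],
                  decay_minutes: float = 0.0) -> np.ndarray:
    """0/1 event indicators at given times.

    ``decay_minutes`` extends each event's active window past its logged
    end: the concentration effect of an event (e.g. a smoke release) can
    outlast the event itself.  The default of 0 keeps the generating
    indicators identical to what annotation reconstructs from the
    logbook.
    """
    E = np.zeros((len(times), len(event_levels)))
    tsv = times.to_numpy()
    decay = np.timedelta64(int(decay_minutes * 60), "s")
    for _, row in logbook.events.iterrows():
        j = event_levels.index(row["event"])
        if row["start"] == row["end"] and decay_minutes == 0.0:
            E[int(np.argmin(np.abs(tsv - np.datetime64(row["start"])))), j] = 1.0
        else:
            sel = (tsv >= np.datetime64(row["start"])) & \
                  (tsv < np.datetime64(row["end"]) + decay)
            E[sel, j] = 1.0
    return E


def _mass_grid(cfg: SimConfig, logbook: Logbook) -> pd.DatetimeIndex:
    n = cfg.shift_minutes * 60 // cfg.mass_dt
    start = logbook.intervals["start"].iloc[0]
    return pd.DatetimeIndex(
        [start + pd.Timedelta(seconds=int(k * cfg.mass_dt)) for k in range(n)])


def simulate_mass_series(cfg: SimConfig, logbook: Logbook, gt: GroundTruth,
                         fraction: str) -> ShiftSeries:
    """Generate one mass-concentration series from the hierarchical model.

    log10 Y(t) = mu_day + alpha[station(t)] + beta[env(t)]
                 + gamma . events(t) + trend(t) + fraction offset + eps,
    eps ~ N(0, sigma2_day).  Concentrations are strictly positive by
    construction.
    """
    if fraction not in gt.fraction_offsets:
        raise ConfigurationError(f"unknown fraction {fraction!r}")
    day_index = gt.day_ids.index(logbook.day_id)
    rng = cfg.rng("mass", day_index, MASS_FRACTIONS.index(fraction)
                  if fraction in MASS_FRACTIONS else 99)
    times = _mass_grid(cfg, logbook)
    station, env, _ = _lookup(logbook, times)
    E = _event_matrix(logbook, times, gt.events, cfg.event_decay_minutes)

    st_map = {s: i for i, s in enumerate(gt.stations)}
    env_map = {e: i for i, e in enumerate(gt.environments)}
    a = gt.alpha[[st_map[s] for s in station]]
    b = gt.beta[[env_map[e] for e in env]]
    g = E @ gt.gamma
    t_min = (times - times[0]).total_seconds().to_numpy() / 60.0
    mean_log = (gt.mu_day[day_index] + a + b + g + gt.trend(day_index, t_min)
                + gt.fraction_offsets[fraction])
    eps = rng.normal(0.0, np.sqrt(gt.sigma2_day[day_index]), len(times))
    values = 10.0 ** (mean_log + eps)

    temp = 19.0 + 3.0 * np.sin(2 * np.pi * t_min / t_min[-1]) \
        + rng.normal(0, 0.5, len(times)) if len(times) > 1 else \
        np.full(len(times), 19.0)
    rh = np.clip(45.0 + 8.0 * np.cos(2 * np.pi * t_min / max(t_min[-1], 1))
                 + rng.normal(0, 2.0, len(times)), 5, 95)

    rec = pd.DataFrame({"timestamp": times, "value": values,
                        "temperature": temp, "rh": rh})
    return ShiftSeries(logbook.day_id, gt.day_jobs[day_index], fraction, rec,
                       units="ug/m3", meta={"calibrated": False})


def _spectrum_weights(cfg: SimConfig, edges: np.ndarray) -> np.ndarray:
    """Channel share of the total number concentration (lognormal spectrum)."""
    from scipy.stats import norm
    l_edges = np.log10(edges)
    cdf = norm.cdf(l_edges, loc=np.log10(cfg.spectrum_mode_um),
                   scale=cfg.spectrum_sigma_log10)
    w = np.diff(cdf)
    return w / w.sum()


def simulate_number_series(cfg: SimConfig, logbook: Logbook,
                           gt: GroundTruth) -> tuple[ChannelSeries, ShiftSeries]:
    """Channelized OPC number series plus wide-range counter totals.

    Both instruments see the same latent smooth trend; the counter total
    exceeds the OPC 0.25–0.7 µm band total by ``cfg.number_factor``
    (ultrafine particles dominate the number concentration but are below
    the OPC's lower size cut).
    """
    edges = default_channel_edges(cfg.n_channels, cfg.channel_lo_um,
                                  cfg.channel_hi_um)
    if edges[0] != cfg.channel_lo_um or edges[-1] != cfg.channel_hi_um:
        raise ConfigurationError("bad channel grid")
    day_index = gt.day_ids.index(logbook.day_id)
    rng = cfg.rng("number", day_index)
    w = _spectrum_weights(cfg, edges)

    # OPC on the mass grid
    times = _mass_grid(cfg, logbook)
    t_min = (times - times[0]).total_seconds().to_numpy() / 60.0
    latent = 10.0 ** gt.trend(day_index, t_min)            # shared trend
    expect = cfg.number_base_total * np.outer(latent, w)   # (n_t, n_ch)
    noise = 10.0 ** rng.normal(0.0, cfg.number_noise_sd, expect.shape) \
        if cfg.number_noise_sd > 0 else 1.0
    channels = ChannelSeries(logbook.day_id, gt.day_jobs[day_index],
                             pd.Series(times), edges, expect * noise)

    # counter on its own (finer) grid, driven by the same latent trend
    n_c = cfg.shift_minutes * 60 // cfg.number_dt
    c_times = pd.DatetimeIndex(
        [times[0] + pd.Timedelta(seconds=int(k * cfg.number_dt))
         for k in range(n_c)])
    tc_min = (c_times - c_times[0]).total_seconds().to_numpy() / 60.0
    latent_c = 10.0 ** gt.trend(day_index, tc_min)
    bw = band_weights(edges, *cfg.counter_band_um)
    band_expect = cfg.number_base_total * float(w @ bw) * latent_c
    c_noise = 10.0 ** rng.normal(0.0, cfg.number_noise_sd, n_c) \
        if cfg.number_noise_sd > 0 else 1.0
    counter_vals = cfg.number_factor * band_expect * c_noise
    counter = ShiftSeries(
        logbook.day_id, gt.day_jobs[day_index], "number",
        pd.DataFrame({"timestamp": c_times, "value": counter_vals}),
        units="#/cm3", meta={"range_nm": (10, 700)})
    return channels, counter


def simulate_gravimetric(cfg: SimConfig, true_calibration: tuple,
                         raw_shift_series: ShiftSeries,
                         noise_sd: float | None = None) -> float:
    """Shift-level gravimetric value: a * (time-weighted raw mean)^b * noise."""
    a, b = true_calibration
    m = raw_shift_series.time_weighted_mean()
    if m <= 0:
        raise ConfigurationError("raw series must be positive")
    sd = cfg.grav_noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        day_index = int(raw_shift_series.day_id.lstrip("d")) - 1 \
            if raw_shift_series.day_id.startswith("d") else 0
        rng = cfg.rng("grav", day_index,
                      MASS_FRACTIONS.index(raw_shift_series.fraction)
                      if raw_shift_series.fraction in MASS_FRACTIONS else 99)
        noise = float(np.exp(rng.normal(0.0, sd)))
    else:
        noise = 1.0
    return float(a * m ** b * noise)


# ---------------------------------------------------------------------------
# whole-campaign assembly
# ---------------------------------------------------------------------------

@dataclass
class DayData:
    day_id: str
    job: str
    logbook: Logbook
    mass: dict                      # fraction -> ShiftSeries ({} if day dropped)
    channels: ChannelSeries | None
    counter: ShiftSeries | None
    gravimetric: dict               # fraction -> float (PM2.5/PM10 only)


@dataclass
class Dataset:
    config: SimConfig
    ground_truth: GroundTruth
    days: list[DayData]

    def mass_series(self, fraction: str) -> list[ShiftSeries]:
        return [d.mass[fraction] for d in self.days if fraction in d.mass]

    def logbooks(self) -> dict:
        return {d.day_id: d.logbook for d in self.days}

    def gravimetric_table(self) -> pd.DataFrame:
        rows = [
            {"day_id": d.day_id, "job": d.job, "fraction": f,
             "gravimetric": v,
             "raw_mean": d.mass[f].time_weighted_mean() if f in d.mass
             else np.nan,
             "mean_temperature": d.mass[f].records["temperature"].mean()
             if f in d.mass else np.nan,
             "mean_rh": d.mass[f].records["rh"].mean() if f in d.mass
             else np.nan}
            for d in self.days for f, v in d.gravimetric.items()
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out / "config.json")
        self.ground_truth.to_json(out / "ground_truth.json")
        for d in self.days:
            dd = out / d.day_id
            dd.mkdir(exist_ok=True)
            d.logbook.to_csv(dd / "logbook.csv")
            for f, s in d.mass.items():
                s.to_csv(dd / f"mass_{f.replace('.', '')}.csv")
            if d.channels is not None:
                d.channels.to_csv(dd / "opc_channels.csv")
            if d.counter is not None:
                d.counter.to_csv(dd / "counter.csv")
        self.gravimetric_table().to_csv(out / "gravimetric.csv", index=False)


def check_design_completeness(cfg: SimConfig,
                              logbooks: list[Logbook]) -> dict:
    """Categories of the design that never occur in the given logbooks."""
    seen_st, seen_env, seen_ev = set(), set(), set()
    for lb in logbooks:
        seen_st |= set(lb.intervals["station"])
        seen_env |= set(lb.intervals["environment"])
        seen_ev |= set(lb.events["event"])
    return {
        "stations": sorted(set(cfg.stations) - seen_st),
        "environments": sorted(set(cfg.environments) - seen_env),
        "events": sorted(set(cfg.events) - seen_ev),
    }


def generate_dataset(cfg: SimConfig, include_number: bool = True,
                     max_retries: int = 20) -> Dataset:
    """Generate the full campaign: logbooks, series, gravimetry, truth.

    Schedules are resampled (bounded retries) until every non-reference
    category of the design occurs in at least one logbook.
    """
    gt = make_ground_truth(cfg)
    logbooks = None
    for retry in range(max_retries):
        cand = [simulate_logbook(cfg, i, retry=retry)
                for i in range(cfg.n_days)]
        missing = check_design_completeness(cfg, cand)
        if not any(missing.values()):
            logbooks = cand
            break
    if logbooks is None:
        raise ConfigurationError(
            f"design not completable in {max_retries} retries; "
            f"missing {missing}")

    drop_rng = cfg.rng("truth", 1)
    dropped = set(drop_rng.choice(cfg.n_days, size=cfg.n_missing_days,
                                  replace=False)) if cfg.n_missing_days else set()

    days = []
    for i, lb in enumerate(logbooks):
        mass = {} if i in dropped else {
            f: simulate_mass_series(cfg, lb, gt, f) for f in MASS_FRACTIONS}
        channels = counter = None
        if include_number and i not in dropped:
            channels, counter = simulate_number_series(cfg, lb, gt)
        grav = {f: simulate_gravimetric(cfg, (cfg.grav_a, cfg.grav_b),
                                        mass[f])
                for f in ("PM2.5", "PM10") if f in mass}
        days.append(DayData(lb.day_id, cfg.day_job(i), lb, mass,
                            channels, counter, grav))
    return Dataset(cfg, gt, days)
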
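"""Inter-device comparison of particle number concentrations.

An optical particle counter reports channelized number concentrations on
31 log-spaced size channels (0.25–20 µm); a diffusion-charger counter
reports a single 10–700 nm total at much finer time resolution.  To
compare the two, the channelized series is integrated over the band where
the instruments' size ranges overlap (0.25–0.7 µm by default), the two
series are aligned onto the coarser time grid, and ratio/trend statistics
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, PmsplineError
from .logbook import ShiftSeries

__all__ = ["ChannelSeries", "default_channel_edges", "integrate_band",
           "align_series", "compare"]


def default_channel_edges(n_channels: int = 31, lo: float = 0.25,
                          hi: float = 20.0) -> np.ndarray:
    """Log-spaced channel edges (µm); n_channels channels need n+1 edges."""
    return np.geomspace(lo, hi, n_channels + 1)


@dataclass
class ChannelSeries:
    """Channelized number-concentration time-series (#/cm³ per channel)."""

    day_id: str
    job: str
    timestamps: pd.Series            # datetime64, strictly increasing
    edges: np.ndarray                # (n_channels + 1,) µm, strictly increasing
    values: np.ndarray               # (n_times, n_channels), >= 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ConfigurationError("channel edges must be strictly increasing")
        if self.values.shape != (len(self.timestamps), len(self.edges) - 1):
            raise ConfigurationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.timestamps)} times x {len(self.edges) - 1} channels"
            )
        if np.any(self.values < 0):
            raise ConfigurationError("channel concentrations must be >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.edges) - 1

    def to_csv(self, path) -> None:
        cols = {f"ch_{lo:.4g}_{hi:.4g}": self.values[:, i]
                for i, (lo, hi) in enumerate(zip(self.edges[:-1], self.edges[1:]))}
        pd.DataFrame({"timestamp": self.timestamps, **cols}).to_csv(
            path, index=False, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path, day_id: str, job: str) -> "ChannelSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        ch_cols = [c for c in df.columns if c.startswith("ch_")]
        edges = [float(c.split("_")[1]) for c in ch_cols]
        edges.append(float(ch_cols[-1].split("_")[2]))
        return cls(day_id, job, df["timestamp"], np.array(edges),
                   df[ch_cols].to_numpy())


def band_weights(edges: np.ndarray, lo: float, hi: float,
                 mode: str = "prorata") -> np.ndarray:
    """Per-channel inclusion weights for the band [lo, hi].

    ``prorata``: a channel partially overlapping the band contributes the
    fraction of its log-diameter width inside the band (aerosol channels
    are log-spaced, and a locally flat dN/dlogD is the natural neutral
    assumption).  ``nearest``: a channel is included iff its midpoint (in
    log diameter) lies inside the band.
    """
    if hi <= lo:
        raise ConfigurationError(f"empty band [{lo}, {hi}]")
    log_e = np.log(edges)
    l_lo, l_hi = np.log(lo), np.log(hi)
    if mode == "prorata":
        upper = np.minimum(log_e[1:], l_hi)
        lower = np.maximum(log_e[:-1], l_lo)
        w = np.clip(upper - lower, 0.0, None) / np.diff(log_e)
    elif mode == "nearest":
        mid = 0.5 * (log_e[:-1] + log_e[1:])
        w = ((mid >= l_lo) & (mid < l_hi)).astype(float)
    else:
        raise ConfigurationError(f"unknown edge mode {mode!r}")
    if w.sum() == 0:
        raise ConfigurationError(
            f"band [{lo}, {hi}] does not overlap channels "
            f"[{edges[0]}, {edges[-1]}]")
    return w


def integrate_band(cs: ChannelSeries, lo: float, hi: float,
                   mode: str = "prorata") -> ShiftSeries:
    """Total number concentration in the size band [lo, hi] µm.

    Channels fully inside the band contribute in full; edge channels
    pro-rata by log-width fraction (or all-or-nothing with
    ``mode='nearest'``).
    """
    w = band_weights(cs.edges, lo, hi, mode)
    total = cs.values @ w
    rec = pd.DataFrame({"timestamp": cs.timestamps, "value": total})
    return ShiftSeries(cs.day_id, cs.job, "number", rec, units="#/cm3",
                       meta={"band_um": (lo, hi), "edge_mode": mode})


def _grid_dt(ts: pd.Series) -> float:
    d = ts.diff().dt.total_seconds().dropna()
    if d.empty:
        raise PmsplineError("cannot infer grid from a single record")
    return float(d.median())


def align_series(a: ShiftSeries, b: ShiftSeries) -> pd.DataFrame:
    """Pair two series on the coarser of their two time grids.

    The finer series is averaged into the coarser grid's half-open
    windows [t, t + dt); window pairs with a missing member are dropped
    (count in ``df.attrs['n_dropped']``).  Returns a frame indexed by
    window start with columns ``a`` and ``b``.
    """
    dt_a, dt_b = _grid_dt(a.timestamps), _grid_dt(b.timestamps)
    coarse, fine, flip = (a, b, False) if dt_a >= dt_b else (b, a, True)
    dt = pd.Timedelta(seconds=max(dt_a, dt_b))

    grid = coarse.timestamps
    lo = max(grid.iloc[0], fine.timestamps.iloc[0])
    hi = min(grid.iloc[-1] + dt, fine.timestamps.iloc[-1] + dt)
    if hi <= lo:
        raise PmsplineError("series have no overlapping time span")

    win = pd.cut(fine.timestamps,
                 bins=pd.DatetimeIndex(list(grid) + [grid.iloc[-1] + dt]),
                 right=False, labels=grid)
    fine_mean = (pd.Series(fine.values, index=win.values)
                 .groupby(level=0, observed=True).mean())

    coarse_s = pd.Series(coarse.values, index=pd.DatetimeIndex(grid))
    df = pd.DataFrame({"coarse": coarse_s, "fine": fine_mean}).dropna()
    if df.empty:
        raise PmsplineError("no paired windows after alignment")
    out = pd.DataFrame({
        "a": df["fine"] if flip else df["coarse"],
        "b": df["coarse"] if flip else df["fine"],
    })
    out.attrs["n_dropped"] = len(coarse_s) - len(df)
    out.attrs["window_seconds"] = dt.total_seconds()
    return out


def compare(paired: pd.DataFrame) -> dict:
    """Ratio/trend statistics for a paired two-device table.

    Returns the ratio of totals (b/a), the Pearson correlation of log10
    values, and the sign-agreement rate of first differences.  The
    correlation is reported as NaN when either log-series is degenerate.
    """
    if len(paired) < 3:
        raise PmsplineError("need at least 3 paired records")
    a = paired["a"].to_numpy(dtype=float)
    b = paired["b"].to_numpy(dtype=float)
    ratio = float(b.sum() / a.sum())

    la, lb = np.log10(a), np.log10(b)
    if np.std(la) == 0 or np.std(lb) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(la, lb).statistic)

    da, db = np.sign(np.diff(a)), np.sign(np.diff(b))
    sign_agreement = float(np.mean(da == db))
    return {
        "ratio_of_totals": ratio,
        "pearson_r_log10": r,
        "sign_agreement": sign_agreement,
        "n_pairs": len(paired),
    }
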
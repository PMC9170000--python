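"""Reported exposure quantities: fold changes, GM/GSD tables, correlations.

Because the model works on the log10 scale, a category coefficient c is
reported as the fold change 10^c — the multiplicative concentration
change relative to the reference category.  A category is *elevated*
when the lower bound of its 95% credible fold-change interval exceeds 1,
and *borderline* when that bound falls just short of 1 by a small
configurable margin.

Raw and calibrated series are summarised with the geometric mean and
geometric standard deviation, the natural summaries of lognormal
exposure data; station-level coefficients are related to station
covariates with plain Pearson correlations (deliberately uncorrected
for multiple comparisons — this is an exploratory screen).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PmsplineError
from .logbook import ShiftSeries
from .model import PosteriorDraws

__all__ = ["EffectSummary", "StationMetadata", "fold_change_summary",
           "flag_elevated", "gm_gsd", "station_correlations",
           "design_type_means"]

BORDERLINE_DELTA = 0.02

#: numeric covariates of the station metadata table
STATION_COVARIATES = ("year_opened", "year_renovated", "annual_passengers",
                      "n_ventilators", "n_entrances",
                      "n_correspondence_concourses", "n_platforms_tracks",
                      "min_altitude")


@dataclass
class EffectSummary:
    """Posterior fold change of one category relative to the reference."""

    category: str
    block: str                      # station | environment | event
    fraction: str
    fold_change_median: float
    ci_low: float
    ci_high: float
    elevated: bool
    borderline: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.fold_change_median <= self.ci_high):
            raise PmsplineError(
                f"{self.category}: interval [{self.ci_low}, {self.ci_high}] "
                f"does not bracket median {self.fold_change_median}")


@dataclass
class StationMetadata:
    """Per-station covariates used in the correlation screen."""

    station: str
    year_opened: int | None = None
    year_renovated: int | None = None
    annual_passengers: float | None = None
    n_ventilators: int | None = None
    n_entrances: int | None = None
    n_correspondence_concourses: int | None = None
    n_platforms_tracks: int | None = None
    design_type: str | None = None      # A..G
    min_altitude: float | None = None

    def __post_init__(self) -> None:
        for y in (self.year_opened, self.year_renovated):
            if y is not None and not 1850 <= y <= 2100:
                raise PmsplineError(f"implausible year {y} for {self.station}")
        for f in ("annual_passengers", "n_ventilators", "n_entrances",
                  "n_correspondence_concourses", "n_platforms_tracks"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise PmsplineError(f"negative {f} for {self.station}")


def metadata_table(rows: list[StationMetadata]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows]).set_index("station")


def fold_change_summary(draws: PosteriorDraws, block: str,
                        fraction: str = "", interval: float = 0.95
                        ) -> list[EffectSummary]:
    """Fold-change summaries 10^(coefficient quantiles) for one block.

    The reference category (first level of the station and environment
    blocks) has all its draws pinned at 0, so its summary is exactly
    (1, 1, 1).
    """
    levels, flat = draws.effect_block(block)
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    out = []
    for j, name in enumerate(levels):
        lo, med, hi = 10.0 ** np.quantile(flat[:, j], [lo_q, 0.5, hi_q])
        out.append(EffectSummary(
            category=name, block=block, fraction=fraction,
            fold_change_median=float(med), ci_low=float(lo),
            ci_high=float(hi), elevated=bool(lo > 1.0),
            borderline=bool(1.0 - BORDERLINE_DELTA < lo <= 1.0)))
    return out


def summary_table(summaries: list[EffectSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def flag_elevated(summaries: list[EffectSummary],
                  delta: float = BORDERLINE_DELTA,
                  subset: list[str] | None = None
                  ) -> tuple[list[EffectSummary], list[EffectSummary]]:
    """Split summaries into elevated and borderline sets.

    Elevated: 95% CI lower bound > 1.  Borderline: lower bound within
    ``delta`` below 1.  ``subset`` restricts the scan to named
    categories (e.g. the physical stations of one line, excluding
    Tunnel).
    """
    pool = [s for s in summaries
            if subset is None or s.category in subset]
    elevated = [s for s in pool if s.ci_low > 1.0]
    borderline = [s for s in pool if 1.0 - delta < s.ci_low <= 1.0]
    return elevated, borderline


def gm_gsd(series_list: list[ShiftSeries], grouping: str = "day"
           ) -> pd.DataFrame:
    """Geometric mean and geometric SD per group and fraction.

    GM = exp(mean(ln y)), GSD = exp(sd(ln y)); groups with fewer than two
    records get a missing GSD.
    """
    if grouping not in ("day", "job"):
        raise PmsplineError("grouping must be 'day' or 'job'")
    rows = []
    key = (lambda s: s.day_id) if grouping == "day" else (lambda s: s.job)
    pooled: dict = {}
    for s in series_list:
        v = s.values
        if np.any(v <= 0):
            raise PmsplineError(f"non-positive values in {s.day_id}")
        pooled.setdefault((key(s), s.fraction), []).append(np.log(v))
    for (group, fraction), logs in sorted(pooled.items()):
        x = np.concatenate(logs)
        gm = float(np.exp(x.mean()))
        gsd = float(np.exp(x.std(ddof=1))) if len(x) > 1 else np.nan
        rows.append({grouping: group, "fraction": fraction,
                     "GM": gm, "GSD": gsd, "n": len(x)})
    return pd.DataFrame(rows)


def station_correlations(effect_summaries: list[EffectSummary],
                         metadata: pd.DataFrame,
                         covariates: tuple = STATION_COVARIATES
                         ) -> pd.DataFrame:
    """Pearson r between station log10 coefficients and each covariate.

    The coefficient point estimate is log10 of the posterior-median fold
    change.  Stations missing a covariate are dropped pairwise; a
    zero-variance covariate yields a missing r.  No multiple-testing
    correction is applied.
    """
    st = [s for s in effect_summaries if s.block == "station"]
    coef = pd.Series({s.category: np.log10(s.fold_change_median)
                      for s in st})
    common = coef.index.intersection(metadata.index)
    if len(common) < 3:
        raise PmsplineError("need >= 3 stations with coefficient + metadata")
    rows = []
    for cov in covariates:
        if cov not in metadata.columns:
            continue
        x = pd.to_numeric(metadata.loc[common, cov], errors="coerce")
        mask = x.notna()
        r = p = np.nan
        n = int(mask.sum())
        if n >= 3 and np.std(x[mask].to_numpy(float)) > 0 \
                and np.std(coef[common][mask].to_numpy(float)) > 0:
            res = stats.pearsonr(coef[common][mask], x[mask])
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({"covariate": cov, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def design_type_means(effect_summaries: list[EffectSummary],
                      metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean fold change per station design type (A..G)."""
    st = {s.category: s.fold_change_median for s in effect_summaries
          if s.block == "station"}
    df = pd.DataFrame({"fold_change": pd.Series(st)})
    df = df.join(metadata["design_type"], how="inner")
    return (df.groupby("design_type")["fold_change"]
            .agg(["mean", "count"]).reset_index())
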
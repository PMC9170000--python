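"""Calibration of real-time optical mass concentrations against gravimetry.

Optical particle counters infer mass from scattered light and routinely
under- or over-estimate true (filter-based) mass depending on aerosol
density and refractive index.  The standard remedy is an empirical
shift-level regression of gravimetric values on the instrument's shift
mean.  Three candidate families are provided; the selection rule keeps
the family with the highest coefficient of determination computed on the
original concentration scale (so the families are comparable; an R²
computed after a log transform would structurally favour the power law):

* power:        g = a · m^b          (fitted by OLS on the log–log scale)
* linear:       g = a · m + c
* exponential:  g = a · exp(b · m)   (fitted by OLS on the semi-log scale)

Only PM2.5 and PM10 can be calibrated — there is no gravimetric
measurement standard for the PM1 and PM0.3 fractions, so requesting them
raises :class:`UnsupportedFractionError`.  The power model optionally
takes additive log-temperature / log-relative-humidity terms (off by
default; the appropriate functional form for the covariates is an open
choice, documented rather than asserted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, UnsupportedFractionError
from .logbook import ShiftSeries

__all__ = ["CalibrationFit", "fit_calibration", "select_family",
           "apply_calibration", "CALIBRATABLE_FRACTIONS", "FAMILIES"]

CALIBRATABLE_FRACTIONS = ("PM2.5", "PM10")
FAMILIES = ("power", "linear", "exponential")

#: R² ties are broken by this preference order (power first), then by
#: parameter count
_TIE_ORDER = {"power": 0, "linear": 1, "exponential": 2}
_R2_TIE_TOL = 1e-9


@dataclass
class CalibrationFit:
    """A fitted raw-to-gravimetric transfer function for one fraction."""

    family: str
    fraction: str
    parameters: dict                 # a, b/c, optional t_coef, rh_coef
    r2: float
    n_shifts: int
    covariates: tuple = ()

    def predict(self, raw: np.ndarray, temperature=None, rh=None) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        p = self.parameters
        if self.family == "power":
            out = np.log(p["a"]) + p["b"] * np.log(raw)
            if "t_coef" in p:
                if temperature is None:
                    raise CalibrationError("fit uses temperature covariate")
                out = out + p["t_coef"] * np.log(np.asarray(temperature, float))
            if "rh_coef" in p:
                if rh is None:
                    raise CalibrationError("fit uses RH covariate")
                out = out + p["rh_coef"] * np.log(np.asarray(rh, float))
            return np.exp(out)
        if self.family == "linear":
            return p["a"] * raw + p["c"]
        if self.family == "exponential":
            return p["a"] * np.exp(p["b"] * raw)
        raise CalibrationError(f"unknown family {self.family!r}")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["covariates"] = list(d["covariates"])
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationFit":
        d = json.loads(Path(path).read_text())
        d["covariates"] = tuple(d["covariates"])
        return cls(**d)


def _check_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    need = {"raw", "gravimetric"}
    if not need.issubset(pairs.columns):
        raise CalibrationError(f"pairs table needs columns {need}")
    df = pairs.dropna(subset=["raw", "gravimetric"])
    if len(df) < 3:
        raise CalibrationError("need at least 3 shift-level pairs")
    if (df["raw"] <= 0).any() or (df["gravimetric"] <= 0).any():
        raise CalibrationError("raw and gravimetric values must be > 0")
    if np.ptp(df["raw"].to_numpy()) == 0:
        raise CalibrationError("degenerate pairs: zero variance in raw values")
    return df


def _r2_original_scale(g: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((g - pred) ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    if ss_tot == 0:
        # zero-variance target carries no calibration information
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_calibration(pairs: pd.DataFrame, family: str, fraction: str = "PM10",
                    covariates: tuple = ()) -> CalibrationFit:
    """Fit one regression family to shift-level (raw, gravimetric) pairs.

    ``pairs`` needs columns ``raw`` and ``gravimetric`` (µg/m³); columns
    ``temperature``/``rh`` are required when listed in ``covariates``
    (power family only).  R² is evaluated on the original scale.
    """
    if fraction not in CALIBRATABLE_FRACTIONS:
        raise UnsupportedFractionError(
            f"no gravimetric measurement standard for {fraction}; only "
            f"{CALIBRATABLE_FRACTIONS} can be calibrated")
    if family not in FAMILIES:
        raise CalibrationError(f"family must be one of {FAMILIES}")
    if covariates and family != "power":
        raise CalibrationError("T/RH covariates only supported for power")
    df = _check_pairs(pairs)
    m = df["raw"].to_numpy(dtype=float)
    g = df["gravimetric"].to_numpy(dtype=float)

    if family == "power":
        cols = [np.ones_like(m), np.log(m)]
        names = ["log_a", "b"]
        for cov, key in (("temperature", "t_coef"), ("rh", "rh_coef")):
            if cov in covariates:
                if cov not in df.columns:
                    raise CalibrationError(f"covariate column {cov!r} missing")
                cols.append(np.log(df[cov].to_numpy(dtype=float)))
                names.append(key)
        A = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(A, np.log(g), rcond=None)
        params = {"a": float(np.exp(coef[0])), "b": float(coef[1])}
        params.update({k: float(v) for k, v in zip(names[2:], coef[2:])})
        kw = {}
        if "t_coef" in params:
            kw["temperature"] = df["temperature"].to_numpy(float)
        if "rh_coef" in params:
            kw["rh"] = df["rh"].to_numpy(float)
        fit = CalibrationFit("power", fraction, params, 0.0, len(df),
                             tuple(covariates))
        pred = fit.predict(m, **kw)
    elif family == "linear":
        A = np.column_stack([m, np.ones_like(m)])
        coef, *_ = np.linalg.lstsq(A, g, rcond=None)
        params = {"a": float(coef[0]), "c": float(coef[1])}
        fit = CalibrationFit("linear", fraction, params, 0.0, len(df))
        pred = fit.predict(m)
    else:  # exponential, OLS on log gravimetric
        A = np.column_stack([np.ones_like(m), m])
        coef, *_ = np.linalg.lstsq(A, np.log(g), rcond=None)
        params = {"a": float(np.exp(coef[0])), "b": float(coef[1])}
        fit = CalibrationFit("exponential", fraction, params, 0.0, len(df))
        pred = fit.predict(m)

    fit.r2 = _r2_original_scale(g, pred)
    return fit


def select_family(pairs: pd.DataFrame, fraction: str = "PM10",
                  covariates: tuple = ()) -> CalibrationFit:
    """Fit all families and keep the best by original-scale R².

    Ties (within 1e-9) prefer the power family, then fewer parameters.
    """
    fits, errors = [], []
    for fam in FAMILIES:
        try:
            fits.append(fit_calibration(pairs, fam, fraction,
                                        covariates if fam == "power" else ()))
        except CalibrationError as exc:
            errors.append(f"{fam}: {exc}")
    if not fits:
        raise CalibrationError("all families failed: " + "; ".join(errors))
    return min(fits, key=lambda f: (-round(f.r2 / _R2_TIE_TOL) * _R2_TIE_TOL,
                                    _TIE_ORDER[f.family],
                                    len(f.parameters)))


def apply_calibration(series: ShiftSeries, fit: CalibrationFit) -> ShiftSeries:
    """Transform every record of a raw series through the fitted function.

    Records mapped to non-positive values (possible for the linear family
    with a negative intercept) are dropped and counted in
    ``meta['n_dropped_calibration']``.
    """
    if series.fraction not in CALIBRATABLE_FRACTIONS:
        raise UnsupportedFractionError(
            f"series fraction {series.fraction} cannot be calibrated")
    if fit.fraction != series.fraction:
        raise CalibrationError(
            f"fit is for {fit.fraction}, series is {series.fraction}")
    rec = series.records.copy()
    kw = {}
    if "t_coef" in fit.parameters:
        kw["temperature"] = rec["temperature"].to_numpy(float)
    if "rh_coef" in fit.parameters:
        kw["rh"] = rec["rh"].to_numpy(float)
    rec["value"] = fit.predict(rec["value"].to_numpy(float), **kw)
    keep = rec["value"] > 0
    n_drop = int((~keep).sum())
    rec = rec.loc[keep].reset_index(drop=True)
    meta = dict(series.meta, calibrated=True, calibration_family=fit.family,
                calibration_parameters=dict(fit.parameters),
                n_dropped_calibration=n_drop)
    return ShiftSeries(series.day_id, series.job, series.fraction, rec,
                       units=series.units, meta=meta)
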
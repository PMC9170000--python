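"""MCMC validation: convergence, autocorrelation, sensitivity, prediction.

Implements the structured validation protocol applied to the exposure
model: the Gelman–Rubin potential scale reduction factor for every
monitored parameter, sample autocorrelation at lags 1–20, a prior
sensitivity analysis that refits the model with the effect-prior
standard deviation moved from its default to smaller and larger values,
and a posterior predictive check comparing observed records against
their 95% predictive intervals.  Trace and density material is exported
as plain data tables suitable for plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateChainError, PmsplineError
from .logbook import DesignMatrices
from .model import Model, ModelSpec, PosteriorDraws, build_model, fit, predict

__all__ = ["gelman_rubin", "autocorrelation", "sensitivity_analysis",
           "posterior_predictive_check", "DiagnosticsReport", "wambs_report"]

#: conventional convergence threshold on R-hat
RHAT_THRESHOLD = 1.1
#: a parameter is flagged as prior-sensitive when its posterior median
#: moves by more than this many posterior SDs between prior settings
SENSITIVITY_THRESHOLD = 0.5


def gelman_rubin(chains: np.ndarray, variant: str = "classic") -> float:
    """Potential scale reduction factor R-hat from >= 2 equal-length chains.

    ``classic`` is the original between/within comparison: with m chains
    of length n, W the mean within-chain variance and B/n the variance of
    the chain means,

        Vhat = (n - 1)/n * W + B/n,    R-hat = sqrt(Vhat / W).

    ``split`` halves every chain first (more sensitive to trends within
    a chain).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise PmsplineError("need a (m >= 2, n) array of chains")
    if chains.shape[1] < 4:
        raise PmsplineError("chains too short (need length >= 4)")
    if variant == "split":
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half: 2 * half]])
    elif variant != "classic":
        raise PmsplineError(f"unknown variant {variant!r}")
    m, n = chains.shape
    within = chains.var(axis=1, ddof=1)
    if np.all(within == 0):
        raise DegenerateChainError("zero within-chain variance in all chains")
    W = float(within.mean())
    B_over_n = float(chains.mean(axis=1).var(ddof=1))
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def autocorrelation(samples: np.ndarray, max_lag: int = 20) -> np.ndarray:
    """Sample autocorrelation function at lags 1..max_lag.

    Lag-adjusted estimator: gamma(k)/gamma(0) with
    gamma(k) = (1/(n-k)) sum (x_t - xbar)(x_{t+k} - xbar), so a perfectly
    anti-periodic series has acf(1) exactly -1.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise PmsplineError("samples must be 1-d")
    n = len(x)
    if n <= max_lag:
        raise PmsplineError(f"need more than {max_lag} samples, got {n}")
    x = x - x.mean()
    g0 = float(x @ x) / n
    if g0 == 0:
        raise DegenerateChainError("constant series: ACF undefined")
    return np.array([float(x[:-k] @ x[k:]) / (n - k) / g0
                     for k in range(1, max_lag + 1)])


@dataclass
class DiagnosticsReport:
    """Aggregated validation results with pass/fail flags."""

    rhat: dict                        # parameter -> R-hat
    rhat_threshold: float
    converged: bool
    skipped_degenerate: list          # parameters with zero variance
    acf: dict                         # parameter -> list of lag-1..20 values
    max_abs_acf_lag1: float
    sensitivity: dict | None          # from sensitivity_analysis
    ppc: dict | None                  # from posterior_predictive_check
    passed: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def compute_rhat_table(draws: PosteriorDraws,
                       variant: str = "classic") -> tuple[dict, list]:
    """R-hat per monitored parameter; degenerate (constant) ones listed."""
    rhat, skipped = {}, []
    for name, arr in draws.monitored().items():
        try:
            rhat[name] = gelman_rubin(arr, variant=variant)
        except DegenerateChainError:
            skipped.append(name)
    return rhat, skipped


def sensitivity_analysis(design: DesignMatrices, base_spec: ModelSpec,
                         alt_sds: tuple = (3.0, 10.0),
                         threshold: float = SENSITIVITY_THRESHOLD,
                         base_draws: PosteriorDraws | None = None) -> dict:
    """Refit with alternative effect-prior SDs and compare effect posteriors.

    For every station/environment/event coefficient, reports
    |median_alt - median_base| / SD_base, and flags parameters exceeding
    ``threshold``.  A coefficient that moves with the prior is
    prior-dominated (typically a category with little or no data).
    """
    if base_draws is None:
        base_draws = fit(build_model(design, base_spec), base_spec)

    def effect_table(draws):
        names, meds, sds = [], [], []
        for block in ("station", "environment", "event"):
            levels, flat = draws.effect_block(block)
            start = 1 if block in ("station", "environment") else 0
            for j in range(start, len(levels)):
                names.append(f"{block}:{levels[j]}")
                meds.append(float(np.median(flat[:, j])))
                sds.append(float(np.std(flat[:, j])))
        return names, np.array(meds), np.array(sds)

    names, base_med, base_sd = effect_table(base_draws)
    deltas, flagged = {}, set()
    for s in alt_sds:
        alt_spec = replace(base_spec, effect_prior_sd=float(s))
        alt_draws = fit(build_model(design, alt_spec), alt_spec)
        _, alt_med, _ = effect_table(alt_draws)
        rel = np.abs(alt_med - base_med) / np.where(base_sd > 0, base_sd,
                                                    np.inf)
        deltas[f"sd={s:g}"] = dict(zip(names, rel.tolist()))
        flagged |= {n for n, v in zip(names, rel) if v > threshold}
    return {
        "base_sd": base_spec.effect_prior_sd,
        "alternative_sds": list(alt_sds),
        "threshold": threshold,
        "deltas": deltas,
        "flagged": sorted(flagged),
        "max_delta": max((max(d.values()) for d in deltas.values()),
                         default=0.0),
    }


def posterior_predictive_check(model: Model, draws: PosteriorDraws,
                               observed: np.ndarray,
                               interval: float = 0.95) -> dict:
    """Coverage of observed log10 records by their predictive intervals.

    ``observed`` must align record-for-record with the model design.
    Returns the coverage fraction plus an exportable observed-vs-
    predicted table.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise PmsplineError("no observed records")
    if len(observed) != model.n:
        raise PmsplineError(
            f"observed has {len(observed)} records, design has {model.n}")
    pp = predict(model, draws, model.design, interval=interval)
    inside = (observed >= pp["lo_log10"].to_numpy()) & \
             (observed <= pp["hi_log10"].to_numpy())
    table = pp.assign(observed_log10=observed, inside=inside)
    return {
        "coverage": float(inside.mean()),
        "interval": interval,
        "n_records": int(len(observed)),
        "table": table,
    }


def trace_tables(draws: PosteriorDraws, parameters: list[str] | None = None
                 ) -> pd.DataFrame:
    """Long-format trace export (chain, draw, parameter, value)."""
    mon = draws.monitored()
    parameters = list(mon) if parameters is None else parameters
    frames = []
    for name in parameters:
        arr = mon[name]
        c, d = arr.shape
        frames.append(pd.DataFrame({
            "chain": np.repeat(np.arange(c), d),
            "draw": np.tile(np.arange(d), c),
            "parameter": name, "value": arr.reshape(-1)}))
    return pd.concat(frames, ignore_index=True)


def wambs_report(model: Model, draws: PosteriorDraws,
                 observed: np.ndarray | None = None,
                 run_sensitivity: bool = False,
                 rhat_variant: str = "classic") -> DiagnosticsReport:
    """Assemble the full validation report (deterministic given draws)."""
    rhat, skipped = compute_rhat_table(draws, variant=rhat_variant)
    converged = all(v < RHAT_THRESHOLD for v in rhat.values())

    acf = {}
    for name, arr in draws.monitored().items():
        pooled = arr[0]  # first chain, post burn-in
        if np.std(pooled) > 0 and len(pooled) > 20:
            acf[name] = autocorrelation(pooled).tolist()
    max_acf1 = max((abs(v[0]) for v in acf.values()), default=0.0)

    sens = None
    if run_sensitivity:
        sens = sensitivity_analysis(model.design, model.spec,
                                    base_draws=draws)
        sens = {k: v for k, v in sens.items() if k != "deltas"}

    ppc = None
    if observed is not None:
        ppc = posterior_predictive_check(model, draws, observed)
        ppc = {k: v for k, v in ppc.items() if k != "table"}

    passed = converged and (ppc is None or ppc["coverage"] > 0.8) and \
        (sens is None or not sens["flagged"])
    return DiagnosticsReport(
        rhat=rhat, rhat_threshold=RHAT_THRESHOLD, converged=converged,
        skipped_degenerate=skipped, acf=acf, max_abs_acf_lag1=max_acf1,
        sensitivity=sens, ppc=ppc, passed=passed)
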
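"""Hierarchical Bayesian spline regression for log10 exposure series.

The observation model for record r of monitored day i is

    log10 Y_ir ~ N( mu_i + x'_station alpha + x'_env beta + x'_event gamma
                    + zeta_i' b(t_ir),  sigma2_i )

with a day-specific intercept mu_i ~ N(m_job(i), tau2_job(i)) absorbing
the job random effect, a day-specific residual variance sigma2_i, and a
per-day cubic B-spline trend zeta_i' b(t_ir).  Station and environment
effects are reference-coded (the reference coefficient is fixed at 0);
event effects are 0/1 indicators shared across days.

Priors: alpha, beta, gamma ~ N(0, s^2) with s configurable (default 5,
sensitivity variants 3 and 10); m_j ~ N(0, 10^2); sigma2_i, tau2_j and
the common spline-coefficient variance sigma2_zeta get weakly
informative Inverse-Gamma(0.01, 0.01) priors in the BUGS tradition.

The sampler is a blocked Gibbs sampler: every full conditional is
conjugate (Normal for the location blocks, Inverse-Gamma for the
variances), so no tuning is required and draws are exact MCMC
transitions.  The spline basis is column-centred within each day, which
removes the constant direction from the trend and makes mu_i
identifiable next to zeta_i.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, InitializationError,
                     ModelConstructionError, PredictionError)
from .logbook import DesignMatrices
from .splines import bspline_basis, n_basis_functions

__all__ = ["ModelSpec", "Model", "PosteriorDraws", "build_model", "fit",
           "predict", "spline_basis", "count_monitored_parameters"]


def spline_basis(t, spec: "ModelSpec", lo: float = 0.0,
                 hi: float | None = None) -> np.ndarray:
    """Cubic B-spline trend basis b(t) at within-shift minutes ``t``.

    Rows are non-negative and sum to 1 (partition of unity) on the
    interior of [lo, hi].
    """
    if hi is None:
        hi = float(np.max(np.atleast_1d(t)))
    return bspline_basis(t, lo, hi, spec.n_interior_knots, spec.spline_degree)


@dataclass
class ModelSpec:
    """Priors, spline definition, category levels and chain settings."""

    effect_prior_sd: float = 5.0        # s of N(0, s^2) on alpha/beta/gamma
    job_mean_prior_sd: float = 10.0
    var_prior_shape: float = 0.01       # Inverse-Gamma(shape, rate)
    var_prior_rate: float = 0.01
    n_interior_knots: int = 8
    spline_degree: int = 3
    chains: int = 3
    iterations: int = 10000
    burn_in: int = 5000
    thin: int = 1
    seed: int = 0
    init_jitter: float = 0.1
    store_zeta: bool = True
    use_trend: bool = True       # False: drop the spline term entirely
    # category levels; filled from the design by build_model
    stations: list[str] | None = None
    environments: list[str] | None = None
    events: list[str] | None = None
    day_ids: list[str] | None = None
    jobs: list[str] | None = None

    def __post_init__(self) -> None:
        if self.effect_prior_sd <= 0:
            raise ConfigurationError("effect prior SD must be > 0")
        if self.burn_in >= self.iterations:
            raise ConfigurationError("burn_in must be < iterations")
        if min(self.chains, self.thin) < 1:
            raise ConfigurationError("chains and thin must be >= 1")

    def with_design(self, design: DesignMatrices) -> "ModelSpec":
        return replace(self, stations=list(design.stations),
                       environments=list(design.environments),
                       events=list(design.events),
                       day_ids=list(design.day_ids),
                       jobs=list(design.jobs))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def count_monitored_parameters(spec: ModelSpec) -> int:
    """Number of parameters tracked for convergence checking.

    All station, environment and event coefficients (the reference
    coefficients counted as explicit zero-valued entries), the per-day
    intercepts and variances, and the per-job intercept and variance
    hyperparameters.  The many spline coefficients are excluded.
    """
    for f in ("stations", "environments", "events", "day_ids", "jobs"):
        if getattr(spec, f) is None:
            raise ConfigurationError(f"spec.{f} not set; use with_design()")
    return (len(spec.stations) + len(spec.environments) + len(spec.events)
            + 2 * len(spec.day_ids) + 2 * len(spec.jobs))


class Model:
    """Bound design + spec: precomputed blocks, densities and layout."""

    def __init__(self, design: DesignMatrices, spec: ModelSpec):
        spec = spec.with_design(design) if spec.stations is None else spec
        for ours, theirs in ((spec.stations, design.stations),
                             (spec.environments, design.environments),
                             (spec.events, design.events),
                             (spec.day_ids, design.day_ids)):
            if list(ours) != list(theirs):
                raise ModelConstructionError(
                    "spec and design category sets differ")
        self.design = design
        self.spec = spec
        self.y = np.asarray(design.y, dtype=float)
        self.n = len(self.y)
        self.n_days = len(design.day_ids)
        self.n_jobs = len(design.jobs)
        self.day_jobs = np.asarray(design.day_jobs, dtype=int)

        self.X = np.hstack([design.X_station, design.X_environment,
                            design.X_event])
        self.p_station = design.X_station.shape[1]
        self.p_env = design.X_environment.shape[1]
        self.p_event = design.X_event.shape[1]
        self.p = self.X.shape[1]

        # contiguous per-day record slices (design rows are day-sorted)
        di = design.day_idx
        if np.any(np.diff(di) < 0):
            raise ModelConstructionError("design rows must be day-sorted")
        bounds = np.searchsorted(di, np.arange(self.n_days + 1))
        self.day_slices = [slice(bounds[i], bounds[i + 1])
                           for i in range(self.n_days)]
        if any(s.stop == s.start for s in self.day_slices):
            raise ModelConstructionError("every day needs >= 1 record")
        self.day_idx = di

        # per-day centred spline bases on the day's own time span
        self.nb = n_basis_functions(spec.n_interior_knots, spec.spline_degree)
        self.day_domain, self.B, self.BtB, self.B_colmeans = [], [], [], []
        for s in self.day_slices:
            t = design.t[s]
            hi = max(float(t.max()), 1e-6)
            Bi = bspline_basis(t, 0.0, hi, spec.n_interior_knots,
                               spec.spline_degree)
            cm = Bi.mean(axis=0)
            self.day_domain.append(hi)
            self.B_colmeans.append(cm)
            self.B.append(Bi - cm)
            self.BtB.append(self.B[-1].T @ self.B[-1])
        # stacked per-day Gram matrices of the fixed-effect block
        self.G = np.stack([self.X[s].T @ self.X[s] for s in self.day_slices]) \
            if self.p else np.zeros((self.n_days, 0, 0))
        self.day_counts = np.array([s.stop - s.start for s in self.day_slices])

    # -- densities -------------------------------------------------------

    def _mean(self, params: dict) -> np.ndarray:
        theta = np.concatenate([
            np.asarray(params["alpha"], float)[1:],
            np.asarray(params["beta"], float)[1:],
            np.asarray(params["gamma"], float),
        ])
        mean = np.asarray(params["mu_day"], float)[self.day_idx]
        if self.p:
            mean = mean + self.X @ theta
        zeta = params.get("zeta")
        if zeta is not None:
            zeta = np.asarray(zeta, float)
            trend = np.empty(self.n)
            for i, s in enumerate(self.day_slices):
                trend[s] = self.B[i] @ zeta[i]
            mean = mean + trend
        return mean

    def log_likelihood(self, params: dict) -> float:
        """Sum of per-record Normal log-densities on the log10 scale."""
        mean = self._mean(params)
        sd = np.sqrt(np.asarray(params["sigma2_day"], float))[self.day_idx]
        return float(np.sum(stats.norm.logpdf(self.y, mean, sd)))

    def log_posterior(self, params: dict) -> float:
        sp = self.spec
        lp = self.log_likelihood(params)
        a0, b0 = sp.var_prior_shape, sp.var_prior_rate
        effects = np.concatenate([
            np.asarray(params["alpha"], float)[1:],
            np.asarray(params["beta"], float)[1:],
            np.asarray(params["gamma"], float)])
        lp += float(np.sum(stats.norm.logpdf(effects, 0, sp.effect_prior_sd)))
        mu = np.asarray(params["mu_day"], float)
        m = np.asarray(params["m_job"], float)
        tau2 = np.asarray(params["tau2_job"], float)
        lp += float(np.sum(stats.norm.logpdf(
            mu, m[self.day_jobs], np.sqrt(tau2[self.day_jobs]))))
        lp += float(np.sum(stats.norm.logpdf(m, 0, sp.job_mean_prior_sd)))
        for v in np.concatenate([np.asarray(params["sigma2_day"], float),
                                 tau2]):
            lp += float(stats.invgamma.logpdf(v, a0, scale=b0))
        zeta = params.get("zeta")
        if zeta is not None:
            s2z = float(params["sigma2_zeta"])
            lp += float(np.sum(stats.norm.logpdf(np.asarray(zeta, float),
                                                 0, np.sqrt(s2z))))
            lp += float(stats.invgamma.logpdf(s2z, a0, scale=b0))
        return lp

    # -- layout ----------------------------------------------------------

    def parameter_names(self, include_reference: bool = True) -> list[str]:
        d = self.design
        names = [f"alpha[{s}]" for s in
                 (d.stations if include_reference else d.stations[1:])]
        names += [f"beta[{e}]" for e in
                  (d.environments if include_reference else d.environments[1:])]
        names += [f"gamma[{e}]" for e in d.events]
        names += [f"mu[{i}]" for i in d.day_ids]
        names += [f"sigma2[{i}]" for i in d.day_ids]
        names += [f"m[{j}]" for j in d.jobs]
        names += [f"tau2[{j}]" for j in d.jobs]
        return names


def build_model(design: DesignMatrices, spec: ModelSpec) -> Model:
    """Bind the design matrices to a model specification."""
    return Model(design, spec)


@dataclass
class PosteriorDraws:
    """MCMC samples indexed (chain, draw, ...) plus the level dictionaries.

    ``alpha``/``beta`` include the reference category as an explicit
    zero-valued first column, matching the convention that all category
    coefficients are monitored.
    """

    alpha: np.ndarray                 # (c, d, n_stations), [:, :, 0] == 0
    beta: np.ndarray                  # (c, d, n_environments)
    gamma: np.ndarray                 # (c, d, n_events)
    mu_day: np.ndarray                # (c, d, n_days)
    sigma2_day: np.ndarray
    m_job: np.ndarray                 # (c, d, n_jobs)
    tau2_job: np.ndarray
    sigma2_zeta: np.ndarray           # (c, d)
    zeta: np.ndarray | None           # (c, d, n_days, nb) or None
    stations: list[str]
    environments: list[str]
    events: list[str]
    day_ids: list[str]
    jobs: list[str]
    seed: int
    spec_hash: str

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def monitored(self, include_reference: bool = False) -> dict:
        """Per-parameter (chain, draw) arrays for diagnostics.

        Reference coefficients are constant 0 by construction and are
        excluded by default (their R-hat is undefined).
        """
        out = {}
        st0 = 0 if include_reference else 1
        for j, s in enumerate(self.stations):
            if j >= st0:
                out[f"alpha[{s}]"] = self.alpha[:, :, j]
        for j, e in enumerate(self.environments):
            if j >= st0:
                out[f"beta[{e}]"] = self.beta[:, :, j]
        for j, e in enumerate(self.events):
            out[f"gamma[{e}]"] = self.gamma[:, :, j]
        for j, d in enumerate(self.day_ids):
            out[f"mu[{d}]"] = self.mu_day[:, :, j]
            out[f"sigma2[{d}]"] = self.sigma2_day[:, :, j]
        for j, jb in enumerate(self.jobs):
            out[f"m[{jb}]"] = self.m_job[:, :, j]
            out[f"tau2[{jb}]"] = self.tau2_job[:, :, j]
        return out

    def effect_block(self, block: str) -> tuple[list[str], np.ndarray]:
        """(level names, flattened draws (n_total, n_levels)) for a block."""
        arr, levels = {
            "station": (self.alpha, self.stations),
            "environment": (self.beta, self.environments),
            "event": (self.gamma, self.events),
        }[block]
        return list(levels), arr.reshape(-1, arr.shape[-1])

    def save(self, out_dir: str | Path) -> None:
        """Persist draws as long-format CSV with a JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = {}
        for name, arr in self.monitored(include_reference=True).items():
            rows[name] = arr.reshape(-1)
        c, d = self.alpha.shape[:2]
        df = pd.DataFrame(rows)
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        df.insert(1, "draw", np.tile(np.arange(d), c))
        df.to_csv(out / "draws.csv", index=False)
        sidecar = {"stations": self.stations,
                   "environments": self.environments, "events": self.events,
                   "day_ids": self.day_ids, "jobs": self.jobs,
                   "seed": self.seed, "spec_hash": self.spec_hash,
                   "chains": c, "draws": d}
        (out / "draws.json").write_text(json.dumps(sidecar, indent=1))


def _invgamma_draw(rng, shape: float, rate: float) -> float:
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def _mvn_draw(rng, Q: np.ndarray, lin: np.ndarray) -> np.ndarray:
    """Draw from N(Q^-1 lin, Q^-1) via Cholesky of the precision Q."""
    L = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, lin)  # cheap relative to the chol reuse below
    z = rng.standard_normal(len(lin))
    return mean + np.linalg.solve(L.T, z)


def fit(model: Model, spec: ModelSpec | None = None) -> PosteriorDraws:
    """Run the blocked Gibbs sampler and return post-burn-in draws.

    Identical model + spec + seed give identical draws.  Requires at
    least 2 chains so convergence is diagnosable.
    """
    spec = model.spec if spec is None else spec
    if spec.chains < 2:
        raise ConfigurationError("need >= 2 chains for diagnosability")
    n_keep = (spec.iterations - spec.burn_in) // spec.thin
    if n_keep < 1:
        raise ConfigurationError("no draws kept: check iterations/burn_in/thin")

    d = model.design
    n_st, n_env = len(d.stations), len(d.environments)
    n_days, n_jobs, nb, p = model.n_days, model.n_jobs, model.nb, model.p
    a0, b0 = spec.var_prior_shape, spec.var_prior_rate
    s2_eff = spec.effect_prior_sd ** 2
    s2_m = spec.job_mean_prior_sd ** 2
    day_jobs = model.day_jobs
    job_days = [np.where(day_jobs == j)[0] for j in range(n_jobs)]
    y = model.y

    out = {k: np.zeros(s) for k, s in {
        "alpha": (spec.chains, n_keep, n_st),
        "beta": (spec.chains, n_keep, n_env),
        "gamma": (spec.chains, n_keep, model.p_event),
        "mu_day": (spec.chains, n_keep, n_days),
        "sigma2_day": (spec.chains, n_keep, n_days),
        "m_job": (spec.chains, n_keep, n_jobs),
        "tau2_job": (spec.chains, n_keep, n_jobs),
        "sigma2_zeta": (spec.chains, n_keep),
    }.items()}
    zeta_out = np.zeros((spec.chains, n_keep, n_days, nb)) \
        if (spec.store_zeta and spec.use_trend) else None

    for chain in range(spec.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), 7919, chain]))

        # initial values: data-informed centre plus chain-specific jitter
        mu = np.array([y[s].mean() for s in model.day_slices])
        mu += rng.normal(0, spec.init_jitter, n_days)
        sigma2 = np.array([max(float(np.var(y[s])), 1e-4)
                           for s in model.day_slices])
        theta = rng.normal(0, spec.init_jitter, p)
        zeta = np.zeros((n_days, nb))
        m = np.array([mu[jd].mean() for jd in job_days])
        tau2 = np.full(n_jobs, 0.05)
        s2z = 0.01
        init = _params_dict(model, theta, mu, sigma2, m, tau2, zeta, s2z)
        if not np.isfinite(model.log_posterior(init)):
            raise InitializationError(
                f"non-finite log-posterior at initialization (chain {chain}): "
                f"day means {mu[:4]}..., variances {sigma2[:4]}...")

        trend = np.zeros(model.n)
        keep = 0
        for it in range(spec.iterations):
            inv_s2 = 1.0 / sigma2
            w = inv_s2[model.day_idx]

            # fixed effects theta = (alpha_free, beta_free, gamma)
            if p:
                r = y - mu[model.day_idx] - trend
                Q = np.tensordot(inv_s2, model.G, axes=(0, 0)) \
                    + np.eye(p) / s2_eff
                lin = model.X.T @ (w * r)
                theta = _mvn_draw(rng, Q, lin)
                xtheta = model.X @ theta
            else:
                xtheta = np.zeros(model.n)

            # per-day spline coefficients and intercepts
            for i, s in enumerate(model.day_slices):
                if spec.use_trend:
                    ri = y[s] - mu[i] - xtheta[s]
                    Qi = model.BtB[i] * inv_s2[i] + np.eye(nb) / s2z
                    li = model.B[i].T @ ri * inv_s2[i]
                    zeta[i] = _mvn_draw(rng, Qi, li)
                    trend[s] = model.B[i] @ zeta[i]

                ji = day_jobs[i]
                resid = y[s] - xtheta[s] - trend[s]
                prec = model.day_counts[i] * inv_s2[i] + 1.0 / tau2[ji]
                mean = (resid.sum() * inv_s2[i] + m[ji] / tau2[ji]) / prec
                mu[i] = rng.normal(mean, 1.0 / np.sqrt(prec))

                ss = float(np.sum((resid - mu[i]) ** 2))
                sigma2[i] = _invgamma_draw(
                    rng, a0 + 0.5 * model.day_counts[i], b0 + 0.5 * ss)

            # job-level hyperparameters
            for j in range(n_jobs):
                nd = len(job_days[j])
                prec = nd / tau2[j] + 1.0 / s2_m
                mean = mu[job_days[j]].sum() / tau2[j] / prec
                m[j] = rng.normal(mean, 1.0 / np.sqrt(prec))
                ssj = float(np.sum((mu[job_days[j]] - m[j]) ** 2))
                tau2[j] = _invgamma_draw(rng, a0 + 0.5 * nd, b0 + 0.5 * ssj)

            if spec.use_trend:
                s2z = _invgamma_draw(rng, a0 + 0.5 * zeta.size,
                                     b0 + 0.5 * float(np.sum(zeta ** 2)))

            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                out["alpha"][chain, keep, 1:] = theta[: model.p_station]
                out["beta"][chain, keep, 1:] = \
                    theta[model.p_station: model.p_station + model.p_env]
                out["gamma"][chain, keep] = \
                    theta[model.p_station + model.p_env:]
                out["mu_day"][chain, keep] = mu
                out["sigma2_day"][chain, keep] = sigma2
                out["m_job"][chain, keep] = m
                out["tau2_job"][chain, keep] = tau2
                out["sigma2_zeta"][chain, keep] = s2z
                if zeta_out is not None:
                    zeta_out[chain, keep] = zeta
                keep += 1

    return PosteriorDraws(
        alpha=out["alpha"], beta=out["beta"], gamma=out["gamma"],
        mu_day=out["mu_day"], sigma2_day=out["sigma2_day"],
        m_job=out["m_job"], tau2_job=out["tau2_job"],
        sigma2_zeta=out["sigma2_zeta"], zeta=zeta_out,
        stations=list(d.stations), environments=list(d.environments),
        events=list(d.events), day_ids=list(d.day_ids), jobs=list(d.jobs),
        seed=int(spec.seed), spec_hash=spec.hash(),
    )


def _params_dict(model, theta, mu, sigma2, m, tau2, zeta, s2z) -> dict:
    alpha = np.zeros(len(model.design.stations))
    alpha[1:] = theta[: model.p_station]
    beta = np.zeros(len(model.design.environments))
    beta[1:] = theta[model.p_station: model.p_station + model.p_env]
    gamma = theta[model.p_station + model.p_env:]
    return {"alpha": alpha, "beta": beta, "gamma": gamma, "mu_day": mu,
            "sigma2_day": sigma2, "m_job": m, "tau2_job": tau2,
            "zeta": zeta, "sigma2_zeta": s2z}


def predict(model: Model, draws: PosteriorDraws, design: DesignMatrices,
            max_draws: int = 1000, interval: float = 0.95,
            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-record posterior predictive summaries on log10 and natural scale.

    Categories and days of ``design`` must be among those fitted.
    Predictive draws include the day-specific observation noise.
    """
    for kind, new, old in (("station", design.stations, draws.stations),
                           ("environment", design.environments,
                            draws.environments),
                           ("event", design.events, draws.events),
                           ("day", design.day_ids, draws.day_ids)):
        unseen = sorted(set(new) - set(old))
        if unseen:
            raise PredictionError(f"unseen {kind} categories: {unseen}")

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([draws.seed, 4201]))
    c, nd = draws.n_chains, draws.n_draws
    total = c * nd
    pick = np.linspace(0, total - 1, min(max_draws, total)).astype(int)

    def flat(a):
        return a.reshape(total, *a.shape[2:])[pick]

    st_i = [draws.stations.index(s) for s in design.stations]
    env_i = [draws.environments.index(e) for e in design.environments]
    ev_i = [draws.events.index(e) for e in design.events]
    day_i = np.array([draws.day_ids.index(i) for i in design.day_ids])

    alpha = flat(draws.alpha)[:, st_i]
    beta = flat(draws.beta)[:, env_i]
    gamma = flat(draws.gamma)[:, ev_i] if ev_i else \
        np.zeros((len(pick), 0))
    theta = np.hstack([alpha[:, 1:], beta[:, 1:], gamma])
    mu = flat(draws.mu_day)[:, day_i]
    sigma2 = flat(draws.sigma2_day)[:, day_i]

    X = np.hstack([design.X_station, design.X_environment, design.X_event])
    mean = mu[:, design.day_idx]
    if X.shape[1]:
        mean = mean + theta @ X.T

    if draws.zeta is not None:
        # rebuild the fitted per-day centred basis for the new records
        zeta = flat(draws.zeta)[:, day_i]
        bounds = np.searchsorted(design.day_idx,
                                 np.arange(len(design.day_ids) + 1))
        trend_mat = np.zeros((len(pick), len(design.y)))
        for i in range(len(design.day_ids)):
            s = slice(bounds[i], bounds[i + 1])
            if s.start == s.stop:
                continue
            fi = model.design.day_ids.index(design.day_ids[i])
            Bi = bspline_basis(design.t[s], 0.0, model.day_domain[fi],
                               model.spec.n_interior_knots,
                               model.spec.spline_degree) \
                - model.B_colmeans[fi]
            trend_mat[:, s] = zeta[:, i] @ Bi.T
        mean = mean + trend_mat

    noise = rng.standard_normal(mean.shape) * np.sqrt(sigma2[:, design.day_idx])
    pred = mean + noise
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    qs = np.quantile(pred, [lo_q, 0.5, hi_q], axis=0)
    out = pd.DataFrame({
        "day_id": np.array(design.day_ids)[design.day_idx],
        "t": design.t,
        "mean_log10": mean.mean(axis=0),
        "lo_log10": qs[0], "median_log10": qs[1], "hi_log10": qs[2],
    })
    out["median"] = 10.0 ** out["median_log10"]
    out["lo"] = 10.0 ** out["lo_log10"]
    out["hi"] = 10.0 ** out["hi_log10"]
    return out
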
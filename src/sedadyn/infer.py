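"""Inverse modelling: recover metacommunity parameters from records.

The observation likelihood is binomial over PCR replicates: simulating the
dynamical model yields relative abundances at each dated sample, the
observation model maps them to per-replicate detection probabilities p*,
and each taxon x sample count contributes a Binomial(R, p*) log-pmf term.
Point estimation maximises this likelihood with seeded multi-start bounded
quasi-Newton; full posteriors come from an affine-invariant ensemble MCMC;
competing model structures are ranked by AIC.

Free parameters are addressed by path strings into the parameter
containers, e.g. ``"alpha[0,1]"``, ``"growth.mu[2]"``, ``"dispersal[0,0,1]"``,
``"epsilon"``, ``"obs.c"`` or ``"obs.fp"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import binom

from .model import IntegrationError, simulate
from .observe import ObservationParams, SedaRecord, detection_probabilities
from .params import DriverSeries, MetacommunityParams

__all__ = [
    "FreeParameter",
    "ModelSpec",
    "FitResult",
    "FitFailure",
    "log_likelihood",
    "fit_map",
    "fit_bayes",
    "compare_models",
    "get_param",
    "set_param",
]

_PATH_RE = re.compile(r"^(obs\.)?([a-z0-9_]+(?:\.[a-z0-9_]+)?)(?:\[([\d,\s]+)\])?$")


def _resolve(params: MetacommunityParams, obs: ObservationParams, path: str):
    m = _PATH_RE.match(path)
    if not m:
        raise ValueError(f"malformed parameter path {path!r}")
    on_obs, name, idx = m.group(1), m.group(2), m.group(3)
    target = obs if on_obs else params
    obj = target
    for part in name.split("."):
        if not hasattr(obj, part):
            raise ValueError(f"unknown parameter {path!r}")
        parent, attr = obj, part
        obj = getattr(obj, part)
    index = tuple(int(i) for i in idx.split(",")) if idx else None
    return parent, attr, index


def get_param(params: MetacommunityParams, obs: ObservationParams, path: str) -> float:
    parent, attr, index = _resolve(params, obs, path)
    value = getattr(parent, attr)
    if index is not None:
        return float(np.asarray(value)[index])
    return float(value)


def set_param(
    params: MetacommunityParams, obs: ObservationParams, path: str, value: float
) -> None:
    parent, attr, index = _resolve(params, obs, path)
    if index is None:
        setattr(parent, attr, float(value))
    else:
        arr = np.asarray(getattr(parent, attr), dtype=float)
        arr[index] = value
        setattr(parent, attr, arr)


@dataclass
class FreeParameter:
    """One free parameter: its path, box bounds and (for MCMC) prior.

    prior is either None (uniform over the bounds) or ("normal", mean, sd)
    truncated to the bounds.
    """

    path: str
    lower: float
    upper: float
    prior: tuple | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError(f"bounds for {self.path} must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"empty bound interval for {self.path}")

    def log_prior(self, x: float) -> float:
        if not self.lower <= x <= self.upper:
            return -np.inf
        if self.prior is None:
            return -np.log(self.upper - self.lower)
        kind, m, s = self.prior
        if kind != "normal":
            raise ValueError(f"unknown prior kind {kind!r}")
        return -0.5 * ((x - m) / s) ** 2 - np.log(s * np.sqrt(2 * np.pi))

    def sample_prior(self, rng: np.random.Generator) -> float:
        if self.prior is None:
            return float(rng.uniform(self.lower, self.upper))
        _, m, s = self.prior
        for _ in range(1000):
            x = float(rng.normal(m, s))
            if self.lower <= x <= self.upper:
                return x
        return float(np.clip(m, self.lower, self.upper))


@dataclass
class ModelSpec:
    """Which parameters are free (with bounds/priors) and which are pinned.

    fixed maps parameter paths to values applied to the base model before
    fitting — e.g. a "no interactions" hypothesis pins the off-diagonal
    alpha entries at zero.
    """

    label: str
    free: list[FreeParameter]
    fixed: dict = field(default_factory=dict)
    allow_confounded: bool = False

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("a model spec needs at least one free parameter")
        paths = [f.path for f in self.free]
        eps_free = any(p.startswith("epsilon") for p in paths)
        attack_free = any(p.startswith("attack") for p in paths)
        if eps_free and attack_free and not self.allow_confounded:
            raise ValueError(
                "epsilon and attack rates are confounded (both scale the "
                "trophic gain); free only one, or set allow_confounded=True"
            )

    @property
    def n_free(self) -> int:
        return len(self.free)

    def apply(
        self, params: MetacommunityParams, obs: ObservationParams
    ) -> tuple[MetacommunityParams, ObservationParams]:
        p = params.copy()
        o = ObservationParams(
            c=obs.c, beta=obs.beta.copy(), fp=obs.fp,
            n_replicates=obs.n_replicates, seed=obs.seed,
        )
        for path, value in self.fixed.items():
            set_param(p, o, path, value)
        return p, o


@dataclass
class FitResult:
    """Point estimates (or posterior summaries) with fit diagnostics."""

    label: str
    estimates: dict
    stderr: dict
    loglik: float
    n_free: int
    params: MetacommunityParams
    obs: ObservationParams
    diagnostics: dict
    seed: int
    intervals: dict | None = None  # path -> (lo, hi) central 95%

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.loglik

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def summary(self) -> pd.DataFrame:
        rows = []
        for path, est in self.estimates.items():
            row = {"parameter": path, "estimate": est}
            se = self.stderr.get(path)
            row["stderr"] = np.nan if se is None else se
            if self.intervals and path in self.intervals:
                row["ci_lo"], row["ci_hi"] = self.intervals[path]
            rows.append(row)
        return pd.DataFrame(rows)


class FitFailure(RuntimeError):
    """All optimizer starts failed; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def log_likelihood(
    params: MetacommunityParams,
    records: Sequence[SedaRecord],
    drivers: Sequence[DriverSeries],
    obs: ObservationParams,
    initial_state,
    t_span: tuple[float, float],
    *,
    age_max: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Binomial replicate log-likelihood of the records under the model.

    Simulates the model over ``t_span``, maps each record's sample ages to
    model time (t = age_max - age, age_max defaulting to the span length),
    converts relative abundances to detection probabilities and sums the
    Binomial(R, p*) log-pmf over all taxa and samples.  A structurally
    impossible observation (p* = 0 with a positive count) yields -inf.
    """
    if age_max is None:
        age_max = float(t_span[1] - t_span[0])
    sample_times = []
    for rec in records:
        if rec.site_index is None:
            raise ValueError(f"record {rec.lake!r} has no site index")
        t = age_max - rec.ages.to_numpy()
        if rec.n_samples and (t.min() < t_span[0] - 1e-9 or t.max() > t_span[1] + 1e-9):
            raise ValueError(
                f"record {rec.lake!r} has ages outside the simulated span"
            )
        sample_times.append(np.sort(t))
    grid = np.unique(
        np.concatenate([np.asarray(t_span, dtype=float)] + sample_times)
    )
    try:
        traj = simulate(
            params, initial_state, drivers, t_span, grid, rtol=rtol, atol=atol
        )
    except IntegrationError as err:
        raise IntegrationError(f"{err} (during likelihood evaluation)") from err

    total = 0.0
    for rec, t in zip(records, sample_times):
        if rec.n_samples == 0:
            continue
        # record columns are stored oldest-first; t is ascending model time
        ages_sorted = np.argsort(-rec.ages.to_numpy(), kind="stable")
        counts = rec.detections.to_numpy()[:, ages_sorted]
        p_star = detection_probabilities(traj, rec.site_index, t, obs)
        with np.errstate(divide="ignore"):
            ll = binom.logpmf(counts, rec.n_replicates, p_star)
        total += ll.sum()
    if np.isnan(total):
        return -np.inf
    return float(total)


def _pack(spec: ModelSpec, params, obs) -> np.ndarray:
    return np.array([get_param(params, obs, f.path) for f in spec.free])


def _unpack(spec: ModelSpec, params, obs, x: np.ndarray) -> None:
    for f, v in zip(spec.free, x):
        set_param(params, obs, f.path, v)


def fit_map(
    spec: ModelSpec,
    records: Sequence[SedaRecord],
    drivers: Sequence[DriverSeries],
    obs: ObservationParams,
    initial_state,
    t_span: tuple[float, float],
    *,
    age_max: float | None = None,
    base_params: MetacommunityParams | None = None,
    seed: int = 0,
    n_starts: int = 8,
    init_strategy: str = "uniform",
    rtol: float = 1e-6,
    atol: float = 1e-8,
    maxiter: int = 300,
    compute_stderr: bool = True,
) -> FitResult:
    """Maximum-likelihood fit by seeded multi-start L-BFGS-B.

    init_strategy: "uniform" draws each start uniformly inside the bounds;
    "warm" starts from the base parameter values plus shrinking
    perturbations.  Standard errors come from the finite-difference
    observed information; if the Hessian is not positive definite they are
    reported as unavailable rather than fabricated.
    """
    if not records:
        raise ValueError("no records to fit")
    if base_params is None:
        raise ValueError("base_params (the fixed parameter skeleton) is required")
    params, obs = spec.apply(base_params, obs)
    bounds = [(f.lower, f.upper) for f in spec.free]
    n_fail = 0

    def objective(x: np.ndarray) -> float:
        _unpack(spec, params, obs, x)
        try:
            ll = log_likelihood(
                params, records, drivers, obs, initial_state, t_span,
                age_max=age_max, rtol=rtol, atol=atol,
            )
        except IntegrationError:
            nonlocal n_fail
            n_fail += 1
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x_base = np.clip(_pack(spec, params, obs), lo, hi)
    starts = []
    if init_strategy == "warm":
        starts.append(x_base)
        for j in range(1, n_starts):
            scale = 0.05 * (hi - lo) * (1 + j % 3)
            starts.append(np.clip(x_base + rng.normal(0, scale), lo, hi))
    elif init_strategy == "uniform":
        for _ in range(n_starts):
            starts.append(rng.uniform(lo, hi))
    else:
        raise ValueError(f"unknown init_strategy {init_strategy!r}")

    results, messages = [], []
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        messages.append(str(res.message))
        if np.isfinite(res.fun) and res.fun < 1e9:
            results.append(res)
    if not results:
        diag = {"messages": messages, "n_integration_failures": n_fail}
        raise FitFailure("all optimizer starts failed", diag)

    best = min(results, key=lambda r: r.fun)
    x_hat = np.clip(best.x, lo, hi)
    _unpack(spec, params, obs, x_hat)
    loglik = -objective(x_hat)

    stderr: dict = {f.path: None for f in spec.free}
    if compute_stderr:
        try:
            H = _fd_hessian(objective, x_hat, lo, hi)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.all(d > 0):
                for f, s in zip(spec.free, np.sqrt(d)):
                    stderr[f.path] = float(s)
        except np.linalg.LinAlgError:
            pass

    tol = 1e-6 * (hi - lo)
    boundary = [
        f.path
        for f, x, a, b, t in zip(spec.free, x_hat, lo, hi, tol)
        if x - a < t or b - x < t
    ]
    diagnostics = {
        "converged": bool(best.success),
        "n_starts": n_starts,
        "n_successful_starts": len(results),
        "n_integration_failures": n_fail,
        "boundary": boundary,
        "message": str(best.message),
    }
    return FitResult(
        label=spec.label,
        estimates={f.path: float(x) for f, x in zip(spec.free, x_hat)},
        stderr=stderr,
        loglik=loglik,
        n_free=spec.n_free,
        params=params,
        obs=obs,
        diagnostics=diagnostics,
        seed=seed,
    )


def _fd_hessian(fun, x, lo, hi, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian, steps scaled to the bound range."""
    n = x.size
    h = rel_step * (hi - lo)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                fp = fun(x + h[i] * _e(n, i))
                fm = fun(x - h[i] * _e(n, i))
                H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                fpp = fun(x + h[i] * _e(n, i) + h[j] * _e(n, j))
                fpm = fun(x + h[i] * _e(n, i) - h[j] * _e(n, j))
                fmp = fun(x - h[i] * _e(n, i) + h[j] * _e(n, j))
                fmm = fun(x - h[i] * _e(n, i) - h[j] * _e(n, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _e(n: int, i: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic; chains has shape (steps, walkers)."""
    n, m = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:half], chains[half : 2 * half]], axis=1)
    n, m = segs.shape
    means = segs.mean(axis=0)
    B = n * means.var(ddof=1)
    W = segs.var(axis=0, ddof=1).mean()
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def fit_bayes(
    spec: ModelSpec,
    records: Sequence[SedaRecord],
    drivers: Sequence[DriverSeries],
    obs: ObservationParams,
    initial_state,
    t_span: tuple[float, float],
    *,
    age_max: float | None = None,
    base_params: MetacommunityParams | None = None,
    seed: int = 0,
    n_walkers: int = 16,
    n_steps: int = 600,
    burn_frac: float = 0.5,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    rhat_threshold: float = 1.1,
) -> FitResult:
    """Posterior sampling with an affine-invariant ensemble sampler (emcee).

    Every free parameter needs a proper prior (uniform over its bounds by
    default).  Returns posterior medians, central 95% intervals and a
    split-chain convergence statistic; non-convergence is flagged in the
    diagnostics, never hidden.
    """
    import emcee

    if base_params is None:
        raise ValueError("base_params is required")
    params, obs = spec.apply(base_params, obs)
    ndim = spec.n_free

    def log_prob(x: np.ndarray) -> float:
        lp = sum(f.log_prior(v) for f, v in zip(spec.free, x))
        if not np.isfinite(lp):
            return -np.inf
        _unpack(spec, params, obs, x)
        try:
            ll = log_likelihood(
                params, records, drivers, obs, initial_state, t_span,
                age_max=age_max, rtol=rtol, atol=atol,
            )
        except IntegrationError:
            return -np.inf
        return lp + ll

    rng = np.random.default_rng(seed)
    p0 = np.array(
        [[f.sample_prior(rng) for f in spec.free] for _ in range(n_walkers)]
    )
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    burn = int(burn_frac * n_steps)
    chain = sampler.get_chain()[burn:]  # (steps, walkers, ndim)
    flat = chain.reshape(-1, ndim)

    estimates, intervals, stderr = {}, {}, {}
    rhats = {}
    for j, f in enumerate(spec.free):
        draws = flat[:, j]
        estimates[f.path] = float(np.median(draws))
        intervals[f.path] = (
            float(np.percentile(draws, 2.5)),
            float(np.percentile(draws, 97.5)),
        )
        stderr[f.path] = float(draws.std(ddof=1))
        rhats[f.path] = _split_rhat(chain[:, :, j])

    _unpack(spec, params, obs, np.array([estimates[f.path] for f in spec.free]))
    try:
        ll_hat = log_likelihood(
            params, records, drivers, obs, initial_state, t_span,
            age_max=age_max, rtol=rtol, atol=atol,
        )
    except IntegrationError:
        ll_hat = -np.inf
    max_rhat = max(rhats.values())
    diagnostics = {
        "converged": bool(max_rhat <= rhat_threshold),
        "rhat": rhats,
        "max_rhat": float(max_rhat),
        "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
        "n_steps": n_steps,
        "n_walkers": n_walkers,
        "burn": burn,
    }
    return FitResult(
        label=spec.label,
        estimates=estimates,
        stderr=stderr,
        loglik=float(ll_hat),
        n_free=ndim,
        params=params,
        obs=obs,
        diagnostics=diagnostics,
        seed=seed,
        intervals=intervals,
    )


def compare_models(
    specs: Sequence[ModelSpec],
    records: Sequence[SedaRecord],
    drivers: Sequence[DriverSeries],
    obs: ObservationParams,
    initial_state,
    t_span: tuple[float, float],
    *,
    age_max: float | None = None,
    base_params: MetacommunityParams | None = None,
    seed: int = 0,
    n_starts: int = 4,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    maxiter: int = 300,
) -> pd.DataFrame:
    """Fit each candidate structure and rank by AIC (ties: fewer parameters).

    A spec whose fit fails is marked failed and excluded from the ranking;
    the comparison continues over the remaining specs.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    rows = []
    fits = {}
    for spec, s in zip(specs, seeds):
        try:
            fit = fit_map(
                spec, records, drivers, obs, initial_state, t_span,
                age_max=age_max, base_params=base_params, seed=int(s),
                n_starts=n_starts, rtol=rtol, atol=atol, maxiter=maxiter,
                compute_stderr=False,
            )
            fits[spec.label] = fit
            rows.append(
                {
                    "label": spec.label,
                    "loglik": fit.loglik,
                    "n_params": spec.n_free,
                    "aic": fit.aic,
                    "failed": False,
                }
            )
        except FitFailure:
            rows.append(
                {
                    "label": spec.label,
                    "loglik": np.nan,
                    "n_params": spec.n_free,
                    "aic": np.nan,
                    "failed": True,
                }
            )
    table = pd.DataFrame(rows)
    ok = table[~table.failed].sort_values(
        ["aic", "n_params"], kind="stable"
    )
    table["rank"] = np.nan
    table.loc[ok.index, "rank"] = np.arange(1, len(ok) + 1)
    table.attrs["fits"] = fits
    return table.sort_values(["failed", "rank"], kind="stable").reset_index(drop=True)
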
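"""Generalized Lotka-Volterra metacommunity dynamics.

The model couples, for each species i at site k,

    dN_ik/dt = N_ik * g_ik + dispersal flux,

where the per-capita rate

    g_ik = b_i(u_k(t)) - sum_j alpha_ij N_jk
           + eps * sum_j F_ij N_jk - sum_j F_ji N_jk

combines a Gaussian niche response of the basal growth rate to an
environmental driver u_k(t), competition/facilitation (alpha), and a
Holling type II functional response F for trophic gains and losses.  The
dispersal term moves individuals between discrete sites at per-capita
rates and conserves total abundance per species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import DriverSeries, MetacommunityParams

__all__ = [
    "IntegrationError",
    "TrajectorySet",
    "niche_response",
    "functional_response",
    "per_capita_growth",
    "dispersal_flux",
    "simulate",
    "EXTINCTION_THRESHOLD",
]

#: Below this abundance a declining population is treated as extinct and
#: pinned at zero, which keeps the integrator out of stiff near-zero decay.
EXTINCTION_THRESHOLD = 1e-12


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails (e.g. step-size collapse)."""


class _Divergence(RuntimeError):
    """Internal fast-fail: the state blew up; no point grinding the solver."""

    def __init__(self, t: float):
        super().__init__(f"state diverged near t = {t:.6g}")
        self.t = t


#: Abundance ceiling: beyond this the trajectory is declared divergent.
DIVERGENCE_CEILING = 1e9


@dataclass
class TrajectorySet:
    """Deterministic abundance trajectories N_ik(t) on an output grid.

    abundance has shape (S, L, T) and is nonnegative; times is the strictly
    increasing output grid in model years.
    """

    times: np.ndarray
    abundance: np.ndarray
    params_used: MetacommunityParams | None = None
    drivers_used: tuple | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.abundance.ndim != 3 or self.abundance.shape[2] != self.times.size:
            raise ValueError("abundance must have shape (S, L, T)")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_species(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_sites(self) -> int:
        return self.abundance.shape[1]

    def at_times(self, t) -> np.ndarray:
        """Linearly interpolated abundance (S, L, len(t)) at model times t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if t.min() < self.times[0] - 1e-9 or t.max() > self.times[-1] + 1e-9:
            raise ValueError(
                f"requested time outside simulated span "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        S, L, _ = self.abundance.shape
        out = np.empty((S, L, t.size))
        for i in range(S):
            for k in range(L):
                out[i, k] = np.interp(t, self.times, self.abundance[i, k])
        return out


def niche_response(params: MetacommunityParams, species: int, u) -> float:
    """Basal growth rate b_i(u) of one species at driver value u (1/year)."""
    g = params.growth
    if not 0 <= species < params.n_species:
        raise IndexError(f"species index {species} out of range")
    z = (np.asarray(u, dtype=float) - g.mu[species]) / g.sigma[species]
    return g.b0[species] + g.r[species] * np.exp(-0.5 * z**2)


def _niche_response_all(params: MetacommunityParams, u_sites: np.ndarray) -> np.ndarray:
    """b_i(u_k) for all species x sites; u_sites has shape (L,)."""
    g = params.growth
    z = (u_sites[None, :] - g.mu[:, None]) / g.sigma[:, None]
    return g.b0[:, None] + g.r[:, None] * np.exp(-0.5 * z**2)


def functional_response(params: MetacommunityParams, prey_abundance) -> np.ndarray:
    """Per-capita consumption rates F_ij at one site (Holling type II).

    F_ij = a_ij / (1 + sum_q a_iq N_q / h); with h = inf this is the linear
    (type I) limit F_ij = a_ij.
    """
    N = np.asarray(prey_abundance, dtype=float)
    if np.any(N < 0):
        raise ValueError("prey abundances must be nonnegative")
    a = params.attack
    if np.isinf(params.handling):
        return a.copy()
    denom = 1.0 + (a @ N) / params.handling
    return a / denom[:, None]


def per_capita_growth(params: MetacommunityParams, N_site, u) -> np.ndarray:
    """Per-capita growth rate vector g at one site (dispersal excluded).

    g_i = b_i(u) - sum_j alpha_ij N_j + eps sum_j F_ij N_j - sum_j F_ji N_j
    """
    N = np.asarray(N_site, dtype=float)
    if N.shape != (params.n_species,):
        raise ValueError(
            f"N_site must have shape ({params.n_species},), got {N.shape}"
        )
    if np.any(N < 0):
        raise ValueError("abundances must be nonnegative")
    g = params.growth
    z = (float(u) - g.mu) / g.sigma
    b = g.b0 + g.r * np.exp(-0.5 * z**2)
    F = functional_response(params, N)
    return b - params.alpha @ N + params.epsilon * (F @ N) - F.T @ N


def dispersal_flux(
    params: MetacommunityParams, species: int, N_species_across_sites
) -> np.ndarray:
    """Net dispersal flux (abundance/year) of one species across sites.

    flux_k = sum_{l != k} m[l, k] N_l  -  N_k sum_{l != k} m[k, l]

    Fluxes sum to zero over sites (mass conservation).
    """
    if not 0 <= species < params.n_species:
        raise IndexError(f"species index {species} out of range")
    n = np.asarray(N_species_across_sites, dtype=float)
    if n.shape != (params.n_sites,):
        raise ValueError(f"expected abundance vector over {params.n_sites} sites")
    if np.any(n < 0):
        raise ValueError("abundances must be nonnegative")
    m = params.dispersal[species]
    return m.T @ n - n * m.sum(axis=1)


def _driver_evaluator(drivers: Sequence[DriverSeries]):
    """u(t) -> vector over sites; one searchsorted when knots are shared."""
    tk0 = drivers[0].times
    shared = all(
        d.times.shape == tk0.shape and np.array_equal(d.times, tk0)
        for d in drivers
    )
    if shared and tk0.size > 1 and np.all(np.diff(tk0) > 0):
        vals = np.column_stack([d.values for d in drivers])  # (K, L)
        slopes = np.diff(vals, axis=0) / np.diff(tk0)[:, None]

        def u_of_t(t: float) -> np.ndarray:
            if t <= tk0[0]:
                return vals[0]
            if t >= tk0[-1]:
                return vals[-1]
            j = np.searchsorted(tk0, t) - 1
            return vals[j] + slopes[j] * (t - tk0[j])

        return u_of_t

    def u_of_t(t: float) -> np.ndarray:
        return np.array([float(d(t)) for d in drivers])

    return u_of_t


def _rhs_factory(params: MetacommunityParams, drivers: Sequence[DriverSeries]):
    S, L = params.n_species, params.n_sites
    alpha = params.alpha
    attack = params.attack
    eps = params.epsilon
    h = params.handling
    m = params.dispersal  # (S, L, L), zero diagonal
    out_rate = m.sum(axis=2)  # (S, L): total per-capita emigration rate
    has_trophic = np.any(attack > 0)
    has_dispersal = np.any(m > 0)
    g = params.growth
    b0 = g.b0[:, None]
    r = g.r[:, None]
    mu = g.mu[:, None]
    sigma = g.sigma[:, None]
    u_of_t = _driver_evaluator(drivers)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        # divergent parameter regions (e.g. runaway mutualism) overflow
        # here and surface as an integrator failure, which callers handle
        with np.errstate(over="ignore", invalid="ignore"):
            return _rhs_inner(t, y)

    def _rhs_inner(t: float, y: np.ndarray) -> np.ndarray:
        N = np.maximum(y.reshape(S, L), 0.0)
        z = (u_of_t(t)[None, :] - mu) / sigma
        growth = b0 + r * np.exp(-0.5 * z * z) - alpha @ N
        if has_trophic:
            # Holling II gains/losses in closed form over all sites:
            # gain_ik = eps * (aN)_ik / denom_ik, loss_ik = (a^T (N/denom))_ik
            aN = attack @ N
            denom = 1.0 if np.isinf(h) else 1.0 + aN / h
            growth += eps * aN / denom - attack.T @ (N / denom)
        dN = N * growth
        if has_dispersal:
            dN += np.einsum("ilk,il->ik", m, N) - N * out_rate
        # extinction clamp: a vanished population cannot decline further
        dN[(N < EXTINCTION_THRESHOLD) & (dN < 0)] = 0.0
        if not np.all(np.isfinite(dN)) or N.max() > DIVERGENCE_CEILING:
            raise _Divergence(t)
        return dN.ravel()

    return rhs


def simulate(
    params: MetacommunityParams,
    initial_abundance,
    drivers: Sequence[DriverSeries],
    t_span: tuple[float, float],
    output_grid,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TrajectorySet:
    """Integrate the metacommunity ODE and sample it on ``output_grid``.

    The integrator is adaptive and stiff-capable (LSODA by default).
    Abundances are clipped at zero on output; a declining population below
    :data:`EXTINCTION_THRESHOLD` is held at zero during integration.
    """
    N0 = np.asarray(initial_abundance, dtype=float)
    S, L = params.n_species, params.n_sites
    if N0.shape != (S, L):
        raise ValueError(f"initial abundance must have shape ({S}, {L})")
    if np.any(N0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    if len(drivers) != L:
        raise ValueError(f"need one driver series per site ({L})")
    grid = np.asarray(output_grid, dtype=float)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if grid[0] < t0 or grid[-1] > t1:
        raise ValueError("output grid must lie within t_span")

    try:
        sol = solve_ivp(
            _rhs_factory(params, drivers),
            (t0, t1),
            N0.ravel(),
            method=method,
            t_eval=grid,
            rtol=rtol,
            atol=atol,
        )
    except _Divergence as err:
        raise IntegrationError(
            f"integration failed near t = {err.t:.6g}: abundances diverged"
        ) from err
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(
            f"integration failed near t = {t_fail:.6g}: {sol.message}"
        )
    abundance = np.clip(sol.y.reshape(S, L, grid.size), 0.0, None)
    return TrajectorySet(
        times=grid,
        abundance=abundance,
        params_used=params,
        drivers_used=tuple(drivers),
    )
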
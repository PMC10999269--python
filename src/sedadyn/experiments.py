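"""Canned validation experiments on the synthetic scenarios.

Each function runs one self-contained study — an analytical oracle check,
a parameter-recovery experiment, a model-selection contest, or a
subsampling robustness experiment — and returns plain numbers.  They are
the package's own evidence that the simulate → observe → fit loop works;
the test suite asserts on them and the acceptance script reports them.

All randomness is derived from a single integer seed via
``numpy.random.SeedSequence`` spawning, so every experiment is exactly
reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .infer import FreeParameter, ModelSpec, compare_models, fit_map, log_likelihood
from .model import simulate
from .observe import ObservationParams, SedaRecord
from .params import DriverSeries, MetacommunityParams, NicheParams
from .resolution import (
    richness_series,
    smooth_trend,
    subsample_spatial,
    subsample_temporal,
    trend_agreement,
    turnover_series,
)
from .scenarios import generate_records, make_scenario

__all__ = [
    "logistic_oracle_error",
    "dispersal_conservation_error",
    "likelihood_oracle_error",
    "recovery_experiment",
    "model_selection_experiment",
    "temporal_resolution_experiment",
    "spatial_resolution_experiment",
    "subsample_counting_check",
]

#: alpha off-diagonal entries freed in the recovery and selection fits
_OFFDIAG = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def _derive_seeds(seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), stream])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def logistic_oracle_error() -> tuple[float, int]:
    """Max relative error of the simulated logistic vs its closed form.

    S = 1, L = 1, r = 1, K = 1, N0 = 0.1 under a constant driver:
    N(t) = 1 / (1 + 9 e^{-t}).
    """
    params = MetacommunityParams(
        n_species=1,
        n_sites=1,
        growth=NicheParams(r=[1.0], mu=[0.0], sigma=[1.0], b0=[0.0]),
        alpha=[[1.0]],
    )
    grid = np.linspace(0.0, 10.0, 201)
    traj = simulate(
        params, [[0.1]], [DriverSeries([0.0, 10.0], [0.0, 0.0])], (0.0, 10.0), grid
    )
    exact = 1.0 / (1.0 + 9.0 * np.exp(-grid))
    err = np.max(np.abs(traj.abundance[0, 0] - exact) / exact)
    return float(err), grid.size


def dispersal_conservation_error(seed: int = 0) -> tuple[float, int]:
    """Per-species total-abundance drift in a pure-dispersal system.

    No growth, no interactions; random site-to-site rates over 10 kyr.
    Returns the max relative deviation of the per-species totals.
    """
    rng = np.random.default_rng(seed)
    S, L = 2, 4
    params = MetacommunityParams(
        n_species=S,
        n_sites=L,
        growth=NicheParams(
            r=np.zeros(S), mu=np.zeros(S), sigma=np.ones(S), b0=np.zeros(S)
        ),
        alpha=np.zeros((S, S)),
        dispersal=rng.uniform(0.0, 0.02, (S, L, L)),
    )
    drivers = [DriverSeries([0.0, 1e4], [0.0, 0.0], site=f"s{k}") for k in range(L)]
    n0 = rng.uniform(0.5, 2.0, (S, L))
    grid = np.linspace(0.0, 1e4, 101)
    traj = simulate(params, n0, drivers, (0.0, 1e4), grid)
    totals = traj.abundance.sum(axis=1)
    err = np.max(np.abs(totals - totals[:, [0]]) / totals[:, [0]])
    return float(err), grid.size


def likelihood_oracle_error() -> tuple[float, int]:
    """|log_likelihood - brute-force binomial sum| on a 2-taxon hand case.

    Two taxa held at constant relative abundance (0.6, 0.4), two samples;
    the oracle sums log C(R,k) + k log p* + (R-k) log(1-p*) by hand.
    """
    params = MetacommunityParams(
        n_species=2,
        n_sites=1,
        growth=NicheParams(
            r=np.zeros(2), mu=np.zeros(2), sigma=np.ones(2), b0=np.zeros(2)
        ),
        alpha=np.zeros((2, 2)),
    )
    drivers = [DriverSeries([0.0, 100.0], [0.0, 0.0])]
    init = np.array([[0.6], [0.4]])
    obs = ObservationParams(c=2.0, beta=1.0, fp=0.01, n_replicates=8)

    import pandas as pd

    ids = ["s0", "s1"]
    counts = np.array([[5, 6], [2, 1]])
    rec = SedaRecord(
        lake="toy",
        ages=pd.Series([80.0, 30.0], index=ids),
        detections=pd.DataFrame(counts, index=["A", "B"], columns=ids),
        n_replicates=8,
        site_index=0,
    )
    ll = log_likelihood(params, [rec], drivers, obs, init, (0.0, 100.0))

    R = 8
    expected = 0.0
    for rel, row in ((0.6, counts[0]), (0.4, counts[1])):
        p = 1.0 - np.exp(-2.0 * rel)
        p = p + (1.0 - p) * 0.01
        for k in row:
            log_comb = gammaln(R + 1) - gammaln(k + 1) - gammaln(R - k + 1)
            expected += log_comb + k * np.log(p) + (R - k) * np.log(1.0 - p)
    return float(abs(ll - expected)), counts.size


def recovery_experiment(
    seed: int = 1,
    *,
    n_starts: int = 8,
    rtol: float = 1e-5,
    maxiter: int = 300,
) -> dict:
    """Recover interaction strengths and niche optima on the trio scenario.

    Generates records with known parameters (3 species, 2 sites, 200
    samples per site, 8 replicates), frees the two nonzero alpha
    off-diagonals and all three niche optima, and fits by multi-start
    maximum likelihood.  Reports sign agreement for the interactions and
    the worst relative error of the niche optima.
    """
    sc = make_scenario("trio", seed)
    records, _ = generate_records(sc, rtol=1e-6, atol=1e-8)
    free = [
        FreeParameter("alpha[0,1]", -1.0, 1.0),
        FreeParameter("alpha[1,0]", -1.0, 1.0),
        FreeParameter("growth.mu[0]", 1.0, 9.0),
        FreeParameter("growth.mu[1]", 1.0, 9.0),
        FreeParameter("growth.mu[2]", 1.0, 9.0),
    ]
    spec = ModelSpec(label="recovery", free=free)
    fit = fit_map(
        spec, records, sc.drivers, sc.obs, sc.initial_abundance, sc.t_span,
        base_params=sc.params, seed=seed + 1, n_starts=n_starts,
        rtol=rtol, atol=rtol * 1e-2, maxiter=maxiter, compute_stderr=False,
    )
    truth_alpha = {
        "alpha[0,1]": sc.params.alpha[0, 1],
        "alpha[1,0]": sc.params.alpha[1, 0],
    }
    signs_ok = all(
        np.sign(fit.estimates[k]) == np.sign(v) for k, v in truth_alpha.items()
    )
    mu_true = sc.params.growth.mu
    mu_err = max(
        abs(fit.estimates[f"growth.mu[{i}]"] - mu_true[i]) / abs(mu_true[i])
        for i in range(3)
    )
    n_obs = sum(r.detections.size for r in records)
    return {
        "alpha_signs_correct": bool(signs_ok),
        "mu_max_rel_error": float(mu_err),
        "estimates": fit.estimates,
        "loglik": fit.loglik,
        "n_observations": n_obs,
    }


def _selection_specs() -> list[ModelSpec]:
    with_int = ModelSpec(
        label="interactions",
        free=[FreeParameter(f"alpha[{i},{j}]", -0.6, 0.6) for i, j in _OFFDIAG]
        + [FreeParameter("growth.mu[1]", 1.0, 9.0)],
    )
    without = ModelSpec(
        label="no-interactions",
        free=[FreeParameter("growth.mu[1]", 1.0, 9.0)],
        fixed={f"alpha[{i},{j}]": 0.0 for i, j in _OFFDIAG},
    )
    return [with_int, without]


def model_selection_experiment(
    seed: int = 1,
    *,
    n_reps: int = 10,
    n_starts: int = 1,
    rtol: float = 1e-5,
    maxiter: int = 30,
) -> dict:
    """AIC contest between interaction and no-interaction structures.

    For each repetition and each generator (trio: with interactions;
    null: without), generates fresh records and ranks the two hypotheses
    by AIC.  Reports how often the generating structure wins.
    """
    out = {}
    for gen, stream in (("trio", 11), ("null", 12)):
        wins = 0
        for rs in _derive_seeds(seed, n_reps, stream):
            sc = make_scenario(gen, rs)
            records, _ = generate_records(sc, rtol=1e-6, atol=1e-8)
            table = compare_models(
                _selection_specs(), records, sc.drivers, sc.obs,
                sc.initial_abundance, sc.t_span, base_params=sc.params,
                seed=rs + 1, n_starts=n_starts, rtol=rtol, atol=rtol * 1e-2,
                maxiter=maxiter,
            )
            winner = table.iloc[0]["label"]
            expected = "interactions" if gen == "trio" else "no-interactions"
            wins += winner == expected
        out[gen] = {"wins": int(wins), "n_reps": n_reps}
    return out


# Analysis configuration for the regional (fenno10) trend experiments:
# conservative detection filtering (>= 2 positive replicates) and the
# abundance-weighted turnover metric, which uses the replicate counts
# rather than presence only.
_TREND_KW = dict(min_replicates=2)
_TURNOVER_METRIC = "braycurtis"
_BASIS_DIM = 6
_BIN = 500.0


def _trend_pair(obj):
    r = smooth_trend(richness_series(obj, _BIN, **_TREND_KW), _BASIS_DIM)
    t = smooth_trend(
        turnover_series(obj, _BIN, metric=_TURNOVER_METRIC, **_TREND_KW),
        _BASIS_DIM,
    )
    return r, t


def temporal_resolution_experiment(
    seed: int = 1, *, n_repeats: int = 10, records=None
) -> dict:
    """Do k=1-per-500-yr-bin subsets track each lake's full-record trends?

    For every lake and seeded repeat, the record is thinned to one sample
    per bin and its smoothed richness and turnover trends are compared
    against the same lake's full-record trends.  Returns the Spearman
    rank correlations averaged over all lakes and repeats.
    """
    if records is None:
        sc = make_scenario("fenno10", seed)
        records, _ = generate_records(sc, rtol=1e-6, atol=1e-8)
    refs = [_trend_pair(rec) for rec in records]
    rho_r, rho_t = [], []
    rep_seeds = _derive_seeds(seed, n_repeats * len(records), 21)
    for j, s in enumerate(rep_seeds):
        rec = records[j % len(records)]
        ref_r, ref_t = refs[j % len(records)]
        sub = subsample_temporal(rec, _BIN, 1, seed=s)
        sub_r, sub_t = _trend_pair(sub)
        rho_r.append(trend_agreement(ref_r, sub_r)[1])
        rho_t.append(trend_agreement(ref_t, sub_t)[1])
    return {
        "rho_richness": float(np.mean(rho_r)),
        "rho_turnover": float(np.mean(rho_t)),
        "n_repeats": n_repeats,
        "n_lakes": len(records),
    }


def spatial_resolution_experiment(
    seed: int = 1, *, n_repeats: int = 10, records=None
) -> dict:
    """Do 2 pooled lakes track the 10-lake pooled regional trends?

    The reference pools every sample from all 10 lakes; each repetition
    pools one random sample per bin from 2 randomly chosen lakes.
    """
    if records is None:
        sc = make_scenario("fenno10", seed)
        records, _ = generate_records(sc, rtol=1e-6, atol=1e-8)
    ref = subsample_spatial(records, len(records), None, _BIN, seed=0)
    ref_r, ref_t = _trend_pair(ref)
    rho_r, rho_t = [], []
    for s in _derive_seeds(seed, n_repeats, 22):
        pooled = subsample_spatial(records, 2, 1, _BIN, seed=s)
        sub_r, sub_t = _trend_pair(pooled)
        rho_r.append(trend_agreement(ref_r, sub_r)[1])
        rho_t.append(trend_agreement(ref_t, sub_t)[1])
    return {
        "rho_richness": float(np.mean(rho_r)),
        "rho_turnover": float(np.mean(rho_t)),
        "n_repeats": n_repeats,
    }


def subsample_counting_check(seed: int = 0) -> dict:
    """Retained-sample counts for k = 1, 2, 3 on a 17-bin, 3-per-bin record.

    With exactly 3 samples in each of 17 occupied 500-yr bins the thinned
    record must retain exactly 17, 34 and 51 samples.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    ages = []
    for b in range(17):
        ages.extend(rng.uniform(b * 500 + 1, (b + 1) * 500 - 1, 3))
    ages = np.sort(ages)[::-1]
    ids = [f"s{i}" for i in range(len(ages))]
    counts = rng.integers(0, 9, (5, len(ages)))
    rec = SedaRecord(
        lake="grid17",
        ages=pd.Series(ages, index=ids),
        detections=pd.DataFrame(
            counts, index=[f"t{i}" for i in range(5)], columns=ids
        ),
        n_replicates=8,
    )
    retained = {
        k: subsample_temporal(rec, 500.0, k, seed=seed + k).n_samples
        for k in (1, 2, 3)
    }
    return {"retained": retained, "n_samples": rec.n_samples}
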
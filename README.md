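# sedadyn

Process-based community modelling for sedimentary ancient DNA (sedaDNA)
time series.

Lake-sediment metabarcoding records score each taxon in each dated sample
by the number of positive PCR replicates (out of R, typically 8). Such
records are long, species-resolved time series of whole communities — rich
enough, in principle, to constrain the *processes* behind ecosystem
change: climate-driven growth, competition and facilitation, trophic
interactions, and dispersal between lakes. `sedadyn` provides the full
loop needed to test that idea on synthetic data and to apply it to real
records:

1. **simulate** a generalized Lotka–Volterra metacommunity forced by
   environmental drivers,
2. **observe** the trajectories as replicate-detection records with
   realistic biases and false positives,
3. **fit** the generating parameters back from the records by maximum
   likelihood or MCMC, and compare competing model structures by AIC,
4. **quantify** how temporal thinning and lake-network size degrade
   recovered richness and turnover trends.

It is aimed at palaeoecologists and modellers who want to couple
dynamical community models to sedaDNA (or pollen-style) records, and at
method developers who need a transparent synthetic-data generator with
known ground truth.

## The model

For species *i* = 1…S at site *k* = 1…L, abundance N<sub>ik</sub> follows

    dN_ik/dt = N_ik · g_ik + Σ_{l≠k} m_i[l,k] N_il − N_ik Σ_{l≠k} m_i[k,l]

with per-capita growth

    g_ik = b_i(u_k(t)) − Σ_j α_ij N_jk + ε Σ_j F_ij N_jk − Σ_j F_ji N_jk

where

- `b_i(u) = b0_i + r_i exp(−(u − μ_i)² / 2σ_i²)` — Gaussian niche response
  of the basal growth rate to the environmental driver u_k(t)
  (e.g. temperature),
- `α_ij` — competition (positive) or facilitation (negative) strength,
- `F_ij = a_ij / (1 + Σ_q a_iq N_q / h)` — Holling type II functional
  response with attack rates a and half-saturation h (h = ∞ gives the
  linear type I form); consumers gain with efficiency ε, resources lose,
- `m_i[l,k]` — per-capita dispersal rate of species i from site l to
  site k; the dispersal term conserves total abundance per species.

The observation model is compositional: a taxon at relative abundance x
is detected per PCR replicate with probability
`p* = (1 − e^{−c·β_t·x}) + (1 − …)·fp`, where c is a detection scale,
β_t a time-constant taxon bias (aquatics, willows), and fp a
false-positive rate. A sample's count is Binomial(R, p*). The fitting
likelihood is the product of these binomials over all taxa and samples,
evaluated by integrating the ODE and reading off relative abundances at
the dated samples.

## Worked example

Recover interaction signs and niche optima from synthetic records of
three plant species at two lakes (200 samples per core, 8 replicates):

```python
from sedadyn import FreeParameter, ModelSpec, fit_map
from sedadyn.scenarios import make_scenario, generate_records

sc = make_scenario("trio", seed=1)          # known generating model
records, traj = generate_records(sc)        # simulate + observe

spec = ModelSpec(label="recovery", free=[
    FreeParameter("alpha[0,1]", -1.0, 1.0),   # truth: +0.30 (competition)
    FreeParameter("alpha[1,0]", -1.0, 1.0),   # truth: -0.15 (facilitation)
    FreeParameter("growth.mu[0]", 1.0, 9.0),  # truth: 3.0
    FreeParameter("growth.mu[1]", 1.0, 9.0),  # truth: 5.0
    FreeParameter("growth.mu[2]", 1.0, 9.0),  # truth: 7.0
])
fit = fit_map(spec, records, sc.drivers, sc.obs, sc.initial_abundance,
              sc.t_span, base_params=sc.params, seed=2, rtol=1e-5)
print(fit.estimates)
```

Output (seed 1/2, about three minutes on one core):

```
{'alpha[0,1]': 0.3008, 'alpha[1,0]': -0.1648,
 'growth.mu[0]': 2.9666, 'growth.mu[1]': 4.9822, 'growth.mu[2]': 6.9896}
```

The competition/facilitation signs are recovered exactly and the niche
optima to about 1% — the replicate-detection records contain enough
signal to separate interaction structure from climate forcing.

The same loop is available from the shell:

```sh
sedadyn scenario --name trio --seed 1 --out bundle/
sedadyn simulate --bundle bundle/ --out traj.tsv
sedadyn fit --bundle bundle/ --model model.yaml --seed 2 --out fit.tsv
sedadyn resolution --bundle bundle/ --bin-width 500 --k 1,2,3 --out res.tsv
```

## Layout

- `sedadyn.params` / `sedadyn.model` — parameter containers, driver
  series, the ODE right-hand side and the adaptive (LSODA) integrator
- `sedadyn.observe` — observation model and record containers
- `sedadyn.scenarios` — the `trio`, `null` and `fenno10` synthetic
  study scenarios
- `sedadyn.infer` — binomial likelihood, multi-start L-BFGS-B fitting,
  emcee posterior sampling, AIC model comparison
- `sedadyn.resolution` — binning, temporal/spatial subsampling,
  richness and turnover series, penalized-spline (GAM) trends
- `sedadyn.io` / `sedadyn.cli` — TSV/YAML dialects, study bundles, the
  `sedadyn` command
- `sedadyn.experiments` — the canned validation experiments used by the
  test suite and the acceptance script

See `docs/methods.md` for the modelling assumptions, parameter
conventions and known limitations.
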
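# Methods

## Dynamical model

`sedadyn` integrates a generalized Lotka–Volterra metacommunity:

    dN_ik/dt = N_ik g_ik + Σ_{l≠k} m_i[l,k] N_il − N_ik Σ_{l≠k} m_i[k,l]
    g_ik = b_i(u_k(t)) − Σ_j α_ij N_jk + ε Σ_j F_ij N_jk − Σ_j F_ji N_jk

Assumptions worth stating explicitly:

- **Dispersal acts on dN/dt, not on the per-capita rate.** Writing the
  exchange term per-capita would be dimensionally inconsistent with
  rates m in 1/time and would not conserve individuals. With
  `m_i[from, to]` and influx Σ_l m_i[l,k] N_il, the per-species total
  across sites is exactly conserved when growth and interactions are
  off; this is verified to 1e-8 relative over 10 kyr in the tests.
- **Trophic signs are canonical**: a consumer i gains ε F_ij N_j from
  each resource j, a resource i loses F_ji N_j to each consumer j. The
  functional response is Holling type II with a shared half-saturation
  h; `h = inf` degenerates exactly to the linear (type I) form. ε and
  the attack rates both scale the gain term and are therefore
  confounded; `ModelSpec` refuses to free both at once unless
  explicitly overridden.
- **The niche response is Gaussian**, `b(u) = b0 + r exp(−(u−μ)²/2σ²)`:
  three interpretable parameters (optimum, breadth, amplitude) plus a
  baseline. A negative b0 makes species decline outside their niche;
  the form is pluggable in principle but is the only one implemented.
- **Drivers are piecewise-linear** in time with constant extrapolation
  beyond the end knots. Ages are calibrated years BP at the I/O
  boundary; internally time runs forward in model years with
  `t = age_max − age_bp`.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA (adaptive,
stiffness-switching). Defaults are rtol 1e-8 / atol 1e-10; the logistic
closed form is matched to better than 1e-6 relative everywhere, and
halving the tolerances moves the 3-species fixture by less than 1e-5
relative. Two guards keep the right-hand side well-behaved:

- an **extinction clamp**: a population below 1e-12 with negative growth
  is held (its derivative zeroed) rather than integrated into
  underflow — it can regrow if conditions improve;
- a **divergence fast-fail**: if any abundance exceeds 1e9 or becomes
  non-finite (runaway mutualism during optimizer exploration), the
  integration aborts immediately as an `IntegrationError` instead of
  letting the solver grind to step-size collapse. The fitter treats
  such evaluations as very bad, not as crashes.

Likelihood evaluations use looser tolerances (rtol 1e-5/1e-6 by
default in the fitting paths): the binomial observation noise dwarfs
integration error at that level, and it keeps a single likelihood
evaluation around 25 ms for the 3-species fixture.

## Observation model

Detection is compositional: metabarcoding replicates reflect the
proportion of a taxon's DNA, not absolute biomass. The per-replicate
detection probability is `p = 1 − exp(−c β_t x)` at relative abundance
x, a saturating curve with one interpretable scale c; β_t is a
time-constant per-taxon bias multiplier (over-represented aquatics and
willows are the field's standard examples — the key property, supported
by the data literature, is that the bias does not drift in time);
false positives are i.i.d. per replicate at rate fp, combined as
`p* = p + (1−p) fp`. Counts are Binomial(R, p*) with R = 8 replicates
by default. `fp = 0.005` is a plausibility default, not an estimate —
no quantitative false-positive rate is established for these records;
sensitivity runs should vary it.

The same `p*` defines the fitting likelihood (sum of binomial log-pmfs
over taxa × samples). A structurally impossible observation (count > 0
where `p* = 0` and fp = 0) yields −inf, returned as a value rather than
an exception so optimizers can reject the region.

## Inference

- `fit_map`: bounded L-BFGS-B from multiple seeded starts (8 by
  default, uniform in the box; a "warm" strategy perturbs the supplied
  values). Free parameters are addressed by path strings
  (`"alpha[0,1]"`, `"growth.mu[2]"`, `"obs.c"` …), so hypotheses are
  expressed as `ModelSpec`s that free some paths and pin others.
  Standard errors come from a central finite-difference observed
  information; when the Hessian is not positive definite they are
  reported as unavailable rather than invented. Estimates within
  numerical distance of a bound are flagged in the diagnostics.
- `fit_bayes`: emcee's affine-invariant ensemble with proper priors
  (uniform over the bounds, or truncated normal). Reports posterior
  medians, central 95% intervals, a split-chain Gelman–Rubin statistic
  per parameter (computed in-package; flagged, never hidden, above
  1.1), and the mean acceptance fraction.
- `compare_models`: fits each `ModelSpec` and ranks by AIC, ties broken
  by fewer parameters; a failed fit is marked and excluded without
  aborting the comparison. AIC was chosen as the simplest defensible
  criterion for nested ODE hypotheses at these sample sizes; a
  Bayes-factor route would need the `fit_bayes` machinery per model and
  is left to the user.
- Initial abundances are taken as known for synthetic bundles (they are
  part of the scenario provenance). For real records they should be
  treated as nuisance parameters or set by a burn-in; the likelihood
  takes `initial_state` explicitly so either policy is the caller's
  one-liner.

## Synthetic scenarios

The generators define the study conditions; they are first-class,
tested code.

**trio / null** — 3 plant species at 2 sites over 2 000 years under a
linear warming ramp (2→8 °C, the second site 0.5 °C warmer), niche
optima at 3/5/7 °C, breadths 1.2–1.5 °C, maximum growth ~0.1/yr and a
−0.02/yr baseline. `trio` adds one competitive link (α₀₁ = +0.30), one
facilitative link (α₁₀ = −0.15), one exploitative link
(a₂₀ = 0.4, ε = 0.3, h = 0.5) and symmetric dispersal 0.005/yr; `null`
switches all of these off. 200 evenly spaced samples per core, R = 8,
detection scale c = 6, fp = 0.005. The driver sweep moves each species
through its niche in turn, so composition turns over twice — this is
what makes the interaction parameters identifiable.

**fenno10** — a 10-lake regional network over 11.7 kyr in the style of
the densest published lake networks: 150 taxa, 60–100 randomly placed
samples per lake (≈120–195 yr mean spacing), R = 8. The driver is a
saturating deglacial warming (−2 → ≈8 °C, fast early, slow later)
followed by a gradual late cooling of ≈2 °C, with lake-specific offsets
(sd 0.3 °C) and smooth ~1 kyr wiggles. Niche optima mix a
warm-skewed triangular component with a uniform component over
(−4.5, 14) °C: the triangular part makes the regional in-niche pool
grow through the warming (richness rises from a sparse glacial flora to
~40–55 and declines somewhat with the late cooling), while the uniform
part guarantees cold-adapted taxa exist in every realization — without
them the compositional observation model renders a near-empty early
landscape as spuriously *rich*, because 150 floor-abundance taxa then
share the composition evenly. Niche breadths are 0.8–1.3 °C, narrow
enough that composition tracks the driver measurably in every 500-yr
bin; turnover is therefore high during the rapid warming, low at the
thermal maximum, and rises again under the late cooling. Species keep a
small persistence floor (b0 = 1e-4/yr, a regional seed-bank/immigration
stand-in) so they can re-expand when their niche arrives. The initial
state is the single-species niche quasi-equilibrium for the initial
climate: starting all species at a common abundance instead leaves an
unsorted transient in the oldest bins.

What these generators deliberately do **not** emulate: taphonomy and
DNA decay with depth, age–depth model uncertainty, read-count
compositionality artefacts (only replicate counts are modelled),
primer/reference-library biases beyond a static multiplier, and
non-climate drivers. Passing the validation experiments therefore shows
the inference and resolution machinery works where the model family is
true — not that real records satisfy these assumptions.

## Resolution analysis

Samples are binned into fixed-width age bins anchored at 0 BP (500 yr
default, labelled by midpoint). Richness counts taxa with at least
`min_replicates` positive replicates in at least one retained sample of
the bin; turnover between consecutive occupied bins is presence-based
Sørensen by default, with an abundance-weighted Bray–Curtis variant on
mean replicate proportions. Trends are penalized B-spline (GAM) fits —
statsmodels `GLMGam`, penalty chosen by a generalized cross-validation
grid — with pointwise ±1.96 SE bands. Series that lie exactly on a
spline (constant, line) fall back to unpenalized least squares with
zero-width bands.

The canned regional experiments (temporal k=1 thinning; pooling 2 of 10
lakes against the 10-lake pool) use `min_replicates = 2` and the
Bray–Curtis metric: with 8 replicates and fp = 0.005, single false
positives accumulate under 10-lake pooling and saturate union richness,
and presence-based turnover between single-sample bins is dominated by
set-sampling noise. Both are standard "conservative filtering" moves in
this data type; library defaults remain 1 and Sørensen.

## Problem sizes and runtime

The validation experiments are sized for a single core: the recovery
experiment fits 5 free parameters to 1 200 binomial observations with 8
starts (~3 min); the model-selection contest runs 10 repetitions per
generator with 1 start and a capped iteration budget per fit (~4 min) —
caps that are safe because the hypotheses are nested, so any ascent of
the richer model can only help the correct side; the regional
experiments generate the 10-lake scenario once (~30 s) and reuse it for
both the temporal and spatial comparisons.

## Known limitations

- The likelihood conditions on a known initial state; jointly
  estimating S×L initial abundances is supported through parameter
  paths but not exercised by the experiments.
- Standard errors from finite-difference Hessians are asymptotic; for
  boundary estimates (flagged) they are not meaningful.
- The detection curve and binomial replicate model ignore within-sample
  replicate correlation (e.g. inhibitor-rich layers).
- AIC comparison assumes the usual regularity; for hypotheses that pin
  parameters at a boundary (e.g. attack rates at 0) it is conservative.
- `resolution` treats ages as exact; chronological uncertainty is out
  of scope.
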
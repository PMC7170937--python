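# Methods

## Model

`pyrocycle` simulates one grid cell (or site) with six carbon pools —
labile, foliar, fine root, wood, litter and soil organic matter (SOM), all
in gC m⁻² — plus one plant-available water bucket (mm), on a monthly time
step. Each month, in order:

1. **Production.** GPP = `lue` · APAR · g_T · days, with LAI = foliar/`lcma`,
   APAR = ½·SW·(1 − e^(−k_ext·LAI)) and g_T = exp(`theta`·(T − T_ref))
   capped at `gt_cap`. Autotrophic respiration is Ra = `f_auto`·GPP, so the
   temperature dependence of Ra enters through g_T inside GPP; a separate
   Ra multiplier is deliberately not used (the simplest form consistent
   with photosynthetic capacity depending on the foliar pool).
2. **Allocation.** NPP = GPP − Ra is split among labile, foliar, fine root
   and wood (`alloc_*`; wood takes the remainder); the labile pool releases
   to foliar at `labile_release` per month — a minimal stand-in for
   phenology.
3. **Turnover.** Foliar and fine-root turnover feed litter; wood turnover
   feeds SOM.
4. **Decomposition.** Litter and SOM mineralize at `decomp_*`·g_T·g_W and
   litter humifies to SOM at `lit2som`·g_T·g_W, where g_W = W/(W+`w_half`)
   is a saturating moisture scalar applied to heterotrophic respiration
   only.
5. **Fire.** Where a fraction `ba` of the cell burns, each pool combusts
   C·ba·cc (labile and fine roots share `cc_foliar`; wood uses the
   structural factor `cc_wood`), and each live pool additionally transfers
   C·ba·(1−cc)·(1−`resilience`) to litter as fire-induced mortality. All
   mortality goes to litter — the simplest routing of live biomass to dead
   organic matter; wood's *natural* turnover still goes to SOM. Fire does
   not add mortality to the dead pools beyond their combustion.
6. **Water.** W′ = clip(W + P − GPP/`wue`, 0, `w_max`). The bucket is an
   assumption (no soil-physics source exists for this model family at this
   resolution): evapotranspiration proportional to GPP with a fixed
   water-use efficiency of 2 gC per mm, capacity 250 mm.

Structural constants live in `ModelConfig`: k_ext = 0.5, T_ref = 15 °C,
gt_cap = 5, w_max = 250 mm, wue = 2 gC mm⁻¹.

**Numerics.** Whenever the fluxes demanded of a pool in one phase exceed its
content, all outfluxes of that pool are scaled by a common factor so it ends
the phase at exactly zero. Pools therefore never go negative and monthly
carbon closure — ΔC = GPP − Ra − Rh − Fire — holds to machine precision by
construction; the test suite asserts it at 1e-9 relative over thousands of
random parameter sets. Fire emission is exactly linear in the burned
fraction within a month.

Sign conventions: NEE = TER − GPP, NBE = NEE + FIRE; positive fluxes go
from land to atmosphere.

## Model–data fusion

Parameters (20) and the six initial carbon pools are estimated per cell by
random-walk Metropolis–Hastings in a transformed space: log for positive
rates and stocks, scaled logit for bounded fractions. Priors are proper and
weakly informative — log-uniform over generous physical ranges for rates,
uniform on the support for fractions — with the allocation fractions
jointly constrained to sum to at most 1. The likelihood is a sum of
independent Gaussian terms over up to five streams: monthly LAI
(= foliar/`lcma`), monthly *z-scored* GPP (so only variability, not
magnitude, constrains the model — matching what solar-induced fluorescence
provides), one time-mean aboveground biomass (wood + foliar), one SOM
stock, and annual fire emissions. Any stream may be absent; a non-finite
likelihood rejects the proposal.

The sampler is a Laplace-preconditioned replica-exchange (parallel
tempering) Metropolis scheme. A quasi-Newton (L-BFGS-B) search finds the
posterior mode in transformed space and a central-difference Hessian gives
a Laplace covariance, which seeds the proposal (scaled 2.38²/d). Four
replicas target prior × likelihood^β with β = (1, 0.55, 0.3, 0.15); each is
a random-walk Metropolis chain with burn-in-only adaptation (scalar step
tuned toward ~0.3 acceptance; covariance refreshed from the most recent
half of the burn-in history), and adjacent replicas attempt a state swap
every other sweep. The iteration budget counts all replica updates, and the
cold chain's post-burn-in draws form the posterior. Defaults: burn-in 30%,
thinning 10. The split-chain potential-scale-reduction diagnostic
(`convergence_diag`) quantifies residual non-convergence across repeated
runs.

This design replaces the simpler single-chain diagonal-proposal sampler for
two measured reasons. First, the posterior has strong correlations
(combustion completeness × fuel stocks, `lue` × allocation × `lcma`) along
which a diagonal proposal mixes far too slowly; the full-covariance
adaptive proposal follows the ridge. Second, the fire parameters are
genuinely multimodal under sparse fire constraints: multi-start
optimization on fixture realizations finds distinct local optima of nearly
equal posterior density (e.g. combustion completeness 0.54 vs 0.69 vs 0.95
with compensating fuel stocks, within ~0.2 log-posterior units), and a
single chain at practical lengths samples one basin only. The tempered
replicas flatten the barriers so the cold chain crosses between basins;
within a fixed update budget this recovers most, but not all, of the
interval width a 10×-longer chain attains — the residual under-coverage is
an honest cost of finite budgets that `convergence_diag` makes visible.

## Counterfactual scenarios

`build_fixed_ba` replaces the burned area inside an experiment window with
the *monthly climatology* of a baseline period (per calendar month, not an
annual scalar — this preserves fire seasonality). `extend_forcing` appends
years by cyclically recycling a chosen span, meteorology and burned area
alike. `run_delta` then simulates observed and control forcing with the
*same* parameter draw and initial state per ensemble member and differences
the fluxes (observed minus control), so the Δ series carry no parameter
noise: ΔNEE = ΔTER − ΔGPP and ΔNBE = ΔNEE + ΔFIRE hold exactly per draw.
Because both scenarios share the burned area beyond the window, later
differences are pure legacy effects of the pool-state divergence.
Parameters are frozen from the fusion — there is no re-assimilation inside
the counterfactual.

`nbe_neutrality_time` operationalizes "NBE returns to neutral", which has
no canonical numeric definition: the annual ensemble-median |ΔNBE| series,
indexed k = 0, 1, … years since the perturbation start, is compared against
a configurable fraction (default 5%) of its peak; the first year at or
after the peak below that threshold is returned, an all-zero series returns
1 (neutral within the first year), and a too-short horizon returns `None`
rather than extrapolating.

## Burned-area statistics and emission conversion

Gridded burned area aggregates to coarser grids by block sum (absolute
area) or area-weighted mean (fractions) on cos-latitude cell areas, exactly
conserving totals. Per-land-cover change between two equal-length periods
pairs years by position; its uncertainty is the standard deviation of the
paired year-to-year differences divided by √n. The percent trend is the OLS
slope divided by the *period-mean* value (×100) — the mean, not the
first-year value, is used as denominator so the statistic is symmetric in
time and scale-invariant; a constant series returns (0, p = 1) by
convention. CO-to-carbon conversion multiplies by a biome emission-factor
ratio ρ with relative uncertainties combined in quadrature,
(σ_C/C)² = (σ_CO/CO)² + (σ_ρ/ρ)²; zero-CO years fall back to absolute
propagation σ_C = ρ·σ_CO, and biome-stratified series sum with
independent-error quadrature.

## Airborne-fraction accounting

With yearly budget terms E_FF, E_LUC, G_ATM, S_OCEAN, S_LAND (PgC yr⁻¹):
AF_obs = G_ATM/(E_FF+E_LUC), AF_process = 1 − (S_OCEAN+S_LAND)/(E_FF+E_LUC),
and the fire-adjusted AF = 1 − (S_OCEAN+S_LAND−ΔFIRE−ΔNEE)/(E_FF+E_LUC),
where the Δ terms keep the land-to-atmosphere sign of the scenario module
(negative = extra sink, subtracted from the sinks). When ΔFIRE+ΔNEE equals
the yearly budget residual exactly, the adjusted series reproduces AF_obs
identically — an algebraic identity the tests enforce at 1e-12 on random
tables, which doubles as a sign-convention guard. An optional anchoring
re-expresses the Δ series relative to their mean over chosen reference
years. S_LAND is used as reported; no re-distribution of the published
budget imbalance is attempted.

## Synthetic data

The generators produce, with one root seed and per-stream child generators
(adding a stream never perturbs existing draws):

- **Forcing:** sinusoidal seasonal temperature, radiation and precipitation
  with lognormal interannual factors (cv 0.1) and a wet season opposite the
  radiation peak; burned area concentrated in the dry season by a
  von-Mises-shaped monthly profile, with second-half annual burning equal to
  `decline_factor` × the first half (exactly so at zero interannual cv).
- **Truth runs:** the truth parameters simulated after a 300-year spin-up at
  the first-period fire regime. Fifty years (an earlier default) leaves the
  SOM pool — residence time of order a century — visibly drifting, which
  would contaminate the counterfactuals with spin-up transients; 300 years
  brings the state close to the fire-inclusive quasi-steady state the
  analysis assumes.
- **Observations:** LAI and z-scored GPP with additive Gaussian noise
  (σ = 0.25 and 0.3), biomass, SOM and annual fire emissions with relative
  noise (10%, 20%, 15%); the recorded uncertainties are exactly the noise
  levels used.
- **Budget tables:** rising fossil emissions, small land-use emissions,
  growth ≈ 45% of emissions, and a land sink constructed to leave a
  prescribed yearly imbalance plus noise.

The packaged reference scenario (`fixture_savanna_decline`, frozen seed) is
a frequently burning tropical savanna: annual burned fraction 0.25,
leaf residence ≈ 1 year, wood residence ≈ 17 years, high foliar (0.7) and
low structural (0.15) combustion completeness, burned-area decline factor
0.8 between two 7-year periods, 30 recycled extension years. Its truth run
has LAI ≈ 0.7–1.1, GPP ≈ 760 gC m⁻² yr⁻¹, fire ≈ 82 gC m⁻² yr⁻¹ and mean
NBE within 5% of zero — realistic magnitudes for dry savanna. A frozen
regression file records its summary outputs (annual GPP/fire, window-mean
ΔFIRE and ΔNEE, legacy-window means, NBE-neutrality year) so refactors
cannot silently change the science.

**What the synthetic data do not emulate:** spatial covariance between
cells, observation-error autocorrelation, drifting climate, CO₂
fertilization, land-use change, nutrient or grazing limits, and plant
functional type diversity. Passing tests therefore demonstrate the
machinery — conservation, estimation, counterfactual logic, bookkeeping —
on data whose generating process matches the model, not the fidelity of
any real-world magnitude.

## Problem sizes used in tests

Tests and the acceptance script run single-cell studies: 168-month
(14-year) windows, 30-year extensions, 5×10⁴-iteration chains, ensembles of
up to a few hundred draws, and small (≤ 8×8) grids for the burned-area
statistics — sizes chosen so a full run remains a desk-scale computation
while every code path, including the gridded ones, is exercised.

## Known limitations

- GPP responds to water only through the (weak) link of g_W on
  decomposition; droughts do not suppress photosynthesis directly.
- One aggregated cell: no fire spread, no spatial heterogeneity in fuel.
- The labile-release constant is a crude phenology; deciduousness and
  green-up timing are not represented.
- The MH sampler's pooled-chain intervals are honest only up to the
  residual between-chain disagreement reported by `convergence_diag`;
  strongly ridge-shaped posteriors (weakly identified combustion factors
  under sparse fire constraints) mix slowly at small iteration budgets.
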
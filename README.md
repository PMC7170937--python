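# pyrocycle

Fire-aware terrestrial carbon-cycle modelling, Bayesian model–data fusion
and burned-area counterfactuals, for a single grid cell or small grids.

Wildfire burns roughly enough carbon each year to matter for the global
carbon budget, and where burned area *declines*, two things happen: less
carbon is combusted immediately (the direct effect), and the spared
vegetation regrows, photosynthesizes more and shifts the whole carbon cycle
toward a sink for years afterwards (the indirect, legacy effect).
`pyrocycle` packages the machinery needed to quantify both: a compact
carbon box model with a prescribed-burned-area fire module, a
Metropolis–Hastings model–data fusion layer that constrains the model with
satellite-like observation streams, paired counterfactual experiments that
isolate the fire-decline response, and airborne-fraction bookkeeping that
translates the result into global carbon-budget terms. It is aimed at
carbon-cycle researchers who want a transparent, testable, desk-scale
implementation of this analysis chain, exercised end to end on synthetic
data with known truth.

## The model in brief

Six carbon pools (labile, foliar, fine root, wood, litter, soil organic
matter) plus a water bucket, monthly steps:

- GPP = LUE · APAR(LAI) · g_T · days, with APAR from Beer–Lambert light
  interception of the foliar pool; Ra = f_auto · GPP; NPP is allocated to
  the live pools.
- Turnover feeds litter and soil; decomposition scales with temperature
  (exponential, sensitivity θ) and moisture (Michaelis–Menten in
  plant-available water).
- Fire, driven by a prescribed monthly burned-area fraction `ba`: each pool
  combusts C·ba·cc with pool-specific combustion completeness `cc`, and each
  live pool transfers C·ba·(1−cc)·(1−resilience) to litter as fire-induced
  mortality. Fluxes combine as NEE = TER − GPP and NBE = NEE + FIRE
  (positive = land to atmosphere).

Carbon is conserved to machine precision each month, pools can never go
negative, and fire emission is exactly linear in burned fraction — the test
suite asserts all three. Estimation is by adaptive random-walk
Metropolis–Hastings (Laplace-preconditioned, burn-in-only adaptation)
against monthly LAI, z-scored GPP variability, biomass and soil-carbon
stocks, and annual fire emissions. See `docs/methods.md` for the full
model, priors, numerics and design choices.

## Worked example

`examples/fire_decline_counterfactual.py` runs the packaged savanna
scenario — a frequently burning dry-tropics cell whose burned area drops
20% between 2001–2007 and 2008–2014 — and prints:

```
2008-2014 window means (gC m-2 yr-1):
  dFIRE  -11.66   direct combustion saving
  dNEE   -27.52   indirect sink enhancement
  indirect/direct ratio 2.36 (the carbon-cycle feedback outweighs the combustion saving)

legacy |dNEE| by post-window years: 2015-2019: 6.95 2020-2024: 3.86 2025-2034: 3.36
NBE neutrality reached 11 years after the perturbation began (5%-of-peak criterion)
```

Read: holding everything else equal, the burned-area decline saves
~12 gC m⁻² yr⁻¹ of direct combustion but triggers an indirect sink more
than twice as large, because spared foliage raises GPP faster than
respiration catches up. After the burned-area scenarios reconverge in 2015
the sink legacy decays roughly exponentially, and the net biome exchange
returns to neutral within about a decade — savanna pools turn over fast.

The other examples cover the forward model (`simulate_fire_regime.py`),
parameter estimation with credible intervals (`fit_parameters.py`) and the
airborne-fraction adjustment (`airborne_fraction.py`). A thin CLI mirrors
the same steps (`pyrocycle --help`; subcommands `simulate`, `fit`,
`scenario`, `synth`, `ba-stats`, `budget`, `pipeline`).

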
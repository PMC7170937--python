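"""Synthetic forcing, truth runs, pseudo-observations and budget tables.

The generators emulate the statistical structure of the real input streams
— seasonal reanalysis-like meteorology, a burned-area regime concentrated
in the dry season with a decadal decline between two equal periods,
satellite-like observation streams with stated noise, and a yearly global
carbon-budget table — so the full analysis is testable end to end against
a known truth without any external download.

Randomness contract: one root seed; each generator stream draws from its
own child generator (``default_rng([stream_id, seed])``), so adding a
stream never perturbs the draws of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .budget import BudgetTable
from .carbon_model import simulate
from .fusion import ObservationSet, ObsStream
from .observations import GriddedBA, LandCoverMap
from .types import DEFAULT_CONFIG, ForcingSeries, ModelConfig, ParameterSet, PoolState, Trajectory

__all__ = [
    "ClimateConfig",
    "BARegime",
    "NoiseConfig",
    "SyntheticConfig",
    "savanna_truth",
    "gen_forcing",
    "gen_truth_run",
    "gen_observations",
    "gen_budget_table",
    "gen_gridded_ba",
    "fixture_savanna_decline",
    "FIXTURE_SEED",
]

_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

# stream ids for per-stream child generators
_MET, _BA, _OBS, _GRID = 11, 12, 13, 14


@dataclass(frozen=True)
class ClimateConfig:
    """Sinusoidal seasonal climate with lognormal interannual noise.

    Defaults describe a dry-tropics (savanna) site: warm year-round with a
    pronounced wet season centred on ``wet_month`` (0-based calendar month).
    """

    t_mean_avg: float = 25.0  # degC
    t_amp: float = 3.0
    sw_avg: float = 20.0  # MJ m-2 d-1
    sw_amp: float = 3.0
    precip_avg: float = 80.0  # mm month-1
    precip_amp: float = 70.0
    wet_month: int = 1
    interannual_cv: float = 0.1  # lognormal cv on precip and radiation
    t_sd: float = 0.5  # additive interannual degC noise


@dataclass(frozen=True)
class BARegime:
    """Burned-area regime: seasonal concentration plus a decadal decline.

    ``annual_frac`` is the mean burned fraction of the cell per year during
    the first half of the record; annual totals in the second half equal
    ``decline_factor`` times the first half (exactly so when
    ``interannual_cv`` is zero).
    """

    annual_frac: float = 0.25
    peak_month: int = 7  # dry-season burning peak (0-based)
    concentration: float = 2.0  # von-Mises-like seasonal concentration
    decline_factor: float = 0.8
    interannual_cv: float = 0.1

    def seasonal_profile(self) -> np.ndarray:
        c = np.arange(12)
        w = np.exp(self.concentration * np.cos(2 * np.pi * (c - self.peak_month) / 12))
        return w / w.sum()


@dataclass(frozen=True)
class NoiseConfig:
    """Per-stream observation noise (1 sigma)."""

    lai_sd: float = 0.25  # absolute, m2 m-2
    gpp_anom_sd: float = 0.3  # absolute, z-score units
    biomass_rel_sd: float = 0.10
    som_rel_sd: float = 0.20
    fire_rel_sd: float = 0.15


def savanna_truth() -> ParameterSet:
    """Reference truth parameters for a frequently burning tropical savanna.

    Short-lived foliage (about a year), a wood residence time of roughly
    twenty years, high foliar and low structural combustion completeness,
    and moderate fire resilience.
    """
    return ParameterSet(
        lue=0.35, f_auto=0.5,
        alloc_foliar=0.16, alloc_labile=0.06, alloc_root=0.30,
        labile_release=0.25, lcma=70.0,
        turn_foliar=0.08, turn_root=0.06, turn_wood=0.005,
        decomp_litter=0.08, decomp_som=0.0008, lit2som=0.02,
        theta=0.05, w_half=50.0,
        cc_foliar=0.7, cc_wood=0.15, cc_litter=0.5, cc_som=0.005,
        resilience=0.3,
    )


@dataclass
class SyntheticConfig:
    """Everything needed to generate one synthetic study."""

    seed: int = 0
    n_years: int = 14
    start_year: int = 2001
    spinup_years: int = 300
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    ba: BARegime = field(default_factory=BARegime)
    truth: ParameterSet = field(default_factory=savanna_truth)
    init: PoolState | None = None  # start of spin-up; None = default stocks
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0 < self.ba.decline_factor <= 1:
            raise ValueError("decline_factor must lie in (0, 1]")


def _seasonal(avg: float, amp: float, phase_month: int) -> np.ndarray:
    c = np.arange(12)
    return avg + amp * np.cos(2 * np.pi * (c - phase_month) / 12)


def gen_forcing(config: SyntheticConfig, decline: bool = True) -> ForcingSeries:
    """Generate monthly meteorology and burned area for ``config.n_years``.

    With ``decline=False`` the burned-area decline factor is ignored (used
    for the pre-study spin-up, which runs at the first-period fire regime).
    """
    n_years = config.n_years
    cl, ba = config.climate, config.ba
    rng_met = np.random.default_rng([_MET, config.seed])
    rng_ba = np.random.default_rng([_BA, config.seed])

    t_clim = _seasonal(cl.t_mean_avg, cl.t_amp, cl.wet_month)
    sw_clim = _seasonal(cl.sw_avg, cl.sw_amp, (cl.wet_month + 6) % 12)
    pr_clim = np.maximum(_seasonal(cl.precip_avg, cl.precip_amp, cl.wet_month), 0.0)

    t_mean = np.tile(t_clim, n_years)
    sw = np.tile(sw_clim, n_years)
    pr = np.tile(pr_clim, n_years)
    if cl.interannual_cv > 0:
        sig = np.sqrt(np.log1p(cl.interannual_cv**2))
        f_pr = np.exp(rng_met.normal(-0.5 * sig**2, sig, n_years))
        f_sw = np.exp(rng_met.normal(-0.5 * sig**2, sig, n_years))
        pr = pr * np.repeat(f_pr, 12)
        sw = sw * np.repeat(f_sw, 12)
    if cl.t_sd > 0:
        t_mean = t_mean + np.repeat(rng_met.normal(0.0, cl.t_sd, n_years), 12)

    profile = ba.seasonal_profile()
    year_fac = np.ones(n_years)
    if decline:
        year_fac[n_years // 2:] = ba.decline_factor
    if ba.interannual_cv > 0:
        sig = np.sqrt(np.log1p(ba.interannual_cv**2))
        year_fac = year_fac * np.exp(rng_ba.normal(-0.5 * sig**2, sig, n_years))
    ba_frac = np.clip(
        ba.annual_frac * np.repeat(year_fac, 12) * np.tile(profile, n_years),
        0.0, 1.0,
    )
    return ForcingSeries(
        t_mean=t_mean, precip=pr, sw_rad=sw,
        days=np.tile(_DAYS, n_years), ba_frac=ba_frac,
        start_year=config.start_year,
    )


_DEFAULT_SPINUP_START = PoolState(labile=50.0, foliar=150.0, fine_root=150.0,
                                  wood=1500.0, litter=300.0, som=8000.0,
                                  water=100.0)


def spinup_state(config: SyntheticConfig,
                 model_config: ModelConfig = DEFAULT_CONFIG) -> PoolState:
    """Pools after ``spinup_years`` at the first-period fire regime.

    Brings the pools near the fire-inclusive quasi-steady state, so the
    study window starts from a dynamic-equilibrium-like condition.
    """
    if config.spinup_years <= 0:
        return config.init or _DEFAULT_SPINUP_START
    spin_cfg = replace(config, n_years=config.spinup_years,
                       seed=config.seed + 1_000_003)
    spin_forcing = gen_forcing(spin_cfg, decline=False)
    start = config.init or _DEFAULT_SPINUP_START
    traj = simulate(config.truth, start, spin_forcing, model_config)
    return traj.state(-1)


def gen_truth_run(config: SyntheticConfig,
                  model_config: ModelConfig = DEFAULT_CONFIG) -> Trajectory:
    """Simulate the truth parameters over the study window after spin-up."""
    init = spinup_state(config, model_config)
    forcing = gen_forcing(config)
    return simulate(config.truth, init, forcing, model_config)


def gen_observations(truth: Trajectory, config: SyntheticConfig) -> ObservationSet:
    """Noisy pseudo-observations of a truth trajectory.

    LAI and z-scored GPP get additive Gaussian noise; the biomass and SOC
    stocks and the annual fire emissions get relative Gaussian noise. The
    uncertainties recorded in the ObservationSet are exactly the noise
    standard deviations used.
    """
    rng = np.random.default_rng([_OBS, config.seed])
    nz = config.noise
    p = config.truth

    lai_true = truth.pool("foliar") / p.lcma
    lai = ObsStream(values=lai_true + rng.normal(0, nz.lai_sd, lai_true.size),
                    sd=np.full(lai_true.size, nz.lai_sd),
                    times=np.arange(lai_true.size))

    gpp = truth.gpp
    z = (gpp - gpp.mean()) / gpp.std()
    gpp_anom = ObsStream(values=z + rng.normal(0, nz.gpp_anom_sd, z.size),
                         sd=np.full(z.size, nz.gpp_anom_sd),
                         times=np.arange(z.size))

    agb_true = float((truth.pool("wood") + truth.pool("foliar")).mean())
    agb_sd = nz.biomass_rel_sd * agb_true
    biomass = ObsStream(values=[agb_true + rng.normal(0, agb_sd)], sd=[agb_sd])

    som_true = float(truth.pool("som").mean())
    som_sd = nz.som_rel_sd * som_true
    som = ObsStream(values=[som_true + rng.normal(0, som_sd)], sd=[som_sd])

    fire_true = truth.fire_emission.reshape(-1, 12).sum(axis=1)
    fire_sd = nz.fire_rel_sd * np.abs(fire_true)
    fire_sd = np.maximum(fire_sd, 1e-6 + 0.01 * nz.fire_rel_sd * fire_true.mean())
    fire = ObsStream(values=fire_true + rng.normal(0, 1, fire_true.size) * fire_sd,
                     sd=fire_sd, times=np.arange(fire_true.size))

    return ObservationSet(lai=lai, gpp_anom=gpp_anom, biomass=biomass,
                          som=som, fire_annual=fire)


def gen_budget_table(
    seed: int,
    n_years: int = 14,
    imbalance: float = 0.6,
    noise_sd: float = 0.1,
    start_year: int = 2001,
) -> BudgetTable:
    """Synthetic yearly carbon-budget table (all PgC yr^-1).

    Fossil emissions rise smoothly, land-use emissions stay small, the
    atmospheric growth follows roughly 45% of total emissions with
    interannual variability, and the land sink is constructed so the
    yearly residual equals ``imbalance`` plus N(0, noise_sd) noise.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng([21, seed])
    t = np.arange(n_years, dtype=float)
    e_ff = 8.0 + 0.15 * t + rng.normal(0, 0.05, n_years)
    e_luc = 1.4 + rng.normal(0, 0.1, n_years)
    em = e_ff + e_luc
    g_atm = 0.45 * em + rng.normal(0, 0.4, n_years)
    s_ocean = 2.3 + 0.02 * t + rng.normal(0, 0.1, n_years)
    resid_noise = rng.normal(0, noise_sd, n_years) if noise_sd > 0 else np.zeros(n_years)
    s_land = em - g_atm - s_ocean - imbalance - resid_noise
    return BudgetTable(years=start_year + np.arange(n_years), e_ff=e_ff,
                       e_luc=e_luc, g_atm=g_atm, s_ocean=s_ocean, s_land=s_land)


def gen_gridded_ba(
    seed: int,
    n_years: int = 14,
    nlat: int = 8,
    nlon: int = 8,
    start_year: int = 2001,
    decline_factor: float = 0.8,
    trend_per_year: float = -0.015,
) -> tuple[GriddedBA, LandCoverMap]:
    """Small gridded burned-area field with a land-cover map.

    Cells are assigned savanna-like classes with distinct fire frequencies;
    burned fractions decline linearly by ``trend_per_year`` (relative) and
    drop by ``decline_factor`` between the two halves of the record, with
    lognormal interannual noise.
    """
    rng = np.random.default_rng([_GRID, seed])
    labels = {0: "savanna", 1: "woody_savanna", 2: "grassland", 3: "forest"}
    base_frac = {0: 0.30, 1: 0.20, 2: 0.15, 3: 0.01}
    classes = rng.integers(0, 4, size=(nlat, nlon))
    lat = -20.0 + 5.0 * (np.arange(nlat) + 0.5)
    lon = -20.0 + 5.0 * (np.arange(nlon) + 0.5)
    profile = BARegime().seasonal_profile()

    data = np.zeros((n_years * 12, nlat, nlon))
    sig = np.sqrt(np.log1p(0.08**2))
    for iy in range(n_years):
        level = 1.0 + trend_per_year * iy
        if iy >= n_years // 2:
            level *= decline_factor
        noise = np.exp(rng.normal(-0.5 * sig**2, sig, (nlat, nlon)))
        for cid, frac in base_frac.items():
            mask = classes == cid
            annual = frac * level * noise
            for m in range(12):
                data[iy * 12 + m][mask] = (annual * profile[m])[mask]
    ba = GriddedBA(data=np.clip(data, 0, 1), lat=lat, lon=lon,
                   start_year=start_year, is_fraction=True)
    return ba, LandCoverMap(classes=classes, labels=labels)


# ---------------------------------------------------------------------------
# packaged reference scenario
# ---------------------------------------------------------------------------

FIXTURE_SEED = 1203


@dataclass
class FixtureBundle:
    """The packaged savanna fire-decline reference scenario."""

    config: SyntheticConfig
    forcing: ForcingSeries
    truth: Trajectory
    obs: ObservationSet
    baseline_years: tuple[int, int]
    window_years: tuple[int, int]
    extension_years: int


def fixture_savanna_decline(seed: int = FIXTURE_SEED) -> FixtureBundle:
    """Reference scenario: a burning savanna with a 20% second-period decline.

    A 14-year study window (two 7-year periods), dry-tropics seasonality,
    short wood residence time and a burned-area decline factor of 0.8;
    counterfactual runs extend 30 years beyond the window by recycling
    the window forcing.
    """
    config = SyntheticConfig(seed=seed)
    truth = gen_truth_run(config)
    forcing = gen_forcing(config)
    obs = gen_observations(truth, config)
    return FixtureBundle(
        config=config, forcing=forcing, truth=truth, obs=obs,
        baseline_years=(2001, 2007), window_years=(2008, 2014),
        extension_years=30,
    )


def load_fixture_regression() -> dict:
    """Frozen summary values of the fixture truth run (regression guard)."""
    path = resources.files("pyrocycle").joinpath("data/savanna_regression.json")
    return json.loads(path.read_text())
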
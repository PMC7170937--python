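"""Core domain containers: pools, parameters, forcing, fluxes, trajectories.

The model tracks six carbon pools (labile, foliar, fine root, wood, litter,
soil organic matter; all gC m^-2) plus one plant-available water pool (mm)
for a single grid cell or site, driven by monthly meteorology and a
prescribed monthly burned-area fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CARBON_POOLS",
    "POOL_NAMES",
    "PARAM_NAMES",
    "FLUX_NAMES",
    "ModelConfig",
    "PoolState",
    "ParameterSet",
    "MetRecord",
    "ForcingSeries",
    "FluxRecord",
    "Trajectory",
]

#: carbon pools, in canonical vector order (water is appended last)
CARBON_POOLS = ("labile", "foliar", "fine_root", "wood", "litter", "som")
POOL_NAMES = CARBON_POOLS + ("water",)

#: model parameters, in canonical vector order
PARAM_NAMES = (
    "lue",
    "f_auto",
    "alloc_foliar",
    "alloc_labile",
    "alloc_root",
    "labile_release",
    "lcma",
    "turn_foliar",
    "turn_root",
    "turn_wood",
    "decomp_litter",
    "decomp_som",
    "lit2som",
    "theta",
    "w_half",
    "cc_foliar",
    "cc_wood",
    "cc_litter",
    "cc_som",
    "resilience",
)

#: primitive monthly fluxes recorded per step, in canonical column order
FLUX_NAMES = (
    "gpp",
    "ra",
    "rh_litter",
    "rh_som",
    "fire_emission",
    "mort_labile",
    "mort_foliar",
    "mort_root",
    "mort_wood",
)


@dataclass(frozen=True)
class ModelConfig:
    """Fixed structural constants of the model.

    Parameters
    ----------
    k_ext : canopy light-extinction coefficient in the Beer-Lambert
        absorbed-radiation term (dimensionless).
    t_ref : reference temperature of the exponential temperature scalar (degC).
    gt_cap : upper cap on the temperature scalar ``g_T = exp(theta*(T - t_ref))``.
    w_max : plant-available water holding capacity of the bucket (mm).
    wue : water-use efficiency linking evapotranspiration to GPP,
        gC per mm of water (E = GPP / wue).
    """

    k_ext: float = 0.5
    t_ref: float = 15.0
    gt_cap: float = 5.0
    w_max: float = 250.0
    wue: float = 2.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k_ext, self.t_ref, self.gt_cap, self.w_max, self.wue], dtype=float
        )


DEFAULT_CONFIG = ModelConfig()


@dataclass
class PoolState:
    """Six carbon pools (gC m^-2) plus plant-available water (mm)."""

    labile: float
    foliar: float
    fine_root: float
    wood: float
    litter: float
    som: float
    water: float = 100.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"pool {f.name!r} must be finite and >= 0, got {v}")

    @property
    def total_carbon(self) -> float:
        """Sum of the six carbon pools; water is excluded."""
        return self.labile + self.foliar + self.fine_root + self.wood + self.litter + self.som

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in POOL_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PoolState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"expected a length-7 pool vector, got shape {arr.shape}")
        return cls(**dict(zip(POOL_NAMES, arr)))

    def replace(self, **kw) -> "PoolState":
        return replace(self, **kw)


@dataclass
class ParameterSet:
    """Per-cell carbon-cycle and fire parameters.

    Rates are per month; fractions are dimensionless. ``cc_*`` are combustion
    completeness factors (fraction of a pool combusted where the cell burns);
    ``resilience`` damps fire-induced mortality of the unburned live biomass:
    each live pool transfers ``C * ba * (1 - cc) * (1 - resilience)`` to litter.
    The labile and fine-root pools share the foliar combustion factor and wood
    uses the structural one.
    """

    lue: float  # light-use efficiency, gC per MJ absorbed PAR
    f_auto: float  # autotrophic respiration fraction of GPP
    alloc_foliar: float
    alloc_labile: float
    alloc_root: float  # wood receives the remaining NPP fraction
    labile_release: float  # labile -> foliar release rate, month^-1
    lcma: float  # leaf carbon mass per unit LAI, gC m^-2
    turn_foliar: float  # month^-1, foliar -> litter
    turn_root: float  # month^-1, fine root -> litter
    turn_wood: float  # month^-1, wood -> som
    decomp_litter: float  # base litter mineralization, month^-1
    decomp_som: float  # base SOM mineralization, month^-1
    lit2som: float  # litter -> SOM humification, month^-1
    theta: float  # exponential temperature sensitivity (degC^-1)
    w_half: float  # half-saturation of the moisture scalar on Rh, mm
    cc_foliar: float
    cc_wood: float
    cc_litter: float
    cc_som: float
    resilience: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = (
            "f_auto",
            "alloc_foliar",
            "alloc_labile",
            "alloc_root",
            "cc_foliar",
            "cc_wood",
            "cc_litter",
            "cc_som",
            "resilience",
        )
        for name in fracs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.alloc_foliar + self.alloc_labile + self.alloc_root > 1.0 + 1e-12:
            raise ValueError("allocation fractions must sum to <= 1")
        for name in ("lue", "lcma", "w_half", "labile_release", "turn_foliar",
                     "turn_root", "turn_wood", "decomp_litter", "decomp_som",
                     "lit2som", "theta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def alloc_wood(self) -> float:
        return 1.0 - self.alloc_foliar - self.alloc_labile - self.alloc_root

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected a length-{len(PARAM_NAMES)} parameter vector, got {arr.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class MetRecord:
    """One month of meteorological forcing."""

    t_mean: float  # degC
    precip: float  # mm month^-1
    sw_rad: float  # MJ m^-2 d^-1 (shortwave)
    days: float = 30.0  # days in month

    def __post_init__(self) -> None:
        if self.precip < 0 or self.sw_rad < 0:
            raise ValueError("precip and sw_rad must be >= 0")
        if not 28.0 <= self.days <= 31.0:
            raise ValueError(f"days in month must be in [28, 31], got {self.days}")


@dataclass
class ForcingSeries:
    """Monthly meteorology plus burned-area fraction for one cell.

    This is the object the counterfactual scenarios rewrite: the burned-area
    channel can be replaced without touching the meteorology.
    """

    t_mean: np.ndarray
    precip: np.ndarray
    sw_rad: np.ndarray
    days: np.ndarray
    ba_frac: np.ndarray  # fraction of the cell burned per month, in [0, 1]
    start_year: int = 2001

    def __post_init__(self) -> None:
        arrs = {}
        n = None
        for name in ("t_mean", "precip", "sw_rad", "days", "ba_frac"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all forcing channels must have the same length")
            arrs[name] = a
        for name, a in arrs.items():
            setattr(self, name, a)
        if n == 0:
            raise ValueError("forcing series must contain at least one month")
        if np.any(self.ba_frac < 0) or np.any(self.ba_frac > 1):
            raise ValueError("ba_frac must lie in [0, 1] for every month")
        if np.any(self.precip < 0) or np.any(self.sw_rad < 0):
            raise ValueError("precip and sw_rad must be >= 0")

    @property
    def n_months(self) -> int:
        return self.t_mean.size

    @property
    def n_years(self) -> int:
        return self.n_months // 12

    @property
    def years(self) -> np.ndarray:
        """Calendar year of each month."""
        return self.start_year + np.arange(self.n_months) // 12

    def month_slice(self, year_from: int, year_to: int) -> slice:
        """Month index slice covering calendar years ``year_from..year_to`` inclusive."""
        i0 = (year_from - self.start_year) * 12
        i1 = (year_to - self.start_year + 1) * 12
        if i0 < 0 or i1 > self.n_months or i0 >= i1:
            raise ValueError(
                f"years {year_from}-{year_to} outside forcing span "
                f"{self.start_year}-{self.start_year + self.n_years - 1}"
            )
        return slice(i0, i1)

    def record(self, i: int) -> MetRecord:
        return MetRecord(
            t_mean=self.t_mean[i], precip=self.precip[i],
            sw_rad=self.sw_rad[i], days=self.days[i],
        )

    def copy(self) -> "ForcingSeries":
        return ForcingSeries(
            t_mean=self.t_mean.copy(), precip=self.precip.copy(),
            sw_rad=self.sw_rad.copy(), days=self.days.copy(),
            ba_frac=self.ba_frac.copy(), start_year=self.start_year,
        )

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        month = np.arange(self.n_months) % 12 + 1
        return pd.DataFrame(
            {
                "year": self.years,
                "month": month,
                "t_mean": self.t_mean,
                "precip": self.precip,
                "sw_rad": self.sw_rad,
                "days": self.days,
                "ba_frac": self.ba_frac,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ForcingSeries":
        required = {"year", "t_mean", "precip", "sw_rad", "days", "ba_frac"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"forcing table missing columns: {sorted(missing)}")
        return cls(
            t_mean=df["t_mean"].to_numpy(float),
            precip=df["precip"].to_numpy(float),
            sw_rad=df["sw_rad"].to_numpy(float),
            days=df["days"].to_numpy(float),
            ba_frac=df["ba_frac"].to_numpy(float),
            start_year=int(df["year"].iloc[0]),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForcingSeries":
        return cls.from_dataframe(pd.read_csv(path))

    def to_netcdf(self, path: str | Path) -> None:
        import xarray as xr

        time = pd.period_range(f"{self.start_year}-01", periods=self.n_months,
                               freq="M").to_timestamp()
        ds = xr.Dataset(
            {
                "t_mean": ("time", self.t_mean, {"units": "degC"}),
                "precip": ("time", self.precip, {"units": "mm month-1"}),
                "sw_rad": ("time", self.sw_rad, {"units": "MJ m-2 d-1"}),
                "days": ("time", self.days, {"units": "d"}),
                "ba_frac": ("time", self.ba_frac, {"units": "1"}),
            },
            coords={"time": time},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "ForcingSeries":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            start_year = int(pd.Timestamp(ds["time"].values[0]).year)
            return cls(
                t_mean=ds["t_mean"].values.astype(float),
                precip=ds["precip"].values.astype(float),
                sw_rad=ds["sw_rad"].values.astype(float),
                days=ds["days"].values.astype(float),
                ba_frac=ds["ba_frac"].values.astype(float),
                start_year=start_year,
            )


@dataclass(frozen=True)
class FluxRecord:
    """All component fluxes of one monthly step (gC m^-2 month^-1).

    Sign convention: ``nee = ter - gpp`` and ``nbe = nee + fire_emission``;
    positive values are land-to-atmosphere.
    """

    gpp: float
    ra: float
    rh_litter: float
    rh_som: float
    fire_emission: float
    mort_labile: float
    mort_foliar: float
    mort_root: float
    mort_wood: float

    @property
    def npp(self) -> float:
        return self.gpp - self.ra

    @property
    def ter(self) -> float:
        return self.ra + self.rh_litter + self.rh_som

    @property
    def nee(self) -> float:
        return self.ter - self.gpp

    @property
    def nbe(self) -> float:
        return self.nee + self.fire_emission

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FLUX_NAMES], dtype=float)


@dataclass
class Trajectory:
    """Month-end pool states and monthly fluxes of one simulation."""

    pools: np.ndarray  # (T, 7) month-end states, POOL_NAMES column order
    fluxes: np.ndarray  # (T, 9) FLUX_NAMES column order
    start_year: int = 2001
    init: PoolState | None = None  # state before the first step

    def __post_init__(self) -> None:
        self.pools = np.asarray(self.pools, dtype=float)
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        if self.pools.ndim != 2 or self.pools.shape[1] != len(POOL_NAMES):
            raise ValueError("pools must have shape (T, 7)")
        if self.fluxes.shape != (self.pools.shape[0], len(FLUX_NAMES)):
            raise ValueError("fluxes must have shape (T, 9)")

    @property
    def n_months(self) -> int:
        return self.pools.shape[0]

    def pool(self, name: str) -> np.ndarray:
        return self.pools[:, POOL_NAMES.index(name)]

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_NAMES.index(name)]

    @property
    def gpp(self) -> np.ndarray:
        return self.flux("gpp")

    @property
    def ra(self) -> np.ndarray:
        return self.flux("ra")

    @property
    def rh(self) -> np.ndarray:
        return self.flux("rh_litter") + self.flux("rh_som")

    @property
    def fire_emission(self) -> np.ndarray:
        return self.flux("fire_emission")

    @property
    def ter(self) -> np.ndarray:
        return self.ra + self.rh

    @property
    def nee(self) -> np.ndarray:
        return self.ter - self.gpp

    @property
    def nbe(self) -> np.ndarray:
        return self.nee + self.fire_emission

    @property
    def total_carbon(self) -> np.ndarray:
        return self.pools[:, :6].sum(axis=1)

    def state(self, i: int = -1) -> PoolState:
        return PoolState.from_array(self.pools[i])

    def to_dataframe(self) -> pd.DataFrame:
        years = self.start_year + np.arange(self.n_months) // 12
        month = np.arange(self.n_months) % 12 + 1
        df = pd.DataFrame({"year": years, "month": month})
        for j, name in enumerate(POOL_NAMES):
            df[name] = self.pools[:, j]
        for j, name in enumerate(FLUX_NAMES):
            df[name] = self.fluxes[:, j]
        df["ter"] = self.ter
        df["nee"] = self.nee
        df["nbe"] = self.nbe
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_netcdf(self, path: str | Path) -> None:
        import xarray as xr

        time = pd.period_range(f"{self.start_year}-01", periods=self.n_months,
                               freq="M").to_timestamp()
        data = {}
        for j, name in enumerate(POOL_NAMES):
            unit = "mm" if name == "water" else "gC m-2"
            data[name] = ("time", self.pools[:, j], {"units": unit})
        for j, name in enumerate(FLUX_NAMES):
            data[name] = ("time", self.fluxes[:, j], {"units": "gC m-2 month-1"})
        xr.Dataset(data, coords={"time": time}).to_netcdf(path, engine="scipy")
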
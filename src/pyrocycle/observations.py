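"""Burned-area statistics and top-down emission conversions.

Gridded monthly burned area (absolute Mha or cell fraction) is aggregated
to coarser grids, stratified by land-cover class to quantify per-class
decadal changes, and summarized as percent-per-year trends and period
means. Fire CO emissions from an atmospheric inversion are converted to
total fire carbon with biome-specific emission-factor ratios, with
relative uncertainties combined in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GriddedBA",
    "LandCoverMap",
    "EmissionSeries",
    "cell_areas_m2",
    "aggregate_ba",
    "ba_change_by_class",
    "percent_trend",
    "period_change",
    "co_to_carbon",
]

_EARTH_RADIUS_M = 6.371e6


def cell_areas_m2(lat: np.ndarray, dlat: float, dlon: float) -> np.ndarray:
    """Areas (m^2) of cell-centered latitude bands of size dlat x dlon degrees."""
    lat = np.asarray(lat, dtype=float)
    lo = np.radians(lat - dlat / 2.0)
    hi = np.radians(lat + dlat / 2.0)
    band = np.abs(np.sin(hi) - np.sin(lo))
    return _EARTH_RADIUS_M**2 * np.radians(dlon) * band


@dataclass
class GriddedBA:
    """Monthly burned area on a regular lat-lon grid.

    ``data`` has shape (time, lat, lon); values are absolute Mha per month
    when ``is_fraction`` is False, else the burned fraction of each cell.
    """

    data: np.ndarray
    lat: np.ndarray  # cell-center latitudes, ascending
    lon: np.ndarray  # cell-center longitudes
    start_year: int = 2001
    is_fraction: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (self.lat.size, self.lon.size):
            raise ValueError("data must have shape (time, lat, lon)")
        if np.any(self.data < 0):
            raise ValueError("burned area must be >= 0")
        if self.is_fraction and np.any(self.data > 1):
            raise ValueError("burned fractions must be <= 1")

    @property
    def n_months(self) -> int:
        return self.data.shape[0]

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else 180.0

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 360.0

    def cell_areas(self) -> np.ndarray:
        """(lat, lon) cell areas in m^2 from the cos-latitude band formula."""
        band = cell_areas_m2(self.lat, self.dlat, self.dlon)
        return np.repeat(band[:, None], self.lon.size, axis=1)

    def to_mha(self) -> "GriddedBA":
        """Absolute burned area in Mha (1 Mha = 1e10 m^2)."""
        if not self.is_fraction:
            return self
        data = self.data * self.cell_areas()[None, :, :] / 1e10
        return GriddedBA(data=data, lat=self.lat, lon=self.lon,
                         start_year=self.start_year, is_fraction=False)

    def annual_total(self) -> pd.Series:
        """Global annual burned area (Mha yr^-1), indexed by year."""
        mha = self.to_mha()
        n_years = mha.n_months // 12
        if n_years * 12 != mha.n_months:
            raise ValueError("whole years required")
        yearly = mha.data[: n_years * 12].reshape(n_years, 12, *mha.data.shape[1:])
        totals = yearly.sum(axis=(1, 2, 3))
        years = mha.start_year + np.arange(n_years)
        return pd.Series(totals, index=years, name="ba_mha")

    def to_netcdf(self, path: str | Path) -> None:
        import xarray as xr

        time = pd.period_range(f"{self.start_year}-01", periods=self.n_months,
                               freq="M").to_timestamp()
        units = "1" if self.is_fraction else "Mha"
        xr.Dataset(
            {"burned_area": (("time", "lat", "lon"), self.data, {"units": units})},
            coords={"time": time, "lat": self.lat, "lon": self.lon},
            attrs={"is_fraction": int(self.is_fraction)},
        ).to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "GriddedBA":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(
                data=ds["burned_area"].values.astype(float),
                lat=ds["lat"].values.astype(float),
                lon=ds["lon"].values.astype(float),
                start_year=int(pd.Timestamp(ds["time"].values[0]).year),
                is_fraction=bool(ds.attrs.get("is_fraction", 0)),
            )


@dataclass
class LandCoverMap:
    """Integer land-cover class per cell with a label table."""

    classes: np.ndarray  # (lat, lon) int labels; negative = masked
    labels: dict[int, str]

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        present = set(np.unique(self.classes[self.classes >= 0]).tolist())
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"unlabelled land-cover classes: {sorted(missing)}")


@dataclass
class EmissionSeries:
    """Annual emissions per region with 1-sigma uncertainties."""

    years: np.ndarray
    values: np.ndarray  # TgC yr^-1 (or TgCO yr^-1 before conversion)
    sd: np.ndarray
    region: str = "global"
    species: str = "C"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.years.shape == self.values.shape == self.sd.shape):
            raise ValueError("years, values and sd must have matching shapes")
        if np.any(self.sd <= 0):
            raise ValueError("uncertainties must be > 0")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "region": self.region, "species": self.species,
            "year": self.years, "value": self.values, "sd": self.sd,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionSeries":
        df = pd.read_csv(path)
        return cls(years=df["year"].to_numpy(int),
                   values=df["value"].to_numpy(float),
                   sd=df["sd"].to_numpy(float),
                   region=str(df["region"].iloc[0]),
                   species=str(df.get("species", pd.Series(["C"])).iloc[0]))


def aggregate_ba(fine: GriddedBA, factor_lat: int, factor_lon: int) -> GriddedBA:
    """Aggregate to a coarser grid by integer block factors.

    Absolute burned areas sum over each block; burned fractions are
    area-weighted means, so the implied absolute totals are conserved.
    """
    if factor_lat < 1 or factor_lon < 1:
        raise ValueError("aggregation factors must be >= 1")
    nlat, nlon = fine.lat.size, fine.lon.size
    if nlat % factor_lat or nlon % factor_lon:
        raise ValueError("coarse cells must tile an integer number of fine cells")
    t = fine.n_months
    blocks = fine.data.reshape(t, nlat // factor_lat, factor_lat,
                               nlon // factor_lon, factor_lon)
    lat_c = fine.lat.reshape(-1, factor_lat).mean(axis=1)
    lon_c = fine.lon.reshape(-1, factor_lon).mean(axis=1)
    if fine.is_fraction:
        w = fine.cell_areas().reshape(nlat // factor_lat, factor_lat,
                                      nlon // factor_lon, factor_lon)
        data = (blocks * w[None]).sum(axis=(2, 4)) / w.sum(axis=(1, 3))[None]
    else:
        data = blocks.sum(axis=(2, 4))
    return GriddedBA(data=data, lat=lat_c, lon=lon_c,
                     start_year=fine.start_year, is_fraction=fine.is_fraction)


def _annual_by_class(ba: GriddedBA, lc: LandCoverMap) -> pd.DataFrame:
    mha = ba.to_mha()
    n_years = mha.n_months // 12
    if n_years * 12 != mha.n_months:
        raise ValueError("whole years required")
    if lc.classes.shape != (ba.lat.size, ba.lon.size):
        raise ValueError("land-cover map must match the burned-area grid")
    yearly = mha.data[: n_years * 12].reshape(n_years, 12, ba.lat.size,
                                              ba.lon.size).sum(axis=1)
    out = {}
    for cls_id, label in lc.labels.items():
        mask = lc.classes == cls_id
        out[label] = yearly[:, mask].sum(axis=1)
    years = mha.start_year + np.arange(n_years)
    return pd.DataFrame(out, index=years)


def ba_change_by_class(
    ba: GriddedBA,
    lc: LandCoverMap,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
) -> pd.DataFrame:
    """Per-class burned-area change between two equal-length year periods.

    Returns, per class: mean annual BA in each period (Mha yr^-1), the
    change (period B minus A), the change as percent of the period-A mean,
    and the uncertainty of the change taken as the standard deviation of
    the paired year-to-year differences divided by sqrt(n).
    """
    ann = _annual_by_class(ba, lc)
    ya = np.arange(period_a[0], period_a[1] + 1)
    yb = np.arange(period_b[0], period_b[1] + 1)
    if ya.size != yb.size:
        raise ValueError("periods must have equal length (paired years)")
    if not (set(ya) <= set(ann.index) and set(yb) <= set(ann.index)):
        raise ValueError("periods outside the burned-area record")
    rows = []
    for label in ann.columns:
        a = ann.loc[ya, label].to_numpy()
        b = ann.loc[yb, label].to_numpy()
        diff = b - a
        delta = diff.mean()
        pct = 100.0 * delta / a.mean() if a.mean() != 0 else np.nan
        unc = diff.std(ddof=1) / np.sqrt(diff.size) if diff.size > 1 else 0.0
        rows.append((label, a.mean(), b.mean(), delta, pct, unc))
    return pd.DataFrame(rows, columns=["class", "mean_a", "mean_b",
                                       "delta_mha_yr", "delta_pct", "uncertainty"])


def percent_trend(annual: "pd.Series | np.ndarray") -> tuple[float, float]:
    """Linear trend of an annual series in percent per year.

    The OLS slope (units yr^-1) is divided by the period-mean value and
    multiplied by 100, with a two-sided p-value from the slope t statistic.
    A constant series returns (0.0, 1.0) by convention. Scale-invariant:
    rescaling the series leaves the percent trend unchanged.
    """
    y = np.asarray(annual, dtype=float)
    if y.size < 3:
        raise ValueError("need at least three years")
    t = np.arange(y.size, dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0, 1.0
    res = stats.linregress(t, y)
    mean = y.mean()
    if mean == 0:
        raise ValueError("period-mean is zero; percent trend undefined")
    return float(100.0 * res.slope / mean), float(res.pvalue)


def period_change(
    annual: "pd.Series",
    period_a: tuple[int, int],
    period_b: tuple[int, int],
) -> dict[str, float]:
    """Period means, across-year standard deviations, and their difference."""
    ya = annual.loc[period_a[0]: period_a[1]]
    yb = annual.loc[period_b[0]: period_b[1]]
    if ya.empty or yb.empty:
        raise ValueError("empty period")
    return {
        "mean_a": float(ya.mean()),
        "sd_a": float(ya.std(ddof=1)) if ya.size > 1 else 0.0,
        "mean_b": float(yb.mean()),
        "sd_b": float(yb.std(ddof=1)) if yb.size > 1 else 0.0,
        "delta": float(yb.mean() - ya.mean()),
    }


def co_to_carbon(
    co: EmissionSeries,
    ratio: float,
    ratio_sd: float = 0.0,
) -> EmissionSeries:
    """Convert fire CO emissions to total fire carbon: C = CO * rho.

    ``ratio`` is the biome-specific emission-factor ratio rho = EF_C / EF_CO
    with 1-sigma uncertainty ``ratio_sd``. Relative uncertainties combine in
    quadrature: (s_C/C)^2 = (s_CO/CO)^2 + (s_rho/rho)^2. Years with zero CO
    fall back to the absolute propagation s_C = rho * s_CO.
    """
    if ratio <= 0:
        raise ValueError("emission-factor ratio must be > 0")
    if ratio_sd < 0:
        raise ValueError("ratio_sd must be >= 0")
    c = co.values * ratio
    rel_rho = ratio_sd / ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_co = np.where(co.values != 0, co.sd / co.values, 0.0)
    sd = np.where(
        co.values != 0,
        np.abs(c) * np.sqrt(rel_co**2 + rel_rho**2),
        ratio * co.sd,
    )
    return EmissionSeries(years=co.years, values=c, sd=sd,
                          region=co.region, species="C")


def sum_regions(series: list[EmissionSeries], region: str = "total") -> EmissionSeries:
    """Sum biome-stratified emission series with independent-error quadrature."""
    if not series:
        raise ValueError("need at least one series")
    years = series[0].years
    if any(not np.array_equal(s.years, years) for s in series):
        raise ValueError("all series must share the same years")
    values = np.sum([s.values for s in series], axis=0)
    sd = np.sqrt(np.sum([s.sd**2 for s in series], axis=0))
    return EmissionSeries(years=years, values=values, sd=sd, region=region,
                          species=series[0].species)
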
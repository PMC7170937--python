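"""Counterfactual burned-area experiments and legacy-effect diagnostics.

The central construct is a paired run: for each posterior draw the model is
run once with the observed burned area and once with a control burned area
(the baseline-period monthly climatology inside an experiment window), with
identical meteorology, parameters and initial state. The per-draw difference
series (observed minus control) isolate the direct combustion effect (dFIRE)
and the indirect carbon-cycle effect (dGPP, dTER, dNEE) of the burned-area
change; after the window both scenarios share the same burned area, so the
differences that remain are legacy effects of the pool-state divergence.

Sign convention: positive flux differences are land-to-atmosphere, so a
burned-area decline yields dFIRE < 0 and dNEE < 0 (an enhanced sink).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .carbon_model import simulate
from .fusion import Posterior
from .types import DEFAULT_CONFIG, ForcingSeries, ModelConfig

__all__ = [
    "ScenarioDelta",
    "build_fixed_ba",
    "extend_forcing",
    "run_delta",
    "legacy_window_means",
    "nbe_neutrality_time",
]

DELTA_VARS = ("fire", "gpp", "ter", "nee", "nbe")


@dataclass
class ScenarioDelta:
    """Paired-run difference series for an ensemble of parameter draws.

    ``monthly[var]`` has shape (n_draws, n_months) in gC m^-2 month^-1;
    annual aggregates and ensemble quartiles are derived on demand.
    ``window`` is the (first, last) calendar year of the perturbation.
    """

    monthly: dict[str, np.ndarray]
    start_year: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.monthly.values()}
        if len(shapes) != 1:
            raise ValueError("all delta variables must share one (draws, months) shape")
        missing = set(DELTA_VARS) - set(self.monthly)
        if missing:
            raise ValueError(f"missing delta variables: {sorted(missing)}")

    @property
    def n_draws(self) -> int:
        return self.monthly["fire"].shape[0]

    @property
    def n_months(self) -> int:
        return self.monthly["fire"].shape[1]

    @property
    def n_years(self) -> int:
        return self.n_months // 12

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    def annual(self, var: str) -> np.ndarray:
        """Per-draw annual sums, shape (n_draws, n_years), gC m^-2 yr^-1."""
        a = self.monthly[var]
        return a[:, : self.n_years * 12].reshape(self.n_draws, self.n_years, 12).sum(axis=2)

    def annual_quantiles(self, var: str) -> pd.DataFrame:
        q = np.quantile(self.annual(var), (0.25, 0.5, 0.75), axis=0)
        return pd.DataFrame({"year": self.years, "q1": q[0], "median": q[1], "q3": q[2]})

    def monthly_quantiles(self, var: str) -> np.ndarray:
        """(3, n_months): first quartile, median, third quartile."""
        return np.quantile(self.monthly[var], (0.25, 0.5, 0.75), axis=0)

    def window_mean(self, var: str, how: str = "median") -> float:
        """Mean annual delta over the perturbation window (gC m^-2 yr^-1)."""
        sl = self._year_slice(*self.window)
        ann = self.annual(var)[:, sl]
        per_draw = ann.mean(axis=1)
        if how == "median":
            return float(np.median(per_draw))
        if how == "mean":
            return float(per_draw.mean())
        raise ValueError("how must be 'median' or 'mean'")

    def _year_slice(self, y0: int, y1: int) -> slice:
        i0, i1 = y0 - self.start_year, y1 - self.start_year + 1
        if i0 < 0 or i1 > self.n_years or i0 >= i1:
            raise ValueError(f"years {y0}-{y1} outside the delta span")
        return slice(i0, i1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy annual quantiles: variable, year, quantile, value."""
        rows = []
        for var in DELTA_VARS:
            q = self.annual_quantiles(var)
            for label in ("q1", "median", "q3"):
                for y, v in zip(q["year"], q[label]):
                    rows.append((var, int(y), label, float(v)))
        return pd.DataFrame(rows, columns=["variable", "year", "quantile", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_fixed_ba(
    forcing: ForcingSeries,
    baseline_years: tuple[int, int],
    window_years: tuple[int, int],
) -> ForcingSeries:
    """Control forcing: window burned area replaced by baseline climatology.

    Every month inside ``window_years`` receives the mean burned fraction of
    the same calendar month over ``baseline_years``; meteorology and months
    outside the window are untouched.
    """
    b0, b1 = baseline_years
    w0, w1 = window_years
    base = forcing.month_slice(b0, b1)
    win = forcing.month_slice(w0, w1)
    if max(b0, w0) <= min(b1, w1):
        raise ValueError("baseline and window years must not overlap")
    clim = forcing.ba_frac[base].reshape(-1, 12).mean(axis=0)
    out = forcing.copy()
    n_win_years = w1 - w0 + 1
    out.ba_frac[win] = np.tile(clim, n_win_years)
    return out


def extend_forcing(
    forcing: ForcingSeries,
    n_years: int,
    recycle_years: tuple[int, int],
) -> ForcingSeries:
    """Append ``n_years`` by cyclically repeating ``recycle_years``.

    Meteorology and burned area are recycled alike, mirroring a run where
    the same forcing is reused beyond the observed record.
    """
    if n_years < 0:
        raise ValueError("n_years must be >= 0")
    if n_years == 0:
        return forcing.copy()
    r = forcing.month_slice(*recycle_years)
    n_rec = (r.stop - r.start) // 12
    year_order = [r.start + (k % n_rec) * 12 for k in range(n_years)]
    idx = np.concatenate([np.arange(s, s + 12) for s in year_order])
    return ForcingSeries(
        t_mean=np.concatenate([forcing.t_mean, forcing.t_mean[idx]]),
        precip=np.concatenate([forcing.precip, forcing.precip[idx]]),
        sw_rad=np.concatenate([forcing.sw_rad, forcing.sw_rad[idx]]),
        days=np.concatenate([forcing.days, forcing.days[idx]]),
        ba_frac=np.concatenate([forcing.ba_frac, forcing.ba_frac[idx]]),
        start_year=forcing.start_year,
    )


def run_delta(
    posterior: Posterior,
    forcing_obs: ForcingSeries,
    forcing_fixed: ForcingSeries,
    window_years: tuple[int, int],
    n_draws: int = 100,
    seed: int = 0,
    init_water: float = 100.0,
    config: ModelConfig = DEFAULT_CONFIG,
) -> ScenarioDelta:
    """Paired observed-minus-control runs over an ensemble of draws.

    Each draw uses one parameter vector and initial state for both runs
    (all else equal), so the difference series carry no parameter noise.
    Both forcings must already have the same (possibly extended) length.
    """
    if forcing_obs.n_months != forcing_fixed.n_months:
        raise ValueError("observed and control forcings must have equal length")
    if not np.array_equal(forcing_obs.t_mean, forcing_fixed.t_mean):
        raise ValueError("scenario forcings must share identical meteorology")
    if posterior.n_draws == 0:
        raise ValueError("posterior contains no draws")
    if n_draws > posterior.n_draws:
        raise ValueError("n_draws exceeds the retained posterior draws")
    rng = np.random.default_rng(seed)
    rows = rng.choice(posterior.n_draws, size=n_draws, replace=False)

    T = forcing_obs.n_months
    monthly = {v: np.empty((n_draws, T)) for v in DELTA_VARS}
    for j, i in enumerate(rows):
        params, init = posterior.draw(int(i))
        if init is None:
            raise ValueError("posterior lacks initial pool columns")
        init = init.replace(water=init_water)
        t_obs = simulate(params, init, forcing_obs, config)
        t_fix = simulate(params, init, forcing_fixed, config)
        monthly["fire"][j] = t_obs.fire_emission - t_fix.fire_emission
        monthly["gpp"][j] = t_obs.gpp - t_fix.gpp
        monthly["ter"][j] = t_obs.ter - t_fix.ter
        monthly["nee"][j] = t_obs.nee - t_fix.nee
        monthly["nbe"][j] = t_obs.nbe - t_fix.nbe
    return ScenarioDelta(monthly=monthly, start_year=forcing_obs.start_year,
                         window=window_years)


def legacy_window_means(
    delta: ScenarioDelta,
    windows: list[tuple[int, int]],
) -> pd.DataFrame:
    """Mean annual delta fluxes over year windows, per ensemble quantile.

    Windows are (first, last) calendar-year pairs, typically offsets after
    the perturbation window (e.g. years 1-5, 6-10 and 11-20 of the legacy
    period). Returns one row per (window, variable) with q1/median/q3 and
    the ensemble-mean column.
    """
    rows = []
    for (y0, y1) in windows:
        sl = delta._year_slice(y0, y1)
        if sl.start >= sl.stop:
            raise ValueError(f"empty window {y0}-{y1}")
        for var in DELTA_VARS:
            per_draw = delta.annual(var)[:, sl].mean(axis=1)
            q1, med, q3 = np.quantile(per_draw, (0.25, 0.5, 0.75))
            rows.append((f"{y0}-{y1}", var, float(q1), float(med), float(q3),
                         float(per_draw.mean())))
    return pd.DataFrame(rows, columns=["window", "variable", "q1", "median",
                                       "q3", "mean"])


def nbe_neutrality_time(
    delta: "ScenarioDelta | np.ndarray",
    tolerance_frac: float = 0.05,
) -> int | None:
    """Years from the perturbation start until net biome exchange is neutral.

    The input is either a ScenarioDelta (the annual ensemble-median dNBE
    from the first perturbation year onward is used) or a plain annual
    |dNBE| series whose element k corresponds to k years after the
    perturbation start. Neutrality is the first year at or after the peak
    of |dNBE| where |dNBE| <= tolerance_frac * peak; the returned value is
    that year offset k (the peak year itself under a 100% tolerance). An
    all-zero series returns 1 (neutral within the first year) by
    convention; ``None`` flags a horizon too short for the criterion.
    """
    if not 0 < tolerance_frac <= 1:
        raise ValueError("tolerance_frac must lie in (0, 1]")
    if isinstance(delta, ScenarioDelta):
        med = np.quantile(delta.annual("nbe"), 0.5, axis=0)
        start = delta.window[0] - delta.start_year
        series = np.abs(med[start:])
    else:
        series = np.abs(np.asarray(delta, dtype=float))
    if series.size == 0:
        raise ValueError("empty series")
    peak = series.max()
    if peak == 0.0:
        return 1
    k_peak = int(series.argmax())
    below = np.nonzero(series[k_peak:] <= tolerance_frac * peak)[0]
    if below.size == 0:
        return None
    return int(k_peak + below[0])
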
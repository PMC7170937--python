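"""Airborne-fraction bookkeeping and the fire-decline budget adjustment.

The global carbon budget per year reads E_FF + E_LUC = G_ATM + S_OCEAN +
S_LAND up to a residual imbalance. Three airborne-fraction views are
computed: the observed one (atmospheric growth over anthropogenic
emissions), the process-explained one (unity minus the process-estimated
sinks over emissions), and the fire-adjusted one, where the counterfactual
fire-decline fluxes dFIRE and dNEE (observed minus fixed burned area;
negative = extra land sink) are added to the process sinks:

    AF_obs      = G_ATM / (E_FF + E_LUC)
    AF_process  = 1 - (S_OCEAN + S_LAND) / (E_FF + E_LUC)
    AF_adjusted = 1 - (S_OCEAN + S_LAND - dFIRE - dNEE) / (E_FF + E_LUC)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BudgetTable",
    "af_observed",
    "af_process",
    "af_adjusted",
    "af_metrics",
]


@dataclass
class BudgetTable:
    """Yearly global carbon-budget terms, all in PgC yr^-1."""

    years: np.ndarray
    e_ff: np.ndarray  # fossil fuel and industry emissions
    e_luc: np.ndarray  # land-use change emissions
    g_atm: np.ndarray  # atmospheric growth
    s_ocean: np.ndarray  # ocean sink
    s_land: np.ndarray  # land sink (process models)

    def __post_init__(self) -> None:
        cols = ("years", "e_ff", "e_luc", "g_atm", "s_ocean", "s_land")
        n = None
        for c in cols:
            a = np.asarray(getattr(self, c), dtype=float if c != "years" else int)
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all budget columns must have equal length")
            setattr(self, c, a)
        if np.any(self.e_ff + self.e_luc <= 0):
            raise ValueError("total anthropogenic emissions must be > 0 each year")

    @property
    def emissions(self) -> np.ndarray:
        return self.e_ff + self.e_luc

    @property
    def imbalance(self) -> np.ndarray:
        """Yearly budget residual E_FF + E_LUC - G_ATM - S_OCEAN - S_LAND."""
        return self.emissions - self.g_atm - self.s_ocean - self.s_land

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "e_ff": self.e_ff, "e_luc": self.e_luc,
            "g_atm": self.g_atm, "s_ocean": self.s_ocean, "s_land": self.s_land,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BudgetTable":
        df = pd.read_csv(path)
        return cls(years=df["year"].to_numpy(int),
                   e_ff=df["e_ff"].to_numpy(float),
                   e_luc=df["e_luc"].to_numpy(float),
                   g_atm=df["g_atm"].to_numpy(float),
                   s_ocean=df["s_ocean"].to_numpy(float),
                   s_land=df["s_land"].to_numpy(float))


def af_observed(budget: BudgetTable) -> np.ndarray:
    """Observed airborne fraction G_ATM / (E_FF + E_LUC), per year."""
    return budget.g_atm / budget.emissions


def af_process(budget: BudgetTable) -> np.ndarray:
    """Process-explained airborne fraction 1 - (S_OCEAN + S_LAND)/(E_FF + E_LUC)."""
    return 1.0 - (budget.s_ocean + budget.s_land) / budget.emissions


def af_adjusted(
    budget: BudgetTable,
    d_fire: np.ndarray,
    d_nee: np.ndarray,
    anchor_years: tuple[int, int] | None = None,
) -> np.ndarray:
    """Fire-decline-adjusted airborne fraction.

    ``d_fire`` and ``d_nee`` are yearly observed-minus-control fluxes in
    PgC yr^-1 with the land-to-atmosphere sign convention (negative =
    additional sink); they are subtracted from the process sinks:
    AF = 1 - (S_OCEAN + S_LAND - dFIRE - dNEE) / (E_FF + E_LUC).

    With ``anchor_years`` the delta series are first re-expressed relative
    to their mean over those years (optional mean-removal anchoring).
    """
    d_fire = np.asarray(d_fire, dtype=float)
    d_nee = np.asarray(d_nee, dtype=float)
    n = budget.years.size
    if d_fire.shape != (n,) or d_nee.shape != (n,):
        raise ValueError("delta series must align with the budget years")
    if anchor_years is not None:
        sel = (budget.years >= anchor_years[0]) & (budget.years <= anchor_years[1])
        if not sel.any():
            raise ValueError("anchor years outside the budget span")
        d_fire = d_fire - d_fire[sel].mean()
        d_nee = d_nee - d_nee[sel].mean()
    sinks = budget.s_ocean + budget.s_land - d_fire - d_nee
    return 1.0 - sinks / budget.emissions


def af_metrics(af_obs: np.ndarray, af_model: np.ndarray) -> dict[str, float]:
    """Mean bias and RMS of model-minus-observed airborne-fraction residuals."""
    af_obs = np.asarray(af_obs, dtype=float)
    af_model = np.asarray(af_model, dtype=float)
    if af_obs.shape != af_model.shape:
        raise ValueError("series must have equal length")
    r = af_model - af_obs
    return {"bias": float(r.mean()), "rms": float(np.sqrt(np.mean(r * r)))}


def af_improvement(
    af_obs: np.ndarray,
    af_before: np.ndarray,
    af_after: np.ndarray,
) -> dict[str, float]:
    """Percent reductions in |bias| and RMS from one model series to another."""
    m0 = af_metrics(af_obs, af_before)
    m1 = af_metrics(af_obs, af_after)
    out = dict(
        bias_before=m0["bias"], bias_after=m1["bias"],
        rms_before=m0["rms"], rms_after=m1["rms"],
    )
    out["bias_reduction_pct"] = (
        100.0 * (1.0 - abs(m1["bias"]) / abs(m0["bias"])) if m0["bias"] != 0 else 0.0
    )
    out["rms_reduction_pct"] = (
        100.0 * (1.0 - m1["rms"] / m0["rms"]) if m0["rms"] != 0 else 0.0
    )
    return out
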
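"""Bayesian model-data fusion: priors, multi-stream likelihood, MH sampler.

Parameters and initial pool states are estimated per cell by random-walk
Metropolis-Hastings in a transformed space (log for positive rates, logit
for bounded fractions), against independent Gaussian likelihood terms for
monthly LAI, z-scored monthly GPP anomalies (a variability-only constraint,
as provided by solar-induced fluorescence), a time-mean aboveground-biomass
stock (wood + foliar), a soil-organic-carbon stock, and annual fire carbon
emissions. Any stream may be absent; its term is simply skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .carbon_model import simulate
from .types import (
    DEFAULT_CONFIG,
    ForcingSeries,
    ModelConfig,
    PARAM_NAMES,
    ParameterSet,
    PoolState,
    Trajectory,
)

__all__ = [
    "ObsStream",
    "ObservationSet",
    "PriorSpec",
    "Posterior",
    "default_priors",
    "log_likelihood",
    "log_prior",
    "random_walk_metropolis",
    "mh_sample",
    "posterior_predict",
    "convergence_diag",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: initial carbon pools sampled alongside the parameters
INIT_POOL_NAMES = tuple(f"init_{p}" for p in
                        ("labile", "foliar", "fine_root", "wood", "litter", "som"))


@dataclass
class ObsStream:
    """One observation stream: values with per-point 1-sigma uncertainties.

    ``times`` are month indices into the trajectory for monthly streams and
    year indices for annual streams; scalar constraints use a single entry.
    """

    values: np.ndarray
    sd: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if self.sd.size == 1 and self.values.size > 1:
            self.sd = np.full(self.values.size, float(self.sd[0]))
        if self.sd.shape != self.values.shape:
            raise ValueError("values and sd must have matching shapes")
        # zero sd is allowed in a noise-free generated set; the likelihood
        # itself rejects non-positive uncertainties
        if np.any(~np.isfinite(self.sd)) or np.any(self.sd < 0):
            raise ValueError("all observation uncertainties must be finite and >= 0")
        if self.times is not None:
            self.times = np.atleast_1d(np.asarray(self.times, dtype=int))
            if self.times.shape != self.values.shape:
                raise ValueError("times must match values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ObservationSet:
    """The data side of the likelihood; any stream may be ``None``."""

    lai: ObsStream | None = None  # monthly LAI (m2 m-2)
    gpp_anom: ObsStream | None = None  # monthly GPP z-scores (unitless)
    biomass: ObsStream | None = None  # one mean aboveground stock (gC m-2)
    som: ObsStream | None = None  # one SOC stock (gC m-2)
    fire_annual: ObsStream | None = None  # annual fire emissions (gC m-2 yr-1)

    STREAMS = ("lai", "gpp_anom", "biomass", "som", "fire_annual")

    def streams(self) -> dict[str, ObsStream]:
        return {k: getattr(self, k) for k in self.STREAMS if getattr(self, k) is not None}

    @property
    def n_points(self) -> int:
        return sum(s.n for s in self.streams().values())

    # -- I/O (long format: stream, time, value, sd) ------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, s in self.streams().items():
            times = s.times if s.times is not None else np.arange(s.n)
            for t, v, sd in zip(times, s.values, s.sd):
                rows.append((name, int(t), float(v), float(sd)))
        return pd.DataFrame(rows, columns=["stream", "time", "value", "sd"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservationSet":
        kwargs = {}
        for name, g in df.groupby("stream"):
            g = g.sort_values("time")
            kwargs[str(name)] = ObsStream(
                values=g["value"].to_numpy(float),
                sd=g["sd"].to_numpy(float),
                times=g["time"].to_numpy(int),
            )
        unknown = set(kwargs) - set(cls.STREAMS)
        if unknown:
            raise ValueError(f"unknown observation streams: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        return cls.from_dataframe(pd.read_csv(path))


def _gauss(model: np.ndarray, s: ObsStream) -> float:
    if np.any(s.sd <= 0):
        raise ValueError("likelihood requires strictly positive uncertainties")
    r = (model - s.values) / s.sd
    return float(-0.5 * np.sum(r * r) - 0.5 * s.n * _LOG2PI - np.sum(np.log(s.sd)))


def modelled_streams(trajectory: Trajectory, lcma: float) -> dict[str, np.ndarray]:
    """Model-space counterparts of the observation streams."""
    gpp = trajectory.gpp
    sd = gpp.std()
    z = (gpp - gpp.mean()) / sd if sd > 0 else np.zeros_like(gpp)
    n = trajectory.n_months
    out = {
        "lai": trajectory.pool("foliar") / lcma,
        "gpp_anom": z,
        "biomass": np.array([(trajectory.pool("wood") + trajectory.pool("foliar")).mean()]),
        "som": np.array([trajectory.pool("som").mean()]),
    }
    if n % 12 == 0:
        out["fire_annual"] = trajectory.fire_emission.reshape(-1, 12).sum(axis=1)
    return out


def log_likelihood(trajectory: Trajectory, obs: ObservationSet, lcma: float) -> float:
    """Sum of independent Gaussian log-densities over the present streams.

    ``lcma`` (leaf carbon mass per area) maps the foliar pool to LAI; it is
    the same parameter the sampler estimates, so the mapping stays
    self-consistent within a draw.
    """
    model = modelled_streams(trajectory, lcma)
    total = 0.0
    for name, s in obs.streams().items():
        m = model.get(name)
        if m is None:
            raise ValueError(f"stream {name!r} needs whole simulation years")
        if s.times is not None and m.size > s.n:
            m = m[s.times]
        elif m.size != s.n:
            raise ValueError(f"stream {name!r}: {s.n} observations vs {m.size} modelled")
        total += _gauss(m, s)
    return total


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorEntry:
    name: str
    family: str  # "loguniform" | "uniform" | "truncnorm"
    lo: float
    hi: float
    mu: float | None = None  # truncnorm only
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("loguniform", "uniform", "truncnorm"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError(f"{self.name}: bounds must be finite with lo < hi")
        if self.family == "loguniform" and self.lo <= 0:
            raise ValueError(f"{self.name}: loguniform needs lo > 0")
        if self.family == "truncnorm" and (self.mu is None or self.sigma is None
                                           or self.sigma <= 0):
            raise ValueError(f"{self.name}: truncnorm needs mu and sigma > 0")

    @property
    def transform(self) -> str:
        return "log" if self.family == "loguniform" else "logit"

    # natural-space log density (unnormalized only where harmless: all
    # families are properly normalized so prior-only sampling is exact)
    def logpdf(self, x: float) -> float:
        if not self.lo <= x <= self.hi:
            return -np.inf
        if self.family == "loguniform":
            return -np.log(x) - np.log(np.log(self.hi / self.lo))
        if self.family == "uniform":
            return -np.log(self.hi - self.lo)
        # truncated normal
        from scipy.stats import truncnorm

        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return float(truncnorm.logpdf(x, a, b, loc=self.mu, scale=self.sigma))

    def to_transformed(self, x: float) -> float:
        if self.transform == "log":
            return float(np.log(x))
        u = (x - self.lo) / (self.hi - self.lo)
        u = min(max(u, 1e-12), 1.0 - 1e-12)
        return float(np.log(u / (1.0 - u)))

    def from_transformed(self, z: float) -> float:
        if self.transform == "log":
            return float(np.exp(z))
        u = 1.0 / (1.0 + np.exp(-z))
        return float(self.lo + (self.hi - self.lo) * u)

    def log_jacobian(self, z: float) -> float:
        """log |dx/dz| of the inverse transform."""
        if self.transform == "log":
            return float(z)
        u = 1.0 / (1.0 + np.exp(-z))
        return float(np.log(self.hi - self.lo) + np.log(u) + np.log1p(-u))

    def midpoint(self) -> float:
        if self.family == "loguniform":
            return float(np.sqrt(self.lo * self.hi))
        if self.family == "truncnorm":
            return float(np.clip(self.mu, self.lo, self.hi))
        return 0.5 * (self.lo + self.hi)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        if self.family == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        from scipy.stats import truncnorm

        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return float(truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma,
                                   random_state=rng))


@dataclass
class PriorSpec:
    """Ordered per-parameter prior specification."""

    entries: list[PriorEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in prior")
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def dim(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> PriorEntry:
        return self.entries[self._index[name]]

    def midpoint(self) -> np.ndarray:
        return np.array([e.midpoint() for e in self.entries])

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([e.sample(rng) for e in self.entries])

    def to_transformed(self, x: np.ndarray) -> np.ndarray:
        return np.array([e.to_transformed(v) for e, v in zip(self.entries, x)])

    def from_transformed(self, z: np.ndarray) -> np.ndarray:
        return np.array([e.from_transformed(v) for e, v in zip(self.entries, z)])

    def log_jacobian(self, z: np.ndarray) -> float:
        return float(sum(e.log_jacobian(v) for e, v in zip(self.entries, z)))


def log_prior(x: np.ndarray, prior: PriorSpec) -> float:
    """Natural-space log prior density; -inf outside bounds.

    The allocation fractions are additionally constrained to sum to <= 1
    whenever all three are part of the vector.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (prior.dim,):
        raise ValueError(f"expected vector of length {prior.dim}, got {x.shape}")
    total = 0.0
    for e, v in zip(prior.entries, x):
        lp = e.logpdf(v)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    idx = prior._index
    if all(k in idx for k in ("alloc_foliar", "alloc_labile", "alloc_root")):
        s = x[idx["alloc_foliar"]] + x[idx["alloc_labile"]] + x[idx["alloc_root"]]
        if s > 1.0:
            return -np.inf
    return total


def default_priors(include_init: bool = True) -> PriorSpec:
    """Broad, weakly informative priors for all model parameters.

    Rates and stocks get log-uniform priors over generous physical ranges;
    fractions get uniform priors on their support.
    """
    lu, un = "loguniform", "uniform"
    entries = [
        PriorEntry("lue", lu, 0.03, 3.0),
        PriorEntry("f_auto", un, 0.3, 0.7),
        PriorEntry("alloc_foliar", un, 0.01, 0.6),
        PriorEntry("alloc_labile", un, 0.01, 0.6),
        PriorEntry("alloc_root", un, 0.01, 0.6),
        PriorEntry("labile_release", lu, 0.01, 1.0),
        PriorEntry("lcma", lu, 20.0, 200.0),
        PriorEntry("turn_foliar", lu, 0.01, 0.5),
        PriorEntry("turn_root", lu, 0.005, 0.3),
        PriorEntry("turn_wood", lu, 2e-4, 0.05),
        PriorEntry("decomp_litter", lu, 0.005, 0.5),
        PriorEntry("decomp_som", lu, 1e-5, 0.01),
        PriorEntry("lit2som", lu, 0.001, 0.3),
        PriorEntry("theta", un, 0.01, 0.1),
        PriorEntry("w_half", lu, 5.0, 200.0),
        PriorEntry("cc_foliar", un, 0.01, 1.0),
        PriorEntry("cc_wood", un, 0.01, 0.6),
        PriorEntry("cc_litter", un, 0.01, 1.0),
        PriorEntry("cc_som", un, 0.001, 0.1),
        PriorEntry("resilience", un, 0.0, 1.0),
    ]
    if include_init:
        entries += [
            PriorEntry("init_labile", lu, 1.0, 500.0),
            PriorEntry("init_foliar", lu, 10.0, 2000.0),
            PriorEntry("init_fine_root", lu, 10.0, 2000.0),
            PriorEntry("init_wood", lu, 50.0, 20000.0),
            PriorEntry("init_litter", lu, 10.0, 5000.0),
            PriorEntry("init_som", lu, 500.0, 50000.0),
        ]
    return PriorSpec(entries)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class Posterior:
    """Retained MCMC draws in natural parameter space."""

    samples: np.ndarray  # (n_retained, dim)
    names: list[str]
    log_post: np.ndarray
    acceptance_rate: float
    seed: int
    n_iter: int = 0
    n_burn: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.names):
            raise ValueError("samples must be (draws, len(names))")

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.column(name), [a, 1.0 - a])
        return float(lo), float(hi)

    def draw(self, i: int) -> tuple[ParameterSet, PoolState]:
        """Materialize draw ``i`` as a parameter set and initial pool state."""
        row = dict(zip(self.names, self.samples[i]))
        params = ParameterSet(**{k: row[k] for k in PARAM_NAMES if k in row})
        pools = {k.removeprefix("init_"): v for k, v in row.items()
                 if k.startswith("init_")}
        init = PoolState(**pools) if pools else None
        return params, init

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.samples, columns=self.names)
        df["log_post"] = self.log_post
        df.to_csv(path, index=False)
        meta = {
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "n_burn": self.n_burn,
            "thin": self.thin,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Posterior":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        names = [c for c in df.columns if c != "log_post"]
        return cls(samples=df[names].to_numpy(float), names=names,
                   log_post=df["log_post"].to_numpy(float), **meta)


def random_walk_metropolis(
    log_target,
    x0: np.ndarray,
    n_iter: int,
    n_burn: int,
    scales: np.ndarray | float = 0.1,
    seed: int = 0,
    thin: int = 1,
    adapt: bool = True,
    target_accept: float = 0.3,
    cov0: np.ndarray | None = None,
    post_burn_boost: float = 1.0,
):
    """Generic random-walk Metropolis with burn-in-only adaptation.

    Proposals are multivariate Gaussian, starting from a diagonal covariance
    built from ``scales`` or from a full ``cov0`` (e.g. a Laplace
    approximation, scaled by 2.38^2/d internally). During burn-in the global
    step size is tuned toward ``target_accept`` and, once enough history
    exists, the proposal covariance is replaced by the scaled empirical
    covariance of the most recent half of the chain history (adaptive
    Metropolis). Everything is frozen at the end of burn-in — optionally
    after inflating the step by ``post_burn_boost``, which trades acceptance
    for longer jumps along posterior ridges — so the retained chain
    satisfies detailed balance.

    Returns ``(samples, log_posts, acceptance_rate)`` where the acceptance
    rate is measured over the post-burn-in phase.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be > 0")
    if not 0 <= n_burn < n_iter:
        raise ValueError("need n_iter > n_burn >= 0")
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    scales = np.broadcast_to(np.asarray(scales, dtype=float), (d,)).copy()
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ValueError("log target is non-finite at the initial point")

    step_fac = 1.0
    _am_started = False
    if cov0 is not None:
        chol = np.linalg.cholesky((2.38**2 / d) * cov0 + 1e-12 * np.eye(d))
    else:
        chol = np.diag(scales)
    history = np.empty((n_burn, d)) if (adapt and n_burn > 0) else None
    n_keep = (n_iter - n_burn + thin - 1) // thin
    samples = np.empty((n_keep, d))
    log_posts = np.empty(n_keep)
    acc_post = 0
    acc_window = 0
    k = 0

    for it in range(n_iter):
        prop = x + step_fac * (chol @ rng.standard_normal(d))
        lp_prop = float(log_target(prop))
        if np.isfinite(lp_prop) and np.log(rng.uniform()) < lp_prop - lp:
            x = prop
            lp = lp_prop
            if it >= n_burn:
                acc_post += 1
            else:
                acc_window += 1
        if it < n_burn:
            if history is not None:
                history[it] = x
            if adapt and (it + 1) % 50 == 0:
                rate = acc_window / 50.0
                acc_window = 0
                step_fac *= np.exp(0.5 * (rate - target_accept))
                step_fac = float(np.clip(step_fac, 1e-3, 1e3))
            if adapt and it + 1 >= max(200, 10 * d) and (it + 1) % 200 == 0:
                # estimate from the most recent half of the burn-in history:
                # the early transient otherwise inflates the covariance
                cov = np.atleast_2d(np.cov(history[(it + 1) // 2: it + 1].T))
                cov += 1e-8 * np.eye(d) * np.trace(cov) / d + 1e-12 * np.eye(d)
                try:
                    new_chol = np.linalg.cholesky((2.38**2 / d) * cov)
                    if not _am_started:
                        # first switch to the empirical-covariance proposal:
                        # restart the scalar tuning from unity once
                        step_fac = 1.0
                        _am_started = True
                    chol = new_chol
                except np.linalg.LinAlgError:
                    pass
            if it == n_burn - 1:
                step_fac *= post_burn_boost
        else:
            if (it - n_burn) % thin == 0:
                samples[k] = x
                log_posts[k] = lp
                k += 1

    accept_rate = acc_post / max(n_iter - n_burn, 1)
    return samples[:k], log_posts[:k], accept_rate


def _laplace_approximation(log_target, z0: np.ndarray, maxiter: int = 400,
                           h: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and inverse-curvature covariance in transformed space.

    L-BFGS-B finds the mode; a central-difference Hessian at the mode,
    negated and inverted (with eigenvalue clipping for safety), provides a
    proposal covariance aligned with the local posterior geometry.
    """
    from scipy.optimize import minimize

    def neg(z):
        v = log_target(z)
        return -v if np.isfinite(v) else 1e10

    res = minimize(neg, z0, method="L-BFGS-B", options={"maxiter": maxiter})
    zmap = res.x
    d = zmap.size
    eye = np.eye(d)
    f0 = log_target(zmap)
    fp = np.array([log_target(zmap + h * eye[i]) for i in range(d)])
    fm = np.array([log_target(zmap - h * eye[i]) for i in range(d)])
    hess = np.zeros((d, d))
    for i in range(d):
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for j in range(i):
            fpp = log_target(zmap + h * (eye[i] + eye[j]))
            hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    if not np.all(np.isfinite(hess)):
        return zmap, np.eye(d) * 0.01
    cov = np.linalg.inv(-hess + 1e-6 * np.eye(d))
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 1e-8, 1e4)
    return zmap, v @ np.diag(w) @ v.T


def _parallel_tempering(
    parts,
    z0: np.ndarray,
    cov0: np.ndarray,
    n_iter: int,
    n_burn_sweeps: int,
    seed: int,
    betas: tuple[float, ...] = (1.0, 0.55, 0.3, 0.15),
    thin: int = 10,
    swap_every: int = 2,
    target_accept: float = 0.3,
):
    """Replica-exchange Metropolis-Hastings on a tempered ladder.

    ``parts(z)`` returns ``(log_prior + log_jacobian, log_likelihood)``;
    replica k targets prior x likelihood^beta_k. Each replica is a
    random-walk chain with its own burn-in-only adaptation (scalar step
    tuning plus empirical-covariance refresh); adjacent replicas attempt a
    state swap every ``swap_every`` sweeps. ``n_iter`` counts total MH
    updates across replicas, so a sweep costs ``len(betas)`` of them.
    Returns the cold chain's retained draws, its log posteriors, the cold
    post-burn-in acceptance rate and the swap acceptance rate.
    """
    k_temps = len(betas)
    d = z0.size
    n_sweeps = n_iter // k_temps
    if not 0 <= n_burn_sweeps < n_sweeps:
        raise ValueError("need n_iter > n_burn >= 0")
    rng = np.random.default_rng(seed)
    x = np.tile(z0, (k_temps, 1))
    p = np.array([parts(x[k]) for k in range(k_temps)])
    base = np.linalg.cholesky((2.38**2 / d) * cov0 + 1e-12 * np.eye(d))
    chol = [base.copy() for _ in range(k_temps)]
    step = np.ones(k_temps)
    am_started = [False] * k_temps
    history = np.zeros((k_temps, n_burn_sweeps, d))
    acc_window = np.zeros(k_temps)
    acc_cold = 0
    swaps_acc = 0
    swaps_try = 0
    n_keep = (n_sweeps - n_burn_sweeps + thin - 1) // thin
    samples = np.empty((n_keep, d))
    log_posts = np.empty(n_keep)
    j = 0
    for it in range(n_sweeps):
        for k in range(k_temps):
            prop = x[k] + step[k] * (chol[k] @ rng.standard_normal(d))
            pp, pl = parts(prop)
            if np.isfinite(pp) and np.log(rng.uniform()) < \
                    (pp + betas[k] * pl) - (p[k, 0] + betas[k] * p[k, 1]):
                x[k] = prop
                p[k] = (pp, pl)
                if it < n_burn_sweeps:
                    acc_window[k] += 1
                elif k == 0:
                    acc_cold += 1
        if it % swap_every == 0 and k_temps > 1:
            a = int(rng.integers(0, k_temps - 1))
            swaps_try += 1
            if np.log(rng.uniform()) < \
                    (betas[a] - betas[a + 1]) * (p[a + 1, 1] - p[a, 1]):
                x[[a, a + 1]] = x[[a + 1, a]]
                p[[a, a + 1]] = p[[a + 1, a]]
                swaps_acc += 1
        if it < n_burn_sweeps:
            history[:, it] = x
            if (it + 1) % 50 == 0:
                for k in range(k_temps):
                    step[k] = float(np.clip(
                        step[k] * np.exp(0.5 * (acc_window[k] / 50 - target_accept)),
                        1e-3, 1e3))
                acc_window[:] = 0
            if (it + 1) >= max(200, 10 * d) and (it + 1) % 200 == 0:
                for k in range(k_temps):
                    cov = np.atleast_2d(np.cov(history[k, (it + 1) // 2: it + 1].T))
                    cov += 1e-10 * np.eye(d)
                    try:
                        new_chol = np.linalg.cholesky((2.38**2 / d) * cov)
                        if not am_started[k]:
                            step[k] = 1.0
                            am_started[k] = True
                        chol[k] = new_chol
                    except np.linalg.LinAlgError:
                        pass
        elif (it - n_burn_sweeps) % thin == 0:
            samples[j] = x[0]
            log_posts[j] = p[0, 0] + p[0, 1]
            j += 1
    rate = acc_cold / max(n_sweeps - n_burn_sweeps, 1)
    swap_rate = swaps_acc / max(swaps_try, 1)
    return samples[:j], log_posts[:j], rate, swap_rate


def mh_sample(
    obs: ObservationSet,
    forcing: ForcingSeries,
    prior: PriorSpec | None = None,
    n_iter: int = 50_000,
    n_burn: int | None = None,
    seed: int = 0,
    proposal_scale: float | np.ndarray = 0.1,
    thin: int = 10,
    init_water: float = 100.0,
    precondition: bool = True,
    betas: tuple[float, ...] = (1.0, 0.55, 0.3, 0.15),
    config: ModelConfig = DEFAULT_CONFIG,
) -> Posterior:
    """Estimate parameters and initial pools by Metropolis-Hastings.

    The chain runs in transformed space (log/logit), with the prior density
    evaluated in natural space plus the transform Jacobian. A non-finite
    likelihood (numerical blow-up) simply rejects the proposal. An empty
    ``ObservationSet`` yields a prior-only chain.

    ``n_iter`` is the total budget of MH updates. With ``precondition``
    (and at least one observation stream) the sampler is a
    Laplace-preconditioned replica-exchange scheme: a quasi-Newton search
    finds the posterior mode, a finite-difference Hessian seeds the
    proposal covariance, and ``len(betas)`` tempered replicas share the
    update budget with regular state swaps — the tempered replicas carry
    the cold chain across the ridges and secondary modes this posterior
    exhibits. Burn-in defaults to 30% (spent on per-replica adaptation,
    frozen afterwards). Without preconditioning a single adaptive
    random-walk chain from the prior midpoint is used, with 50% burn-in.
    """
    if prior is None:
        prior = default_priors()
    names = prior.names
    idx = {n: i for i, n in enumerate(names)}
    par_idx = [idx[n] for n in PARAM_NAMES if n in idx]
    par_names = [n for n in PARAM_NAMES if n in idx]
    if par_names != list(PARAM_NAMES):
        missing = set(PARAM_NAMES) - set(par_names)
        raise ValueError(f"prior must cover all model parameters; missing {sorted(missing)}")
    init_idx = [idx.get(n) for n in INIT_POOL_NAMES]
    if any(i is None for i in init_idx):
        raise ValueError("prior must cover the six initial carbon pools")

    consts = config.as_array()
    from ._core import simulate_core

    streams = obs.streams()
    lcma_i = idx["lcma"]

    def parts(z: np.ndarray) -> tuple[float, float]:
        x = prior.from_transformed(z)
        lp = log_prior(x, prior)
        if not np.isfinite(lp):
            return -np.inf, 0.0
        lp += prior.log_jacobian(z)
        if not streams:
            return lp, 0.0
        init = np.empty(7)
        for j, i in enumerate(init_idx):
            init[j] = x[i]
        init[6] = init_water
        pools, fluxes = simulate_core(
            x[par_idx] if par_idx != list(range(20)) else x[:20],
            init, forcing.t_mean, forcing.precip, forcing.sw_rad,
            forcing.days, forcing.ba_frac, consts,
        )
        traj = Trajectory(pools=pools, fluxes=fluxes, start_year=forcing.start_year)
        ll = log_likelihood(traj, obs, lcma=x[lcma_i])
        if not np.isfinite(ll):
            return -np.inf, 0.0
        return lp, ll

    def log_target(z: np.ndarray) -> float:
        lp, ll = parts(z)
        return lp + ll if np.isfinite(lp) else -np.inf

    if n_iter <= 0:
        raise ValueError("n_iter must be > 0")
    z_mid = prior.to_transformed(prior.midpoint())
    use_precond = precondition and bool(streams)

    if use_precond:
        z_map, cov0 = _laplace_approximation(log_target, z_mid)
        k_temps = len(betas)
        n_sweeps = n_iter // k_temps
        burn_sweeps = (int(0.3 * n_sweeps) if n_burn is None
                       else n_burn // k_temps)
        samples_z, log_posts, rate, _ = _parallel_tempering(
            parts, z_map, cov0, n_iter=n_iter, n_burn_sweeps=burn_sweeps,
            seed=seed, betas=betas, thin=thin,
        )
        burn_total = burn_sweeps * k_temps
    else:
        burn_total = n_iter // 2 if n_burn is None else n_burn
        samples_z, log_posts, rate = random_walk_metropolis(
            log_target, z_mid, n_iter=n_iter, n_burn=burn_total,
            scales=proposal_scale, seed=seed, thin=thin,
        )

    samples = np.vstack([prior.from_transformed(z) for z in samples_z])
    return Posterior(
        samples=samples, names=list(names), log_post=log_posts,
        acceptance_rate=float(rate), seed=seed, n_iter=n_iter,
        n_burn=burn_total, thin=thin,
    )


def posterior_predict(
    posterior: Posterior,
    forcing: ForcingSeries,
    n_draws: int,
    seed: int = 0,
    init_water: float = 100.0,
    config: ModelConfig = DEFAULT_CONFIG,
) -> dict[str, np.ndarray]:
    """Monte-Carlo flux quantiles per month.

    Simulates the model for ``n_draws`` posterior draws and returns, per
    flux, a (3, T) array of the first quartile, median and third quartile.
    """
    if posterior.n_draws == 0:
        raise ValueError("posterior contains no draws")
    if n_draws > posterior.n_draws:
        raise ValueError("n_draws exceeds the retained posterior draws")
    rng = np.random.default_rng(seed)
    rows = rng.choice(posterior.n_draws, size=n_draws, replace=False)
    keys = ("gpp", "ra", "rh", "fire_emission", "ter", "nee", "nbe")
    stack = {k: np.empty((n_draws, forcing.n_months)) for k in keys}
    for j, i in enumerate(rows):
        params, init = posterior.draw(int(i))
        if init is None:
            raise ValueError("posterior lacks initial pool columns")
        init = init.replace(water=init_water)
        traj = simulate(params, init, forcing, config)
        for k in keys:
            stack[k][j] = getattr(traj, k)
    q = (0.25, 0.5, 0.75)
    return {k: np.quantile(v, q, axis=0) for k, v in stack.items()}


def convergence_diag(posteriors: list[Posterior] | list[np.ndarray]) -> dict[str, float]:
    """Split-chain potential scale reduction factor (Gelman-Rubin R-hat).

    Each chain is split in half; R-hat compares between- and within-half
    variances per parameter and approaches 1 for well-mixed chains.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least two chains")
    if isinstance(posteriors[0], Posterior):
        names = posteriors[0].names
        chains = [p.samples for p in posteriors]
    else:
        chains = [np.asarray(c, dtype=float) for c in posteriors]
        if chains[0].ndim == 1:
            chains = [c[:, None] for c in chains]
        names = [f"p{i}" for i in range(chains[0].shape[1])]
    n = chains[0].shape[0]
    if any(c.shape != chains[0].shape for c in chains):
        raise ValueError("all chains must have equal length and dimension")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    halves = []
    for c in chains:
        halves.append(c[:half])
        halves.append(c[half: 2 * half])
    arr = np.stack(halves)  # (m, half, d)
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    # degenerate chains: no within-variance at all -> 1 if the chains agree,
    # infinity if they sit at different constants
    rhat = np.where(w == 0, np.where(b_over_n == 0, 1.0, np.inf), rhat)
    return dict(zip(names, rhat.astype(float)))
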
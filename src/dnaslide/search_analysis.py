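"""Disorder averages, search-time conversion, and power-law regime fitting.

The facilitated search alternates rounds of 1D sliding with 3D excursions.
With ``N_s = L / Lambda`` sliding rounds over a searched length ``L`` (bases),
an exploration length ``Lambda`` per round, and sliding and bulk times per
round assumed equal at the optimum (``t_Lambda = t_3D``), the minimum overall
search time reduces to

    t_s = 2 (L / Lambda) * t_Lambda ,   t_Lambda = tau_Lambda / nu ,

where ``tau_Lambda`` is the (dimensionless) conditioned MFPT to traverse
``Lambda`` sites and ``nu`` the attempt frequency.  Defaults mirror the
bacterial estimates: ``nu = 1e8`` Hz, ``L = 1e6`` bases, ``Lambda = 50``
bases.

The dependence of ``tau_50`` and of the complex half-life on the reaction
probability ``sigma`` exhibits two power-law regimes (a small-``sigma``
plateau and a large-``sigma`` screening branch); the fits here are ordinary
least squares in log10-log10 coordinates, and the regime transition is the
closed-form intersection of the two fitted lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, NoIntersectionError
from .first_passage import mfpt_profile
from .landscape import generate_landscape

__all__ = [
    "SearchParameters",
    "PowerLawFit",
    "search_time",
    "disorder_average",
    "fit_power_law",
    "regime_transition",
    "derive_seeds",
]

#: default log-log fit windows for the two sigma regimes
PLATEAU_WINDOW = (1e-7, 1e-5)
SCREENING_WINDOW = (3e-4, 3e-2)


@dataclass(frozen=True)
class SearchParameters:
    """Physical search parameters: attempt frequency and lengths in bases."""

    nu: float = 1e8
    L: float = 1e6
    lam: float = 50.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise InvalidParameterError(f"nu must be > 0, got {self.nu}")
        if not (self.L >= self.lam >= 1):
            raise InvalidParameterError(
                f"need L >= lam >= 1, got L={self.L}, lam={self.lam}"
            )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law ``y = prefactor * x**exponent`` (log10 space)."""

    exponent: float
    prefactor: float
    fit_range: tuple[float, float]
    residual: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent


def search_time(tau_lambda: float | np.ndarray, params: SearchParameters) -> float | np.ndarray:
    """Minimum overall search time in seconds, ``2 (L/lam) tau / nu``."""
    tau = np.asarray(tau_lambda, dtype=float)
    if np.any(tau < 0):
        raise InvalidParameterError("tau must be >= 0")
    out = 2.0 * (params.L / params.lam) * tau / params.nu
    return float(out) if out.ndim == 0 else out


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """``n`` independent sub-seeds derived deterministically from one seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def disorder_average(
    mu: float,
    sigma: float | np.ndarray = 0.0,
    n_realizations: int = 20,
    base_seed: int = 0,
    n_sites: int = 100,
    beta: float = 1.0,
    sites: np.ndarray | None = None,
) -> dict:
    """Arithmetic disorder average of the conditioned MFPT profile.

    Each realization draws an independent landscape (seeds derived from
    ``base_seed``), recomputes the full profile, and the per-site mean and
    standard error over realizations are returned along with the per-site
    spread and all realization seeds.
    """
    if n_realizations < 1:
        raise InvalidParameterError("n_realizations must be >= 1")
    seeds = derive_seeds(base_seed, n_realizations)
    taus = []
    out_sites = None
    for sd in seeds:
        land = generate_landscape(n_sites, mu, int(sd))
        out_sites, tau, _reach = mfpt_profile(land, beta=beta, sigma=sigma, sites=sites)
        taus.append(tau)
    taus = np.vstack(taus)
    mean = np.nanmean(taus, axis=0)
    sd_across = np.nanstd(taus, axis=0, ddof=1) if n_realizations > 1 else np.zeros_like(mean)
    return {
        "sites": out_sites,
        "mean": mean,
        "stderr": sd_across / np.sqrt(n_realizations),
        "spread": sd_across,
        "per_realization": taus,
        "seeds": seeds,
        "mu": mu,
        "n_realizations": n_realizations,
    }


def fit_power_law(
    x_grid: np.ndarray,
    y_values: np.ndarray,
    fit_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit ``y ~ x**e`` by least squares on log10-log10 coordinates."""
    x = np.asarray(x_grid, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if fit_range is None:
        fit_range = (float(x.min()), float(x.max()))
    mask = (x >= fit_range[0]) & (x <= fit_range[1])
    if mask.sum() < 3:
        raise InvalidParameterError("need at least 3 points inside the fit range")
    if np.any(x[mask] <= 0) or np.any(y[mask] <= 0) or not np.all(np.isfinite(y[mask])):
        raise InvalidParameterError("power-law fit needs positive finite values")
    lx, ly = np.log10(x[mask]), np.log10(y[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = float(np.sqrt(np.mean((ly - (slope * lx + intercept)) ** 2)))
    return PowerLawFit(
        exponent=float(slope),
        prefactor=float(10.0**intercept),
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        residual=resid,
    )


def regime_transition(fit_small: PowerLawFit, fit_large: PowerLawFit) -> float:
    """``sigma*`` where the two fitted power laws intersect (closed form)."""
    de = fit_small.exponent - fit_large.exponent
    if abs(de) < 1e-12:
        raise NoIntersectionError("fitted power laws are parallel")
    log_sigma = (np.log10(fit_large.prefactor) - np.log10(fit_small.prefactor)) / de
    return float(10.0**log_sigma)
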
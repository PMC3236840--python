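"""Quenched Gaussian binding-energy landscapes and Arrhenius hopping probabilities.

A sliding protein sees each base-pair position ``i = 1..N`` as a lattice site
with binding free energy ``U_i`` (in units of k_B T, measured relative to the
nonspecific baseline).  For a generic bacterial protein the ``U_i`` are well
approximated by independent draws from a zero-mean Gaussian whose standard
deviation ``mu`` is the *roughness* of the landscape.

Transport between adjacent sites follows a Metropolis-capped Arrhenius rule:
in one attempt time ``1/nu`` the walker hops across the bond with probability

    alpha = (1/2) * min{1, exp(-beta * dU)},

where ``dU`` is the destination energy minus the current-site energy.  The
factor of one half comes from normalisation over the two directions and
guarantees ``alpha_right + alpha_left <= 1`` at every site; the remainder is
the *sojourn* probability through which the dissociation channel acts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "EnergyLandscape",
    "HoppingProbabilities",
    "generate_landscape",
    "estimate_roughness",
    "hopping_probabilities",
    "sample_site_reaction_rates",
    "read_landscape",
    "write_landscape",
]

#: conversion between a Gaussian FWHM and its standard deviation
_FWHM_TO_SD = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class EnergyLandscape:
    """Per-site binding free energies ``U_i`` (k_B T) — the quenched disorder.

    Site ``i`` (1-based, ``i = 1..n_sites``) maps to ``energies[i - 1]``.
    """

    energies: np.ndarray
    mu_nominal: float
    seed: int | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=np.float64)
        if e.ndim != 1 or e.size < 2:
            raise InvalidParameterError("a landscape needs at least 2 sites")
        if not np.all(np.isfinite(e)):
            raise InvalidParameterError("energies must be finite")
        object.__setattr__(self, "energies", e)

    @property
    def n_sites(self) -> int:
        return int(self.energies.size)


@dataclass(frozen=True)
class HoppingProbabilities:
    """Per-attempt hop probabilities derived from a landscape.

    ``alpha_right[i]`` is the probability to hop from site ``i+1`` to ``i+2``
    (0-based array over 1-based sites) in one attempt time ``1/nu``;
    ``alpha_left`` likewise to the left.  ``alpha_left[0] = 0`` (reflecting
    origin) and ``alpha_right[-1] = 0`` (no right neighbour; unused once the
    last site is a trap).  ``sojourn = 1 - alpha_right - alpha_left``.
    """

    alpha_right: np.ndarray
    alpha_left: np.ndarray
    beta: float
    sojourn: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        s = 1.0 - (self.alpha_right + self.alpha_left)
        if np.any(s < -1e-15):
            raise InvalidParameterError("alpha_right + alpha_left exceeds 1")
        object.__setattr__(self, "sojourn", np.maximum(s, 0.0))

    @property
    def n_sites(self) -> int:
        return int(self.alpha_right.size)


def generate_landscape(n_sites: int, mu: float, seed: int) -> EnergyLandscape:
    """Draw a quenched landscape of ``n_sites`` iid N(0, mu^2) energies.

    Parameters
    ----------
    n_sites:
        Number of lattice sites (base pairs), at least 2.
    mu:
        Roughness: the standard deviation of the energy distribution, in
        k_B T.  ``mu = 0`` gives a flat landscape.
    seed:
        RNG seed, recorded on the returned object; identical seeds give
        bit-identical landscapes.
    """
    if n_sites < 2:
        raise InvalidParameterError(f"n_sites must be >= 2, got {n_sites}")
    if mu < 0:
        raise InvalidParameterError(f"mu must be >= 0, got {mu}")
    rng = np.random.default_rng(seed)
    energies = rng.normal(0.0, mu, size=n_sites) if mu > 0 else np.zeros(n_sites)
    return EnergyLandscape(energies=energies, mu_nominal=float(mu), seed=int(seed))


def estimate_roughness(landscape: EnergyLandscape) -> float:
    """Root-mean-square fluctuation of the energies about their mean.

    Population convention (divide by N): the roughness is an ensemble-average
    fluctuation, so no sample-size correction is applied.
    """
    e = landscape.energies
    if e.size < 2:
        raise InvalidParameterError("need at least 2 sites to estimate roughness")
    return float(np.sqrt(np.mean((e - e.mean()) ** 2)))


def hopping_probabilities(landscape: EnergyLandscape, beta: float = 1.0) -> HoppingProbabilities:
    """Convert a landscape into nearest-neighbour hop probabilities.

    ``alpha = (1/2) min{1, exp(-beta dU)}`` per bond and direction, with
    ``dU`` the destination-minus-current energy difference.  Downhill moves
    are capped at 1/2; uphill moves are Arrhenius-suppressed.
    """
    if beta <= 0:
        raise InvalidParameterError(f"beta must be > 0, got {beta}")
    u = landscape.energies
    n = u.size
    alpha_right = np.zeros(n)
    alpha_left = np.zeros(n)
    du_right = u[1:] - u[:-1]  # bond i -> i+1
    alpha_right[:-1] = 0.5 * np.minimum(1.0, np.exp(-beta * du_right))
    alpha_left[1:] = 0.5 * np.minimum(1.0, np.exp(beta * du_right))
    return HoppingProbabilities(alpha_right=alpha_right, alpha_left=alpha_left, beta=float(beta))


def sample_site_reaction_rates(
    n_sites: int, mean_sigma: float, fwhm: float, seed: int
) -> np.ndarray:
    """Draw per-site dissociation probabilities ``sigma_i``.

    The distribution is a Gaussian with the given mean and full width at
    half maximum, truncated to the open interval (0, 1) by resampling so the
    values remain valid per-step probabilities.  ``fwhm = 0`` returns the
    degenerate distribution (all values equal to ``mean_sigma``).
    """
    if n_sites < 1:
        raise InvalidParameterError(f"n_sites must be >= 1, got {n_sites}")
    if not (0.0 < mean_sigma < 1.0):
        raise InvalidParameterError(f"mean_sigma must be in (0, 1), got {mean_sigma}")
    if fwhm < 0:
        raise InvalidParameterError(f"fwhm must be >= 0, got {fwhm}")
    if fwhm == 0:
        return np.full(n_sites, float(mean_sigma))
    sd = fwhm * _FWHM_TO_SD
    rng = np.random.default_rng(seed)
    out = np.empty(n_sites)
    filled = 0
    while filled < n_sites:
        draw = rng.normal(mean_sigma, sd, size=max(n_sites - filled, 64))
        ok = draw[(draw > 0.0) & (draw < 1.0)]
        take = min(ok.size, n_sites - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# plain-text landscape I/O: two columns (site TAB energy), '#' metadata header


def write_landscape(path: str | Path, landscape: EnergyLandscape) -> None:
    """Write a landscape as a two-column TSV with a '#' metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# dnaslide energy landscape (energies in k_BT)\n")
        fh.write(
            f"# n_sites={landscape.n_sites}\tmu_nominal={landscape.mu_nominal!r}"
            f"\tseed={landscape.seed}\n"
        )
        fh.write("# site\tenergy\n")
        for i, e in enumerate(landscape.energies, start=1):
            fh.write(f"{i}\t{float(e)!r}\n")


def read_landscape(path: str | Path) -> EnergyLandscape:
    """Read a landscape written by :func:`write_landscape` or a user profile.

    Accepts any two-column table (site index, energy in k_B T); '#' lines are
    treated as metadata and parsed for ``mu_nominal`` and ``seed`` when
    present (user-supplied profiles without them get ``mu_nominal`` set to
    the empirical roughness and ``seed=None``).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    sites: list[int] = []
    energies: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        cols = line.split()
        sites.append(int(cols[0]))
        energies.append(float(cols[1]))
    order = np.argsort(sites)
    e = np.asarray(energies)[order]
    mu = float(meta["mu_nominal"]) if "mu_nominal" in meta else float(
        np.sqrt(np.mean((e - e.mean()) ** 2))
    )
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return EnergyLandscape(energies=e, mu_nominal=mu, seed=seed)
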
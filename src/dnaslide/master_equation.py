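"""Continuous-time transport equations for the sliding walker.

The walker starts at site 1 (reflecting origin) and diffuses over a lattice
of ``N`` sites; a perfectly absorbing trap sits at ``trap_site``.  Per attempt
time ``1/nu`` the walker at site ``i`` may (i) hop right with probability
``alpha_{i+1,i}``, (ii) hop left with probability ``alpha_{i-1,i}``, or
(iii) dissociate with probability ``sigma_i * (1 - alpha_{i+1,i} -
alpha_{i-1,i})`` — the reaction acts only through the sojourn probability.
Read as rates (units of ``nu``) these rules define a tridiagonal generator
``Q`` for the transient sites ``1..trap_site-1``, and the occupation
probabilities obey ``dp/dt = Q p`` with ``p(0) = delta_{i1}``.

Boundary conventions: the origin has no left channel and its reaction rate
uses its actual sojourn probability ``1 - alpha_{2,1}``; the trap only
receives flux (``alpha_{n,n-1} p_{n-1}``) and never releases or reacts.
All times are dimensionless (units of ``1/nu``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .errors import InvalidParameterError, SolverError
from .landscape import EnergyLandscape, HoppingProbabilities, hopping_probabilities

__all__ = [
    "LatticeSystem",
    "OccupationTrajectory",
    "build_system",
    "solve_occupation",
    "transient_generator",
]


@dataclass(frozen=True)
class LatticeSystem:
    """A fully specified diffusion-reaction process on the lattice.

    ``sigma`` is the per-site reaction probability (scalar input is
    broadcast); ``trap_site`` is 1-based in ``2..n_sites``.
    """

    hopping: HoppingProbabilities
    sigma: np.ndarray
    trap_site: int

    def __post_init__(self) -> None:
        n = self.hopping.n_sites
        if not (2 <= self.trap_site <= n):
            raise InvalidParameterError(
                f"trap_site must be in 2..{n}, got {self.trap_site}"
            )
        sig = np.broadcast_to(np.asarray(self.sigma, dtype=np.float64), (n,)).copy()
        if np.any(sig < 0) or np.any(sig >= 1):
            raise InvalidParameterError("sigma values must lie in [0, 1)")
        object.__setattr__(self, "sigma", sig)

    @property
    def n_sites(self) -> int:
        return self.hopping.n_sites

    @property
    def n_transient(self) -> int:
        return self.trap_site - 1

    @property
    def reaction_rates(self) -> np.ndarray:
        """Effective reaction rate ``sigma_i * sojourn_i`` per transient site."""
        m = self.n_transient
        return self.sigma[:m] * self.hopping.sojourn[:m]

    @property
    def trap_rate(self) -> float:
        """Influx rate into the trap, ``alpha_{n,n-1}``."""
        return float(self.hopping.alpha_right[self.trap_site - 2])


@dataclass(frozen=True)
class OccupationTrajectory:
    """Occupation probabilities ``p_i(t)`` over the transient sites.

    ``p[k, i]`` is the probability at time ``times[k]`` of occupying transient
    site ``i+1``; ``absorbed``/``reacted`` are the cumulative probabilities
    captured by the trap or lost to dissociation.
    """

    times: np.ndarray
    p: np.ndarray
    absorbed: np.ndarray
    reacted: np.ndarray
    terminated_by: str = "t_max"
    rtol: float = 1e-8
    atol: float = 1e-12

    @property
    def transient_mass(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def conservation_defect(self) -> float:
        """Max over the grid of ``|sum_i p_i + absorbed + reacted - 1|``."""
        total = self.transient_mass + self.absorbed + self.reacted
        return float(np.max(np.abs(total - 1.0)))


def build_system(
    landscape: EnergyLandscape,
    beta: float = 1.0,
    sigma: float | np.ndarray = 0.0,
    trap_site: int | None = None,
) -> LatticeSystem:
    """Assemble the stochastic process from a landscape and reaction input.

    ``trap_site`` defaults to the last site.  Scalar ``sigma`` is broadcast
    to every site (the uniform-dissociation assumption); an array gives
    site-dependent rates.
    """
    hop = hopping_probabilities(landscape, beta)
    if trap_site is None:
        trap_site = landscape.n_sites
    return LatticeSystem(hopping=hop, sigma=np.asarray(sigma), trap_site=int(trap_site))


def transient_generator(system: LatticeSystem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal generator of the transient block.

    Returns ``(diag, lower, upper)`` where ``dp_i/dt = lower[i-1] p_{i-1}
    + diag[i] p_i + upper[i] p_{i+1}`` (0-based transient indices):
    ``lower[i]`` is the right-hop rate out of site ``i+1`` into ``i+2`` and
    ``upper[i]`` the left-hop rate out of site ``i+2`` into ``i+1``.
    """
    m = system.n_transient
    ar = system.hopping.alpha_right[:m]
    al = system.hopping.alpha_left[:m]
    lower = ar[:-1].copy()  # i -> i+1, feeds below
    upper = al[1:].copy()   # i+1 -> i, feeds above
    out = ar + al + system.reaction_rates
    return -out, lower, upper


def dense_generator(system: LatticeSystem) -> np.ndarray:
    """Dense ``m x m`` transient generator (for oracles and small systems)."""
    diag, lower, upper = transient_generator(system)
    q = np.diag(diag)
    m = diag.size
    if m > 1:
        q[np.arange(1, m), np.arange(m - 1)] = lower
        q[np.arange(m - 1), np.arange(1, m)] = upper
    return q


def solve_transient_banded(system: LatticeSystem, rhs: np.ndarray) -> np.ndarray:
    """Solve ``(-Q) x = rhs`` for the tridiagonal transient generator."""
    diag, lower, upper = transient_generator(system)
    m = diag.size
    ab = np.zeros((3, m))
    ab[0, 1:] = -upper
    ab[1, :] = -diag
    ab[2, :-1] = -lower
    return solve_banded((1, 1), ab, rhs)


def solve_occupation(
    system: LatticeSystem,
    t_max: float,
    n_grid: int = 600,
    grid: str = "log",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    stop_mass: float = 1e-10,
    method: str = "BDF",
) -> OccupationTrajectory:
    """Integrate the master equation from the sharp initial condition.

    The state is augmented with the cumulative absorbed probability
    (time-integral of the trap influx ``alpha_{n,n-1} p_{n-1}``) and the
    cumulative reacted probability (integral of the total dissociation
    loss), so probability conservation can be checked on every grid point.
    Integration stops early once the transient mass falls below
    ``stop_mass`` (reported via ``terminated_by``).

    Parameters
    ----------
    t_max:
        Horizon in units of ``1/nu``.
    n_grid, grid:
        Size and spacing ("log" or "linear") of the output grid; ``t = 0``
        is always included.
    """
    if t_max <= 0:
        raise InvalidParameterError(f"t_max must be > 0, got {t_max}")
    m = system.n_transient
    diag, lower, upper = transient_generator(system)
    react = system.reaction_rates
    trap_rate = system.trap_rate

    jac = np.zeros((m + 2, m + 2))
    jac[:m, :m] = dense_generator(system)
    jac[m, m - 1] = trap_rate           # d(absorbed)/dt
    jac[m + 1, :m] = react              # d(reacted)/dt

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return jac @ y

    if grid == "log":
        t_eval = np.concatenate(([0.0], np.geomspace(t_max * 1e-6, t_max, n_grid - 1)))
    elif grid == "linear":
        t_eval = np.linspace(0.0, t_max, n_grid)
    else:
        raise InvalidParameterError(f"unknown grid kind {grid!r}")

    y0 = np.zeros(m + 2)
    y0[0] = 1.0

    def mass_event(_t: float, y: np.ndarray) -> float:
        return float(y[:m].sum() - stop_mass)

    mass_event.terminal = True
    mass_event.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=lambda _t, _y: jac,
        events=mass_event,
    )
    if not sol.success:
        raise SolverError(f"stiff integration failed: {sol.message}")
    terminated_by = "mass_below_threshold" if sol.t_events[0].size else "t_max"
    y = sol.y.T
    return OccupationTrajectory(
        times=sol.t,
        p=np.maximum(y[:, :m], 0.0),
        absorbed=y[:, m],
        reacted=y[:, m + 1],
        terminated_by=terminated_by,
        rtol=rtol,
        atol=atol,
    )
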
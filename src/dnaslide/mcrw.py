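"""Exact Monte Carlo Random Walk (MCRW) simulation of the sliding rules.

The walk is strictly discrete in time: one decision per attempt time
``1/nu``.  At each step a single uniform draw selects hop-right
(``u < alpha_right``), hop-left (``u < alpha_right + alpha_left``) or the
sojourn branch, inside which a second draw triggers dissociation with
probability ``sigma_i`` — so the per-step reaction probability is exactly
``sigma_i (1 - alpha_right - alpha_left)``.  A trajectory ends when the
walker reaches the trap (success) or reacts; a run launches fresh
trajectories from the origin until a target number of successes has been
collected, as in the original validation protocol (1000 successes).

First-visit times are recorded for every site a trajectory touches, and the
per-site arithmetic means over all visiting trajectories estimate the
survival-conditioned mean first-passage times (any walker that reaches a
far site passed every nearer site first, so intermediate-site statistics
may pool all trajectories, successful or not).

The batch runner is compiled with numba; a pure-Python trajectory simulator
with optional visit recording is kept for fine-grained inspection and
root-mean-square displacement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InvalidParameterError, RunawayTrajectoryError
from .master_equation import LatticeSystem

__all__ = [
    "TrajectoryRecord",
    "McrwSummary",
    "simulate_trajectory",
    "run_mcrw",
    "rms_displacement",
]


@dataclass(frozen=True)
class TrajectoryRecord:
    """One trajectory: first-visit step per site, length, and outcome.

    ``first_visit[i]`` (0-based site index) is the step count at first
    arrival, ``-1`` if never visited; site 1 has first-visit 0.  ``outcome``
    is ``"reached-target"``, ``"reacted"`` or ``"censored"`` (stopped by a
    step budget).  ``visit_sequence[t]`` is the 0-based site occupied after
    ``t`` steps, recorded only on request.
    """

    first_visit: np.ndarray
    n_steps: int
    outcome: str
    visit_sequence: np.ndarray | None = None
    reaction_site: int | None = None


@dataclass(frozen=True)
class McrwSummary:
    """Per-site first-visit statistics aggregated over a run.

    Sites are 1-based in ``sites``; ``mean_fpt`` is NaN where no trajectory
    ever visited the site.
    """

    sites: np.ndarray
    mean_fpt: np.ndarray
    stderr: np.ndarray
    n_samples: np.ndarray
    n_success: int
    n_trajectories: int
    seed: int


def simulate_trajectory(
    system: LatticeSystem,
    rng: np.random.Generator,
    record_visits: bool = False,
    max_steps: int = 10**9,
    stop_after: int | None = None,
) -> TrajectoryRecord:
    """Simulate one trajectory of the discrete-time walk.

    ``stop_after`` censors the trajectory cleanly after that many steps
    (useful for displacement statistics on effectively unbounded lattices);
    exceeding ``max_steps`` without terminating raises instead.
    """
    ar = system.hopping.alpha_right
    al = system.hopping.alpha_left
    sig = system.sigma
    trap = system.trap_site - 1
    first_visit = np.full(system.n_sites, -1, dtype=np.int64)
    first_visit[0] = 0
    visits = [0] if record_visits else None
    pos = 0
    step = 0
    outcome = None
    reaction_site = None
    while True:
        if stop_after is not None and step >= stop_after:
            outcome = "censored"
            break
        if step >= max_steps:
            raise RunawayTrajectoryError(f"trajectory exceeded {max_steps} steps")
        step += 1
        u = rng.random()
        if u < ar[pos]:
            pos += 1
        elif u < ar[pos] + al[pos]:
            pos -= 1
        else:
            if rng.random() < sig[pos]:
                outcome = "reacted"
                reaction_site = pos
                break
        if visits is not None:
            visits.append(pos)
        if first_visit[pos] < 0:
            first_visit[pos] = step
        if pos == trap:
            outcome = "reached-target"
            break
    return TrajectoryRecord(
        first_visit=first_visit,
        n_steps=step,
        outcome=outcome,
        visit_sequence=np.asarray(visits, dtype=np.int64) if visits is not None else None,
        reaction_site=reaction_site,
    )


@njit(cache=False)
def _mcrw_kernel(ar, al, sig, trap, n_success_target, max_trajectories, max_steps, seed):
    np.random.seed(seed)
    n = trap + 1
    sum_fpt = np.zeros(n)
    sum_fpt_sq = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    first_visit = np.empty(n, dtype=np.int64)
    n_success = 0
    n_traj = 0
    overran = False
    while n_success < n_success_target and n_traj < max_trajectories:
        n_traj += 1
        for i in range(n):
            first_visit[i] = -1
        first_visit[0] = 0
        pos = 0
        step = 0
        while True:
            if step >= max_steps:
                overran = True
                break
            step += 1
            u = np.random.random()
            if u < ar[pos]:
                pos += 1
            elif u < ar[pos] + al[pos]:
                pos -= 1
            else:
                if np.random.random() < sig[pos]:
                    break  # reacted
                continue
            if first_visit[pos] < 0:
                first_visit[pos] = step
            if pos == trap:
                n_success += 1
                break
        if overran:
            break
        for i in range(n):
            fv = first_visit[i]
            if fv >= 0:
                counts[i] += 1
                sum_fpt[i] += fv
                sum_fpt_sq[i] += float(fv) * float(fv)
    return sum_fpt, sum_fpt_sq, counts, n_success, n_traj, overran


def run_mcrw(
    system: LatticeSystem,
    n_success_target: int = 1000,
    seed: int = 0,
    max_trajectories: int = 10**8,
    max_steps: int = 10**9,
) -> McrwSummary:
    """Run trajectories until ``n_success_target`` reach the trap.

    Aggregates per-site mean first-visit times with standard errors over
    all trajectories that visited each site.  One seeded stream drives the
    whole run; identical seeds reproduce the run exactly.

    Raises
    ------
    RunawayTrajectoryError
        If a single trajectory exceeds ``max_steps``, or the trajectory
        budget is exhausted before the success target is met (the message
        names the achieved success count).
    """
    if n_success_target < 1:
        raise InvalidParameterError("n_success_target must be >= 1")
    trap = system.trap_site - 1
    sum_fpt, sum_sq, counts, n_success, n_traj, overran = _mcrw_kernel(
        system.hopping.alpha_right,
        system.hopping.alpha_left,
        system.sigma,
        trap,
        n_success_target,
        max_trajectories,
        max_steps,
        seed,
    )
    if overran:
        raise RunawayTrajectoryError(f"a trajectory exceeded {max_steps} steps")
    if n_success < n_success_target:
        raise RunawayTrajectoryError(
            f"target effectively unreachable: {n_success}/{n_success_target} "
            f"successes after {n_traj} trajectories"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_fpt / counts
        var = sum_sq / counts - mean**2
        stderr = np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1))
    mean[counts == 0] = np.nan
    stderr[counts == 0] = np.nan
    return McrwSummary(
        sites=np.arange(1, trap + 2),
        mean_fpt=mean,
        stderr=stderr,
        n_samples=counts,
        n_success=int(n_success),
        n_trajectories=int(n_traj),
        seed=int(seed),
    )


def rms_displacement(records: list[TrajectoryRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Root-mean-square displacement from the origin per time step.

    At step ``t`` the RMS is taken across the trajectories still walking at
    ``t`` (position recorded in their visit sequences).  Returns
    ``(steps, rms)``; ``rms[0] = 0`` since every walker starts at the
    origin.  Requires visit sequences to have been retained.
    """
    records = [r for r in records if r.visit_sequence is not None]
    if not records:
        raise InvalidParameterError("no records with visit sequences")
    t_max = max(r.visit_sequence.size for r in records)
    sum_sq = np.zeros(t_max)
    n_alive = np.zeros(t_max, dtype=np.int64)
    for r in records:
        seq = r.visit_sequence.astype(np.float64)
        sum_sq[: seq.size] += seq**2
        n_alive[: seq.size] += 1
    rms = np.sqrt(sum_sq / n_alive)
    return np.arange(t_max), rms
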
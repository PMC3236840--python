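"""Renormalized first-passage distributions, MFPT profiles, and oracles."""

import numpy as np
import pytest

from dnaslide import (
    EnergyLandscape,
    UnreachableTargetError,
    build_system,
    discrete_mfpt_oracle,
    first_passage_distribution,
    generate_landscape,
    mfpt_and_reach,
    mfpt_matrix_oracle,
    mfpt_profile,
)

#: conditioned mean steps for U=(0,1,0), sigma=0.1 (h-transform closed form)
BARRIER_CONDITIONED_MEAN = 7.2910227417
BARRIER_REACH = 0.5298538940


def _discrete_time_march(system, t_cap=200_000):
    """Independent oracle: march the discrete chain and accumulate trap flux."""
    m = system.n_transient
    ar = system.hopping.alpha_right[:m]
    al = system.hopping.alpha_left[:m]
    stay = (1.0 - ar - al) * (1.0 - system.sigma[:m])
    p = np.zeros(m)
    p[0] = 1.0
    mass = 0.0
    first_moment = 0.0
    for t in range(1, t_cap + 1):
        flux = ar[-1] * p[-1]
        new = stay * p
        new[1:] += ar[:-1] * p[:-1]
        new[:-1] += al[1:] * p[1:]
        p = new
        mass += flux
        first_moment += t * flux
        if p.sum() < 1e-14:
            break
    return first_moment / mass, mass


class TestExactSmallSystems:
    def test_two_site_exponential_first_passage(self):
        land = EnergyLandscape(energies=np.zeros(2), mu_nominal=0.0)
        system = build_system(land, sigma=0.0, trap_site=2)
        res = first_passage_distribution(system)
        assert res.mfpt == pytest.approx(2.0, rel=1e-10)
        assert res.reach_probability == pytest.approx(1.0, abs=1e-10)
        # F(t) = (1/2) e^{-t/2}; renormalized density equals it directly
        assert np.allclose(res.fpt_density, 0.5 * np.exp(-res.times / 2), atol=1e-7)

    def test_density_normalizes_to_reach_probability(self, barrier_landscape):
        system = build_system(barrier_landscape, sigma=0.1, trap_site=3)
        res = first_passage_distribution(system, n_grid=2000)
        assert np.trapezoid(res.fpt_density, res.times) == pytest.approx(1.0, abs=1e-3)
        assert np.all(res.fpt_density >= 0.0)

    def test_flat_profile_equals_n_times_n_minus_one(self, flat_landscape):
        sites, tau, reach = mfpt_profile(flat_landscape, sigma=0.0)
        expected = sites * (sites - 1.0)
        assert tau[0] == 0.0
        assert np.all(reach == pytest.approx(1.0, abs=1e-12))
        rel = np.abs(tau[1:] - expected[1:]) / expected[1:]
        assert np.max(rel) < 1e-8
        assert tau[9] == pytest.approx(90.0) and tau[49] == pytest.approx(2450.0)
        # on a flat landscape more distance never takes less expected time
        assert np.all(np.diff(tau) > 0)

    def test_barrier_reaction_free_closed_form(self, barrier_landscape):
        system = build_system(barrier_landscape, sigma=0.0, trap_site=3)
        tau, reach = mfpt_and_reach(system)
        assert tau == pytest.approx(2 * (2 * np.e + 1), rel=1e-10)
        assert reach == pytest.approx(1.0, abs=1e-12)


class TestOracleAgreement:
    def test_barrier_conditioned_mean_all_routes(self, barrier_landscape):
        system = build_system(barrier_landscape, sigma=0.1, trap_site=3)
        tau_ct, reach_ct = mfpt_and_reach(system)
        tau_mx, reach_mx = mfpt_matrix_oracle(system)
        tau_dx, reach_dx = discrete_mfpt_oracle(system)
        # unit-mean step times make the discrete and continuous conditioned
        # means coincide exactly (-Q = I - P)
        for tau, reach in [(tau_ct, reach_ct), (tau_mx, reach_mx), (tau_dx, reach_dx)]:
            assert tau == pytest.approx(BARRIER_CONDITIONED_MEAN, rel=1e-9)
            assert reach == pytest.approx(BARRIER_REACH, rel=1e-9)
        # survivors are faster than the reaction-free walkers
        assert tau_ct < 2 * (2 * np.e + 1)

    def test_time_march_oracle_agrees(self, barrier_landscape):
        system = build_system(barrier_landscape, sigma=0.1, trap_site=3)
        tau_march, reach_march = _discrete_time_march(system)
        assert tau_march == pytest.approx(BARRIER_CONDITIONED_MEAN, rel=1e-6)
        assert reach_march == pytest.approx(BARRIER_REACH, rel=1e-6)

    def test_banded_route_matches_matrix_oracle_on_rugged_systems(self):
        land = generate_landscape(50, 1.0, 31)
        for sigma in [0.0, 1e-3, 1e-1]:
            system = build_system(land, sigma=sigma)
            tau_a, reach_a = mfpt_and_reach(system)
            tau_b, reach_b = mfpt_matrix_oracle(system)
            assert tau_a == pytest.approx(tau_b, rel=1e-6)
            assert reach_a == pytest.approx(reach_b, rel=1e-6)


class TestScreening:
    def test_mfpt_decreases_with_reaction_rate(self, rugged_landscape):
        taus = []
        for sigma in [0.0, 1e-3, 1e-2, 1e-1]:
            system = build_system(rugged_landscape, sigma=sigma, trap_site=50)
            tau, _ = mfpt_and_reach(system)
            taus.append(tau)
        assert np.all(np.diff(taus) < 0)

    def test_reach_probability_decreases_with_sigma(self, rugged_landscape):
        reaches = []
        for sigma in [0.0, 1e-3, 1e-2]:
            system = build_system(rugged_landscape, sigma=sigma, trap_site=50)
            _, reach = mfpt_and_reach(system)
            reaches.append(reach)
        assert reaches[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(reaches) < 0)

    def test_profile_screens_at_every_site(self, rugged_landscape):
        _, tau0, _ = mfpt_profile(rugged_landscape, sigma=0.0)
        _, tau2, _ = mfpt_profile(rugged_landscape, sigma=1e-2)
        assert np.all(tau2[1:] <= tau0[1:])

    def test_effectively_unreachable_target_raises(self):
        land = generate_landscape(100, 3.0, 5)
        system = build_system(land, sigma=0.99)
        with pytest.raises(UnreachableTargetError):
            mfpt_and_reach(system)

    def test_profile_records_gaps_instead_of_failing(self):
        land = generate_landscape(100, 3.0, 5)
        sites, tau, reach = mfpt_profile(land, sigma=0.99)
        assert np.isfinite(tau[1])            # nearby sites still reachable
        assert np.isnan(tau[-1])              # far sites recorded as gaps
        assert reach[-1] == 0.0
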
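"""Landscape generation, roughness estimation, hopping rule, reaction rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dnaslide import (
    EnergyLandscape,
    InvalidParameterError,
    estimate_roughness,
    generate_landscape,
    hopping_probabilities,
    read_landscape,
    sample_site_reaction_rates,
    write_landscape,
)


class TestGenerateLandscape:
    def test_seed_reproducibility_is_bitwise(self):
        a = generate_landscape(1000, 0.75, 42)
        b = generate_landscape(1000, 0.75, 42)
        assert np.array_equal(a.energies, b.energies)
        assert a.seed == 42 and a.mu_nominal == 0.75

    def test_mu_zero_gives_exactly_flat_landscape(self):
        land = generate_landscape(10, 0.0, 3)
        assert np.array_equal(land.energies, np.zeros(10))

    def test_large_sample_matches_gaussian_moments(self):
        n, mu = 10**5, 2.0
        land = generate_landscape(n, mu, 7)
        assert abs(land.energies.mean()) < 3 * mu / np.sqrt(n)
        assert abs(land.energies.std() - mu) < 0.01 * mu

    def test_reference_roughness_scale(self):
        # 100 sites at mu = 0.75: sample sd within 3 standard errors
        land = generate_landscape(100, 0.75, 11)
        se_of_sd = 0.75 / np.sqrt(2 * 100)
        assert abs(land.energies.std(ddof=1) - 0.75) < 3 * se_of_sd

    @pytest.mark.parametrize("n_sites,mu", [(1, 0.5), (0, 1.0), (10, -0.1)])
    def test_invalid_parameters_rejected(self, n_sites, mu):
        with pytest.raises(InvalidParameterError):
            generate_landscape(n_sites, mu, 0)


class TestEstimateRoughness:
    def test_constant_energies_have_zero_roughness(self):
        land = EnergyLandscape(energies=np.zeros(4), mu_nominal=0.0)
        assert estimate_roughness(land) == 0.0

    def test_two_site_population_convention(self):
        # (-1, +1): mean 0, population RMS fluctuation exactly 1
        land = EnergyLandscape(energies=np.array([-1.0, 1.0]), mu_nominal=1.0)
        assert estimate_roughness(land) == pytest.approx(1.0, abs=1e-15)

    def test_consistency_with_generation(self):
        land = generate_landscape(10**5, 1.0, 5)
        assert estimate_roughness(land) == pytest.approx(1.0, rel=0.01)


class TestHoppingProbabilities:
    def test_flat_landscape_is_symmetric_half(self, flat_landscape):
        hop = hopping_probabilities(flat_landscape, beta=1.0)
        assert np.all(hop.alpha_right[:-1] == 0.5)
        assert np.all(hop.alpha_left[1:] == 0.5)
        assert np.all(hop.sojourn[1:-1] == 0.0)
        assert hop.alpha_left[0] == 0.0  # reflecting origin

    def test_uphill_step_is_arrhenius_suppressed(self):
        land = EnergyLandscape(energies=np.array([0.0, 1.0]), mu_nominal=0.0)
        hop = hopping_probabilities(land, beta=1.0)
        assert hop.alpha_right[0] == pytest.approx(np.exp(-1.0) / 2, abs=1e-15)

    def test_downhill_step_is_capped_at_half(self):
        land = EnergyLandscape(energies=np.array([0.0, -2.0]), mu_nominal=0.0)
        hop = hopping_probabilities(land, beta=1.0)
        assert hop.alpha_right[0] == 0.5

    def test_probabilities_partition_unity(self, rugged_landscape):
        hop = hopping_probabilities(rugged_landscape, beta=1.0)
        total = (hop.alpha_right + hop.alpha_left) + hop.sojourn
        assert np.all(np.abs(total - 1.0) < 1e-15)
        interior = slice(1, -1)
        assert np.all(hop.alpha_right[interior] <= 0.5)
        assert np.all(hop.alpha_left[interior] <= 0.5)
        assert np.all(hop.alpha_right[interior] + hop.alpha_left[interior] <= 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        energies=st.lists(st.floats(-5, 5), min_size=3, max_size=8),
        bump=st.floats(0.01, 3.0),
        beta=st.floats(0.1, 3.0),
    )
    def test_raising_destination_energy_never_raises_alpha(self, energies, bump, beta):
        u = np.asarray(energies)
        land = EnergyLandscape(energies=u, mu_nominal=0.0)
        hop = hopping_probabilities(land, beta=beta)
        raised = u.copy()
        raised[1] += bump  # destination of the 1 -> 2 bond
        hop2 = hopping_probabilities(EnergyLandscape(energies=raised, mu_nominal=0.0), beta=beta)
        assert hop2.alpha_right[0] <= hop.alpha_right[0]


class TestSiteReactionRates:
    def test_zero_fwhm_is_degenerate(self):
        out = sample_site_reaction_rates(100, 1e-3, 0.0, 1)
        assert np.all(out == 1e-3)

    def test_values_strictly_inside_unit_interval(self):
        out = sample_site_reaction_rates(10**4, 1e-3, 1e-3, 2)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_broad_distribution_mean(self):
        # FWHM equal to the mean: compare against the truncated-normal
        # moments (truncation at 0 shifts the mean upward slightly, beyond
        # 3 naive standard errors at this sample size).
        n, m, fwhm = 10**5, 1e-3, 1e-3
        sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
        a, b = (0.0 - m) / sd, (1.0 - m) / sd
        expected = stats.truncnorm.mean(a, b, loc=m, scale=sd)
        se = stats.truncnorm.std(a, b, loc=m, scale=sd) / np.sqrt(n)
        out = sample_site_reaction_rates(n, m, fwhm, 3)
        assert abs(out.mean() - expected) < 3 * se
        assert out.mean() == pytest.approx(m, rel=0.02)

    @pytest.mark.parametrize("mean,fwhm", [(0.0, 0.1), (1.0, 0.1), (0.5, -0.1)])
    def test_invalid_parameters_rejected(self, mean, fwhm):
        with pytest.raises(InvalidParameterError):
            sample_site_reaction_rates(10, mean, fwhm, 0)


class TestLandscapeIO:
    def test_round_trip_is_exact(self, tmp_path, rugged_landscape):
        path = tmp_path / "landscape.tsv"
        write_landscape(path, rugged_landscape)
        back = read_landscape(path)
        assert np.array_equal(back.energies, rugged_landscape.energies)
        assert back.mu_nominal == rugged_landscape.mu_nominal
        assert back.seed == rugged_landscape.seed

    def test_reads_plain_user_profile(self, tmp_path):
        path = tmp_path / "user.tsv"
        path.write_text("1\t0.0\n2\t1.5\n3\t-0.5\n")
        land = read_landscape(path)
        assert np.array_equal(land.energies, [0.0, 1.5, -0.5])
        assert land.seed is None
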
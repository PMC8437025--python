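"""Monte Carlo transport kernels against closed-form and statistical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coralslab.grid import build_grid
from coralslab.photon_mc import (
    LightField,
    fresnel_reflectance,
    mid_slice,
    resample_light_field,
    run_photon_mc,
    sample_hg_cos,
    sample_step,
    smooth_light_field,
)
from coralslab.scenarios import baseline_stack


def uniform_optics_stack(mu_a_per_cm=0.0, mu_s_per_cm=0.0, g=0.0, n=1.0):
    """Baseline geometry with every layer given the same optical properties."""
    stack, domain = baseline_stack()
    out = []
    for lay in stack:
        out.append(lay.model_copy(update={
            "optical": lay.optical.model_copy(update={
                "mu_a_per_cm": mu_a_per_cm, "mu_s_per_cm": mu_s_per_cm,
                "g": g, "n": n,
            })
        }))
    return out, domain


class TestSampleStep:
    def test_closed_form(self):
        assert sample_step(100.0, math.exp(-1.0)) == pytest.approx(0.01)

    def test_ballistic_for_nonpositive_mu(self):
        assert sample_step(0.0, 0.5) == math.inf
        assert sample_step(-1.0, 0.5) == math.inf

    def test_short_step_limit(self):
        assert sample_step(100.0, 1.0 - 1e-12) == pytest.approx(0.0, abs=1e-12)

    def test_mean_free_path(self, rng):
        u = rng.random(1_000_000)
        lengths = -np.log(u) / 50.0
        # exponential: mean 1/mu, sd 1/mu
        assert abs(lengths.mean() - 0.02) < 3 * 0.02 / math.sqrt(len(u))


class TestHenyeyGreenstein:
    def test_isotropic_closed_form(self):
        assert sample_hg_cos(0.0, 0.75) == pytest.approx(0.5)

    def test_mean_cosine_equals_g(self, rng):
        u = rng.random(1_000_000)
        draws = sample_hg_cos(0.9, u)
        sd = draws.std(ddof=1) / math.sqrt(len(u))
        assert abs(draws.mean() - 0.9) < 3 * sd

    def test_forward_peaked_tail_fraction(self, rng):
        # closed-form CDF: P(cos > c) = 1 - u(c) with
        # u(c) = ((1-g^2)/sqrt(1+g^2-2 g c) - (1-g)) / (2 g)
        g, c = 0.98, 0.8
        u_c = ((1 - g * g) / math.sqrt(1 + g * g - 2 * g * c) - (1 - g)) / (2 * g)
        p_exact = 1.0 - u_c
        draws = sample_hg_cos(g, rng.random(200_000))
        p_hat = float(np.mean(draws > c))
        sigma = math.sqrt(p_exact * (1 - p_exact) / 200_000)
        assert abs(p_hat - p_exact) < 4 * sigma
        assert p_exact == pytest.approx(0.97795, abs=1e-4)

    @given(st.floats(min_value=-1.0, max_value=1.0),
           st.floats(min_value=1e-9, max_value=1.0 - 1e-9))
    def test_in_range(self, g, u):
        assert -1.0 <= float(sample_hg_cos(g, u)) <= 1.0


class TestFresnel:
    def test_normal_incidence_air_water(self):
        expect = ((1.0 - 1.33) / (1.0 + 1.33)) ** 2
        assert fresnel_reflectance(1.0, 1.33, 1.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.02006, abs=1e-5)

    def test_matched_media(self):
        assert fresnel_reflectance(1.38, 1.38, 0.5) == 0.0

    def test_total_internal_reflection(self):
        # mesoglea (1.45) -> water (1.33), beyond the critical angle
        cos_crit = math.sqrt(1.0 - (1.33 / 1.45) ** 2)
        assert fresnel_reflectance(1.45, 1.33, 0.5 * cos_crit) == 1.0

    @given(st.floats(min_value=1.0, max_value=2.0),
           st.floats(min_value=1.0, max_value=2.0),
           st.floats(min_value=1e-6, max_value=1.0))
    def test_bounded(self, n1, n2, cosi):
        assert 0.0 <= fresnel_reflectance(n1, n2, cosi) <= 1.0


class TestTransport:
    def test_unattenuated_collimated_beam(self):
        """Matched-index, non-scattering, non-absorbing slab: fluence is 1."""
        stack, domain = uniform_optics_stack()
        light = run_photon_mc(stack, domain, n_photons=200, seed=3)
        np.testing.assert_allclose(light.normalized_fluence, 1.0, rtol=1e-12)
        assert light.tallies["transmitted"] == pytest.approx(200.0)

    def test_beer_lambert_multilayer(self):
        """Absorbing, non-scattering, matched-index layers follow the product
        of exponentials; continuous absorption makes the tally zero-variance."""
        stack, domain = baseline_stack()
        stack = [lay.model_copy(update={
            "optical": lay.optical.model_copy(update={
                "mu_s_per_cm": 0.0, "g": 0.0, "n": 1.0})
        }) for lay in stack]
        grid = build_grid(stack, domain)
        light = run_photon_mc(stack, domain, n_photons=100, seed=5, grid=grid)
        mu_a = grid.cell_prop("mu_a_per_m")
        tau_edges = np.concatenate([[0.0], np.cumsum(mu_a * grid.dz)])
        with np.errstate(divide="ignore", invalid="ignore"):
            expect = np.where(
                mu_a > 0,
                (np.exp(-tau_edges[:-1]) - np.exp(-tau_edges[1:])) / (mu_a * grid.dz),
                np.exp(-tau_edges[:-1]),
            )
        np.testing.assert_allclose(light.normalized_fluence, expect, rtol=1e-9)

    def test_weight_conservation_and_determinism(self, baseline):
        stack, domain = baseline
        a = run_photon_mc(stack, domain, n_photons=30_000, seed=42)
        b = run_photon_mc(stack, domain, n_photons=30_000, seed=42)
        assert a.conservation_residual < 1e-6
        assert np.array_equal(a.normalized_fluence, b.normalized_fluence)
        assert a.tallies == b.tallies
        c = run_photon_mc(stack, domain, n_photons=30_000, seed=43)
        assert not np.array_equal(a.normalized_fluence, c.normalized_fluence)

    def test_surface_enhancement_and_attenuation(self, baseline):
        """Scattering and index mismatches enhance scalar irradiance above 1
        at the tissue surface; the gastrodermis strongly attenuates it."""
        stack, domain = baseline
        light = run_photon_mc(stack, domain, n_photons=100_000, seed=9)
        grid = build_grid(stack, domain)
        surf = grid.tissue_surface_m
        near_surface = np.abs(light.z_centers_m - surf) < 0.1e-3
        assert light.normalized_fluence[near_surface].max() > 1.0
        below_og = grid.mask("gastric_cavity")
        assert (light.normalized_fluence[below_og].mean()
                < 0.3 * light.normalized_fluence[near_surface].max())

    def test_isotropic_nonabsorbing_fluence_exceeds_unity(self):
        """Backscatter in a thick isotropically scattering medium raises the
        near-surface fluence above the incident irradiance."""
        stack, domain = uniform_optics_stack(mu_a_per_cm=0.0, mu_s_per_cm=50.0,
                                             g=0.0, n=1.0)
        light = run_photon_mc(stack, domain, n_photons=20_000, seed=13)
        assert light.normalized_fluence[:50].max() > 1.0
        assert light.conservation_residual < 1e-9

    def test_variance_scales_inversely_with_photons(self, baseline):
        stack, domain = baseline
        grid = build_grid(stack, domain)
        surf_cell = int(np.argmax(grid.mask("mucus")))

        def surface_estimates(n, seeds):
            return [run_photon_mc(stack, domain, n_photons=n, seed=s,
                                  grid=grid).normalized_fluence[surf_cell]
                    for s in seeds]

        lo = np.var(surface_estimates(1_000, range(100, 120)), ddof=1)
        hi = np.var(surface_estimates(10_000, range(200, 220)), ddof=1)
        ratio = lo / hi
        assert 4.0 < ratio < 25.0   # 10x photons -> ~10x lower variance


class TestSmoothingAndSlicing:
    def _uniform_field(self, baseline, value=2.0):
        stack, domain = baseline
        light = run_photon_mc(stack, domain, n_photons=100, seed=1)
        for name in ("normalized_fluence", "fluence_umol_m2_s",
                     "absorbed_photons_mol_m3_s", "absorbed_power_W_m3"):
            getattr(light, name)[:] = value
        return light

    def test_uniform_field_unchanged(self, baseline):
        light = self._uniform_field(baseline)
        out = smooth_light_field(light, kernel_width_m=30e-6)
        np.testing.assert_allclose(out.absorbed_power_W_m3, 2.0, rtol=1e-12)

    def test_delta_spike_spread_conservatively(self, baseline):
        light = self._uniform_field(baseline, value=0.0)
        grid_dz = np.diff(light.z_edges_m)
        spike = 250  # inside the water layer
        light.absorbed_power_W_m3[spike] = 1.0 / grid_dz[spike]
        total = np.sum(light.absorbed_power_W_m3 * grid_dz)
        out = smooth_light_field(light, kernel_width_m=40e-6)
        assert out.absorbed_power_W_m3.max() < light.absorbed_power_W_m3.max()
        assert np.count_nonzero(out.absorbed_power_W_m3 > 0) > 3
        total_out = np.sum(out.absorbed_power_W_m3 * grid_dz)
        assert abs(total_out - total) / total < 1e-9

    def test_mid_slice(self):
        field3d = np.ones((10, 4, 5)) * np.arange(10)[:, None, None]
        np.testing.assert_array_equal(mid_slice(field3d), field3d[:, :, 2])
        field1d = np.arange(7.0)
        np.testing.assert_array_equal(mid_slice(field1d), field1d)

    def test_conservative_resampling(self, baseline):
        stack, domain = baseline
        fine = build_grid(stack, domain, dz=10e-6)
        coarse = build_grid(stack, domain, dz=20e-6)
        light = run_photon_mc(stack, domain, n_photons=20_000, seed=2, grid=fine)
        out = resample_light_field(light, coarse)
        a = np.sum(light.absorbed_power_W_m3 * fine.dz)
        b = np.sum(out.absorbed_power_W_m3 * coarse.dz)
        assert abs(a - b) <= 1e-12 * max(a, 1e-300)
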
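"""Transport kernel: elementary physics, conservation, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skindpf import (
    RunConfig,
    build_default_model,
    default_ring_edges,
    fresnel_reflectance,
    launch_weight,
    replicate_seed,
    run_transport,
    sample_free_path,
    sample_scatter_direction,
    specular_reflectance,
)
from skindpf.oracles import hg_mean_cos

from conftest import make_homogeneous


class TestFreePath:
    def test_u_equals_one_gives_zero(self):
        assert sample_free_path(5.0, 1.0) == 0.0

    def test_closed_form(self):
        assert sample_free_path(2.0, math.exp(-1.0)) == pytest.approx(0.5)

    def test_sample_mean_matches_exponential(self):
        rng = np.random.default_rng(42)
        mu = 22.33  # a study-grid scattering coefficient
        n = 1_000_000
        samples = sample_free_path(mu, 1.0 - rng.random(n))
        se = samples.std(ddof=1) / math.sqrt(n)
        assert abs(samples.mean() - 1.0 / mu) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_free_path(0.0, 0.5)
        with pytest.raises(ValueError):
            sample_free_path(1.0, 0.0)


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_cos_theta_matches_quadrature(self, g):
        """Sampled ⟨cosθ⟩ equals the HG first moment (= g) within 3 SE."""
        rng = np.random.default_rng(7)
        n = 400_000
        dirs = sample_scatter_direction(
            g, rng.random(n), rng.random(n), np.tile([0.0, 0.0, 1.0], (n, 1))
        )
        cost = dirs[:, 2]
        se = cost.std(ddof=1) / math.sqrt(n)
        target = hg_mean_cos(g)
        assert target == pytest.approx(g, abs=1e-9)
        assert abs(cost.mean() - target) < 3 * se

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        g=st.floats(-0.95, 0.95),
        u1=st.floats(0.0, 1.0, exclude_max=True),
        u2=st.floats(0.0, 1.0, exclude_max=True),
        inc=st.tuples(
            st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
        ).filter(lambda v: 1e-3 < math.hypot(*v)),
    )
    def test_output_is_unit_vector(self, g, u1, u2, inc):
        v = np.asarray(inc) / np.linalg.norm(inc)
        out = sample_scatter_direction(g, u1, u2, v)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_anisotropy(self):
        with pytest.raises(ValueError):
            sample_scatter_direction(1.0, 0.5, 0.5, [0, 0, 1])


class TestBoundaries:
    def test_matched_interface_transmits(self):
        assert fresnel_reflectance(0.7, 1.4, 1.4) == 0.0

    def test_normal_incidence_closed_form(self):
        expected = ((1.37 - 1.0) / (1.37 + 1.0)) ** 2
        assert fresnel_reflectance(1.0, 1.37, 1.0) == pytest.approx(expected)
        assert specular_reflectance(1.0, 1.37) == pytest.approx(expected)

    def test_total_internal_reflection(self):
        critical = math.asin(1.0 / 1.37)
        cos_beyond = math.cos(critical + 0.05)
        assert fresnel_reflectance(cos_beyond, 1.37, 1.0) == 1.0

    def test_launch_weight(self):
        assert launch_weight(1.0, 1.0) == pytest.approx(1.0)
        assert launch_weight(1.0, 1.37) == pytest.approx(1.0 - 0.024372874717370804)


class TestRunTransport:
    def test_energy_conservation(self, model_2pct):
        cfg = RunConfig(n_photons=20_000, seed=5, wavelength=650.0)
        ledger = run_transport(model_2pct, cfg)
        assert ledger.conservation_residual() < 1e-6

    def test_energy_conservation_scatterpath(self, model_2pct):
        cfg = RunConfig(
            n_photons=20_000, seed=5, wavelength=1050.0,
            step_sampling_mode="scattering", roulette_threshold=0.0,
        )
        ledger = run_transport(model_2pct, cfg)
        assert ledger.conservation_residual() < 1e-6

    def test_same_seed_bit_identical(self, model_2pct):
        cfg = RunConfig(n_photons=5_000, seed=123, wavelength=850.0)
        a = run_transport(model_2pct, cfg)
        b = run_transport(model_2pct, cfg)
        assert np.array_equal(a.detected_weight, b.detected_weight)
        assert np.array_equal(a.n_detected, b.n_detected)
        assert np.array_equal(a.sum_weighted_path_by_layer, b.sum_weighted_path_by_layer)
        assert a.absorbed_weight == b.absorbed_weight

    def test_different_seeds_differ(self, model_2pct):
        a = run_transport(model_2pct, RunConfig(n_photons=5_000, seed=1, wavelength=850.0))
        b = run_transport(model_2pct, RunConfig(n_photons=5_000, seed=2, wavelength=850.0))
        assert not np.array_equal(a.n_detected, b.n_detected)

    def test_specular_weight_recorded(self, model_2pct):
        cfg = RunConfig(n_photons=2_000, seed=1, wavelength=850.0)
        ledger = run_transport(model_2pct, cfg)
        r_sp = specular_reflectance(1.0, 1.37)
        assert ledger.specular_weight == pytest.approx(2_000 * r_sp, rel=1e-9)

    def test_matched_boundaries_have_no_specular(self, model_2pct):
        cfg = RunConfig(
            n_photons=2_000, seed=1, wavelength=850.0, matched_boundaries=True
        )
        ledger = run_transport(model_2pct, cfg)
        assert ledger.specular_weight == 0.0

    def test_nonscattering_slab_beer_lambert(self):
        """Transmitted unscattered weight through a pure absorber = exp(−μa L)."""
        mua, thick = 10.0, 0.2
        model = make_homogeneous(mua=mua, mus=1e-6, g=0.0, n=1.0, thickness=thick)
        cfg = RunConfig(
            n_photons=100_000, seed=9, wavelength=850.0,
            matched_boundaries=True, roulette_threshold=0.0,
        )
        ledger = run_transport(model, cfg)
        expected = math.exp(-mua * thick)
        observed = ledger.transmitted_weight / ledger.launched
        se = math.sqrt(expected * (1 - expected) / ledger.launched)
        assert abs(observed - expected) < 3 * se + 1e-4

    def test_conservative_scatterer_reflects_everything(self):
        """μa→0 semi-infinite scatterer with matched boundaries returns ~all weight."""
        model = make_homogeneous(mua=1e-9, mus=10.0, g=0.9, n=1.0, thickness=1e6)
        cfg = RunConfig(
            n_photons=3_000, seed=4, wavelength=850.0,
            matched_boundaries=True, extend_bottom=True, max_path=1e7,
            roulette_threshold=0.0,
        )
        ledger = run_transport(model, cfg)
        assert ledger.reflected_weight / ledger.launched > 0.99

    def test_per_layer_paths_sum_to_total(self, model_2pct):
        cfg = RunConfig(n_photons=20_000, seed=3, wavelength=650.0)
        ledger = run_transport(model_2pct, cfg)
        total_by_layer = ledger.sum_weighted_path_by_layer.sum(axis=1)
        assert total_by_layer == pytest.approx(ledger.sum_weighted_path, rel=1e-9)
        unweighted = ledger.sum_path_by_layer.sum(axis=1)
        assert unweighted == pytest.approx(ledger.sum_path, rel=1e-9)

    def test_detected_paths_bounded_below_by_exit_radius(self, model_2pct):
        cfg = RunConfig(n_photons=50_000, seed=8, wavelength=850.0)
        ledger = run_transport(model_2pct, cfg)
        centers = ledger.ring_centers()
        for k in range(ledger.n_rings):
            if ledger.n_detected[k] > 0:
                # mean path cannot be shorter than the inner ring radius
                assert ledger.mean_path(k) >= ledger.ring_edges[k]
                assert ledger.mean_path(k) / centers[k] > 1.0

    def test_zero_photons_rejected(self, model_2pct):
        with pytest.raises(ValueError):
            RunConfig(n_photons=0)

    def test_replicate_seeds_independent_and_reproducible(self):
        s1 = replicate_seed(7, 0)
        s2 = replicate_seed(7, 1)
        assert s1 != s2
        assert s1 == replicate_seed(7, 0)
        assert 0 <= s1 < 2**31

    def test_ring_edges_validation(self):
        with pytest.raises(ValueError):
            default_ring_edges(np.array([1.0, 0.5]))


class TestRoulette:
    def test_expected_weight_conserved(self, model_2pct):
        """roulette_net (kills − boosts) has mean ~0 over a large run."""
        cfg = RunConfig(n_photons=200_000, seed=11, wavelength=450.0)
        ledger = run_transport(model_2pct, cfg)
        # net roulette flow is a tiny fraction of the absorbed weight
        assert abs(ledger.roulette_net) < 0.01 * ledger.absorbed_weight

    def test_disabled_roulette_has_zero_net(self, model_2pct):
        cfg = RunConfig(
            n_photons=5_000, seed=11, wavelength=850.0, roulette_threshold=0.0
        )
        ledger = run_transport(model_2pct, cfg)
        assert ledger.roulette_net == 0.0
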
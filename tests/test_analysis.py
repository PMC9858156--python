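"""DPF estimation, replicate statistics, Beer–Lambert utility, sensitivity maps."""

import math

import numpy as np
import pytest

from skindpf import (
    DetectionLedger,
    InsufficientStatisticsError,
    RunConfig,
    dpf_from_ledger,
    mbll_attenuation,
    penetration_depth,
    replicate_sweep,
    sensitivity_map,
)


def synthetic_ledger(ring_edges, packets):
    """Ledger filled by hand: packets = [(ring, weight, path), ...]."""
    ledger = DetectionLedger(ring_edges=np.asarray(ring_edges, float), n_layers=1)
    for ring, w, path in packets:
        ledger.detected_weight[ring] += w
        ledger.n_detected[ring] += 1
        ledger.sum_weighted_path[ring] += w * path
        ledger.sum_path[ring] += path
        ledger.sum_weighted_path_by_layer[ring, 0] += w * path
        ledger.sum_path_by_layer[ring, 0] += path
    return ledger


class TestDpfFromLedger:
    def test_single_packet(self):
        ledger = synthetic_ledger([1.75, 2.25], [(0, 1.0, 10.0)])
        assert dpf_from_ledger(ledger, 2.0) == pytest.approx(5.0)

    def test_weighted_mean_of_two_packets(self):
        ledger = synthetic_ledger([1.75, 2.25], [(0, 1.0, 4.0), (0, 1.0, 6.0)])
        assert dpf_from_ledger(ledger, 2.0) == pytest.approx(2.5)

    def test_weights_shift_the_weighted_estimator_only(self):
        ledger = synthetic_ledger([1.75, 2.25], [(0, 3.0, 4.0), (0, 1.0, 6.0)])
        assert dpf_from_ledger(ledger, 2.0) == pytest.approx((3 * 4 + 6) / 4 / 2)
        assert dpf_from_ledger(ledger, 2.0, weighted=False) == pytest.approx(2.5)

    def test_empty_ring_raises_insufficient_statistics(self):
        ledger = synthetic_ledger([1.75, 2.25, 2.75], [(0, 1.0, 4.0)])
        with pytest.raises(InsufficientStatisticsError):
            dpf_from_ledger(ledger, 2.5)

    def test_sds_outside_rings_rejected(self):
        ledger = synthetic_ledger([1.75, 2.25], [(0, 1.0, 4.0)])
        with pytest.raises(ValueError):
            dpf_from_ledger(ledger, 5.0)


class TestMbll:
    def test_product_form(self):
        assert mbll_attenuation(1.0, 1.0, 2.0, 5.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("zeroed", range(4))
    def test_any_zero_factor_gives_zero(self, zeroed):
        args = [1.2, 3.4, 5.6, 7.8]
        args[zeroed] = 0.0
        assert mbll_attenuation(*args) == 0.0

    def test_linear_in_dpf(self):
        assert mbll_attenuation(0.5, 2.0, 3.0, 8.0) == pytest.approx(
            2 * mbll_attenuation(0.5, 2.0, 3.0, 4.0)
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            mbll_attenuation(-1.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def small_grid(model_2pct):
    return replicate_sweep(
        model_2pct, [650.0, 850.0], [1.0, 2.0, 3.0],
        n_photons=20_000, n_replicates=3, base_seed=5,
    )


@pytest.fixture(scope="module")
def maps(model_2pct):
    out = {}
    for sds, seed in ((2.0, 41), (6.0, 42)):
        cfg = RunConfig(n_photons=120_000, seed=seed, wavelength=1050.0)
        out[sds] = sensitivity_map(model_2pct, cfg, sds)
    return out


class TestReplicateSweep:

    def test_shapes_and_replicates(self, small_grid):
        assert small_grid.dpf_mean.shape == (2, 3)
        assert small_grid.dpf_sd.shape == (2, 3)
        assert small_grid.mean_path_by_layer.shape == (2, 3, 7)
        assert small_grid.n_replicates == 3
        assert small_grid.sd_valid

    def test_dpf_at_least_one_everywhere(self, small_grid):
        assert np.all(small_grid.dpf_mean >= 1.0)
        assert np.all(small_grid.dpf_sd >= 0.0)

    def test_per_layer_decomposition_matches_total(self, small_grid):
        totals = small_grid.total_mean_path()
        assert small_grid.mean_path_by_layer.sum(axis=2) == pytest.approx(
            totals, rel=1e-9
        )

    def test_single_replicate_sd_flagged(self, model_2pct):
        grid = replicate_sweep(
            model_2pct, [850.0], [1.0], n_photons=5_000, n_replicates=1, base_seed=1
        )
        assert not grid.sd_valid
        assert np.all(grid.dpf_sd == 0.0)

    def test_empty_ring_error_carries_context(self, model_2pct):
        # 10 photons cannot populate an 8 mm ring
        with pytest.raises(InsufficientStatisticsError, match="sds 8"):
            replicate_sweep(
                model_2pct, [850.0], [8.0], n_photons=10, n_replicates=1, base_seed=1
            )

    def test_sd_shrinks_with_photon_budget(self, model_2pct):
        """Replicate SD scales roughly like 1/√n_photons."""
        kwargs = dict(n_replicates=6, base_seed=9)
        coarse = replicate_sweep(
            model_2pct, [850.0], [2.0], n_photons=5_000, **kwargs
        )
        fine = replicate_sweep(
            model_2pct, [850.0], [2.0], n_photons=80_000, **kwargs
        )
        ratio = coarse.dpf_sd[0, 0] / fine.dpf_sd[0, 0]
        # expected √16 = 4; wide band for 6-replicate noise
        assert 1.5 < ratio < 12.0

    def test_grid_lookup(self, small_grid):
        assert small_grid.dpf(850.0, 2.0) == small_grid.dpf_mean[1, 1]
        with pytest.raises(ValueError):
            small_grid.dpf(700.0, 2.0)


class TestWriters:
    def test_wide_table_shape_and_round_trip(self, tmp_path, model_2pct):
        import pandas as pd

        from skindpf import write_dpf_long, write_dpf_table, write_layer_paths

        grid = replicate_sweep(
            model_2pct, [650.0, 850.0], [1.0, 2.0], n_photons=10_000,
            n_replicates=2, base_seed=3,
        )
        wide = tmp_path / "dpf.csv"
        write_dpf_table(grid, wide)
        df = pd.read_csv(wide, index_col=0)
        assert list(df.columns) == ["DPF650nm", "DPF850nm"]
        assert df.shape == (2, 2)
        assert df.to_numpy() == pytest.approx(grid.dpf_mean.T)

        long = tmp_path / "long.csv"
        write_dpf_long(grid, long)
        df_long = pd.read_csv(long)
        assert len(df_long) == 4
        assert set(df_long.columns) >= {"wavelength_nm", "sds_mm", "dpf_mean", "dpf_sd"}

        layers = tmp_path / "layers.csv"
        write_layer_paths(grid, layers)
        df_layers = pd.read_csv(layers)
        assert len(df_layers) == 2 * 2 * 7


class TestSensitivityMap:
    def test_normalized_and_nonnegative(self, maps):
        grid, _, _ = maps[2.0]
        assert np.all(grid >= 0)
        assert grid.sum() == pytest.approx(1.0)

    def test_larger_separation_probes_deeper(self, maps):
        g2, _, z2 = maps[2.0]
        g6, _, z6 = maps[6.0]
        assert penetration_depth(g6, z6) > penetration_depth(g2, z2)

    def test_reaches_deep_blood_net_dermis_at_6mm(self, maps, model_2pct):
        """At 1050 nm / 6 mm the sensitive region extends below 0.65 mm depth."""
        g6, _, z6 = maps[6.0]
        centers = 0.5 * (z6[:-1] + z6[1:])
        deep = g6.sum(axis=0)[centers > 0.65].sum()
        assert deep > 0.05

    def test_no_detection_raises(self, model_2pct):
        cfg = RunConfig(n_photons=50, seed=1, wavelength=1050.0)
        with pytest.raises(InsufficientStatisticsError):
            sensitivity_map(model_2pct, cfg, 7.5)
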
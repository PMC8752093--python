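"""Trace generator: determinism, count statistics, degenerate inputs."""

import numpy as np
import pytest

import fcslab as f
from conftest import BIN, BOX_FACTOR, constant_trace


def tiny_config(volume, **overrides):
    kw = dict(volume=volume,
              species=(f.SpeciesSpec("s", D=15.0, concentration=5.0,
                                     brightness_G=20000.0),),
              duration=0.1, base_bin=1e-4, time_step=1e-4,
              box_factor=BOX_FACTOR, seed=42)
    kw.update(overrides)
    return f.SimulationConfig(**kw)


def block_se(values, n_blocks=10):
    blocks = np.array_split(np.asarray(values, dtype=float), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestSimulateTrace:
    def test_identical_seeds_give_identical_traces(self, volume):
        cfg = tiny_config(volume)
        t1, t2 = f.simulate_trace(cfg), f.simulate_trace(cfg)
        assert np.array_equal(t1.counts_G, t2.counts_G)
        assert np.array_equal(t1.counts_R, t2.counts_R)

    def test_different_seeds_differ(self, volume):
        t1 = f.simulate_trace(tiny_config(volume, seed=1))
        t2 = f.simulate_trace(tiny_config(volume, seed=2))
        assert not np.array_equal(t1.counts_G, t2.counts_G)

    def test_background_only_rate_and_flat_correlation(self, volume):
        cfg = f.SimulationConfig(volume=volume, species=(),
                                 background_G=1000.0, background_R=1000.0,
                                 duration=4.0, base_bin=5e-4, time_step=5e-4,
                                 box_factor=BOX_FACTOR, seed=5)
        trace = f.simulate_trace(cfg)
        for ch in "GR":
            rate = f.mean_count_rate(trace, ch)
            se = block_se(trace.counts(ch)) / cfg.base_bin
            assert abs(rate - 1000.0) < 3 * se
        curve = f.correlate_direct(trace, "GG", max_lag=0.025)
        # no lag grossly significant, and the pooled amplitude consistent
        # with zero (Poisson background bins are independent across lags)
        assert np.all(np.abs(curve.G) < 6 * curve.G_err)
        pooled_se = np.mean(curve.G_err) / np.sqrt(curve.G.size)
        assert abs(curve.G.mean()) < 4 * pooled_se

    def test_mean_rate_matches_analytic_expectation(
            self, single_species_trace, single_species_config):
        expected = f.expected_mean_rate(single_species_config, "G")
        rate = f.mean_count_rate(single_species_trace, "G")
        # SE from 1000-bin blocks: occupancy fluctuations are correlated
        # within tau_D but blocks of 20 ms are nearly independent
        coarse = single_species_trace.counts_G.reshape(-1, 1000).sum(1)
        se = block_se(coarse, 25) / (1000 * BIN) / np.sqrt(50 / 25)
        assert abs(rate - expected) < 4 * se + 0.01 * expected

    def test_bleached_trace_mean_matches_decay_average(self, volume):
        cfg = tiny_config(volume, duration=2.0, base_bin=1e-3, time_step=1e-3,
                          species=(f.SpeciesSpec(
                              "b", D=15.0, concentration=40.0,
                              brightness_G=40000.0, bleach_rate=0.5),))
        trace = f.simulate_trace(cfg)
        expected = f.expected_mean_rate(cfg, "G")
        assert abs(f.mean_count_rate(trace, "G") - expected) < 0.12 * expected

    def test_near_immobile_species_decays_negligibly(self, volume):
        # D = 0.01 um^2/s -> tau_D = 1.56 s; over lags <= 20 ms the model
        # predicts G(tau)/G(first lag) >= 0.98, so the measured curve must
        # stay within noise of flat
        cfg = f.SimulationConfig(
            volume=volume,
            species=(f.SpeciesSpec("slow", D=0.01, concentration=2.0,
                                   brightness_G=50000.0),),
            duration=40.0, base_bin=5e-4, time_step=5e-4,
            box_factor=BOX_FACTOR, seed=3)
        trace = f.simulate_trace(cfg)
        curve = f.correlate_direct(trace, "GG", max_lag=0.02)
        tau_D = volume.omega_xy**2 / (4 * 0.01)
        model_ratio = (f.model_3d_diffusion(curve.lags[-1], 1.0, tau_D, 5.0)
                       / f.model_3d_diffusion(curve.lags[0], 1.0, tau_D, 5.0))
        measured_ratio = curve.G[-1] / curve.G[0]
        err = (curve.G_err[-1] + curve.G_err[0]) / curve.G[0]
        assert model_ratio > 0.98
        assert abs(measured_ratio - model_ratio) < 3 * err

    @pytest.mark.parametrize("overrides", [
        dict(duration=-1.0),
        dict(base_bin=-1e-4),
        dict(base_bin=5e-5),            # smaller than time_step
        dict(base_bin=2.5e-4),          # not an integer multiple
        dict(box_factor=3.0),
        dict(species=(), background_G=0.0, background_R=0.0),
    ])
    def test_invalid_configs_rejected(self, volume, overrides):
        with pytest.raises(ValueError):
            tiny_config(volume, **overrides)


class TestMeanCountRate:
    def test_all_zero_trace(self):
        assert f.mean_count_rate(constant_trace(0), "G") == 0.0

    def test_constant_counts_arithmetic(self):
        trace = constant_trace(3, n_bins=1000, bin_width=1e-5)
        assert f.mean_count_rate(trace, "G") == pytest.approx(3e5)

    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            f.mean_count_rate(constant_trace(1), "B")


class TestCellScatterModel:
    def test_median_preserved_and_reproducible(self):
        rng = np.random.default_rng(7)
        x = f.sample_cell_values(17.3, 6.1, 5000, rng)
        assert np.median(x) == pytest.approx(17.3, rel=0.05)
        rng2 = np.random.default_rng(7)
        assert np.array_equal(x, f.sample_cell_values(17.3, 6.1, 5000, rng2))

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            f.sample_cell_values(-1.0, 1.0, 10, rng)
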
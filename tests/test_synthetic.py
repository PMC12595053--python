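"""Generator properties: determinism, planted structure, closed-form recovery."""

import numpy as np
import pytest

from ensotel.oni import MonthlyIndexSeries, classify_phases, running_mean3
from ensotel.synthetic import (
    SimulationConfig,
    default_scenario,
    generate_cube,
    generate_gpp_pair,
    generate_index,
    generate_masks,
)

SMALL = dict(n_months=48, grid_shape=(6, 6))


class TestGenerateIndex:
    def test_degenerate_noise_free_is_all_zero(self):
        cfg = SimulationConfig(**SMALL, ar1_coeff=0.0, index_noise_sd=0.0)
        s = generate_index(cfg)
        np.testing.assert_array_equal(s.values, 0.0)
        labels = classify_phases(running_mean3(s))
        assert set(labels.labels) == {"neutral"}

    def test_constant_offset_forces_warm_phase_everywhere(self):
        cfg = SimulationConfig(**SMALL, ar1_coeff=0.0, index_noise_sd=0.0)
        s = generate_index(cfg)
        shifted = MonthlyIndexSeries(start=s.start, values=s.values + 1.0)
        labels = classify_phases(running_mean3(shifted))
        assert set(labels.labels) == {"elnino"}

    def test_threshold_count_matches_oracle_resimulation(self):
        cfg = SimulationConfig(n_months=348, grid_shape=(2, 2), seed=7,
                               ar1_coeff=0.8, index_noise_sd=0.3)
        s = generate_index(cfg)
        # independent re-simulation with the same substream definition
        rng = np.random.default_rng(np.random.SeedSequence([7, 0]))
        eps = rng.normal(0.0, 0.3, 348)
        x = np.empty(348)
        x[0] = eps[0]
        for t in range(1, 348):
            x[t] = 0.8 * x[t - 1] + eps[t]
        x -= x.mean()
        assert (np.abs(s.values) >= 0.5).sum() == (np.abs(x) >= 0.5).sum()
        np.testing.assert_allclose(s.values, x)

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(**SMALL, seed=11)
        a, b = generate_index(cfg), generate_index(cfg)
        assert np.array_equal(a.values, b.values)

    def test_recentered_realization_has_zero_mean(self):
        s = generate_index(SimulationConfig(n_months=348, grid_shape=(2, 2)))
        assert abs(s.values.mean()) < 1e-12

    @pytest.mark.parametrize("bad", [dict(ar1_coeff=1.0),
                                     dict(index_noise_sd=-0.1),
                                     dict(ar1_coeff=np.nan),
                                     dict(n_months=12)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**{**SMALL, **bad})


class TestGenerateCube:
    def test_zero_beta_noise_free_is_pure_climatology(self):
        cfg = SimulationConfig(**SMALL, noise_sd=0.0, trend_slope=0.0)
        idx = generate_index(cfg)
        cube, truth = generate_cube(cfg, idx, "t")
        clim = cfg.climatology_table()
        months = (np.arange(48)) % 12
        expected = np.broadcast_to(clim[months][:, None, None], cube.shape)
        np.testing.assert_allclose(cube.values, expected)
        assert not truth.signal_mask.any()

    def test_single_pixel_beta_gives_exact_proportionality(self):
        beta = np.zeros((6, 6))
        beta[2, 3] = 2.0
        cfg = SimulationConfig(**SMALL, beta_field=beta, noise_sd=0.0,
                               seasonal_amplitude=0.0)
        idx = generate_index(cfg)
        cube, truth = generate_cube(cfg, idx, "t")
        np.testing.assert_allclose(cube.values[:, 2, 3], 2.0 * idx.values)
        np.testing.assert_array_equal(cube.values[:, 0, 0], 0.0)
        assert truth.signal_mask.sum() == 1

    def test_lagged_pixel_follows_index_after_lag(self):
        lag = np.full((6, 6), 2)
        cfg = SimulationConfig(**SMALL, beta_field=1.0, lag_field=lag,
                               noise_sd=0.0, seasonal_amplitude=0.0)
        idx = generate_index(cfg)
        cube, _ = generate_cube(cfg, idx, "t")
        np.testing.assert_allclose(cube.values[2:, 0, 0], idx.values[:-2])
        np.testing.assert_array_equal(cube.values[:2, 0, 0], 0.0)

    def test_shape_mismatch_rejected(self):
        cfg = SimulationConfig(**SMALL)
        idx = generate_index(cfg)
        with pytest.raises(ValueError):
            generate_cube(
                SimulationConfig(**SMALL, beta_field=np.ones((3, 3))), idx, "t")
        short = MonthlyIndexSeries(start=(1992, 1), values=np.zeros(12))
        with pytest.raises(ValueError, match="n_months"):
            generate_cube(cfg, short, "t")

    def test_same_seed_bit_identical_cubes(self):
        cfg = SimulationConfig(**SMALL, beta_field=1.0, seed=3)
        idx = generate_index(cfg)
        a, _ = generate_cube(cfg, idx, "t")
        b, _ = generate_cube(cfg, idx, "t")
        assert np.array_equal(a.values, b.values)

    def test_adding_a_variable_does_not_perturb_existing_one(self):
        cfg = SimulationConfig(**SMALL, beta_field=1.0, seed=3)
        idx = generate_index(cfg)
        a, _ = generate_cube(cfg, idx, "tmax")
        _ = generate_cube(cfg, idx, "newvar")
        b, _ = generate_cube(cfg, idx, "tmax")
        assert np.array_equal(a.values, b.values)

    def test_empirical_r_matches_closed_form_linear_noise_model(self):
        """corr(index, beta*index + noise) -> beta*s_x / sqrt(beta^2 s_x^2 + s_n^2)."""
        beta = np.zeros((20, 40))
        beta[:, :20] = np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        cfg = SimulationConfig(n_months=348, grid_shape=(20, 40),
                               beta_field=beta, noise_sd=0.5,
                               seasonal_amplitude=0.0, seed=13)
        idx = generate_index(cfg)
        cube, truth = generate_cube(cfg, idx, "t")
        x = idx.values
        sx = x.std(ddof=0)
        theory = beta * sx / np.sqrt(beta**2 * sx**2 + 0.5**2)
        xc = x - x.mean()
        data = cube.values - cube.values.mean(axis=0)
        num = np.einsum("t,tij->ij", xc, data)
        den = np.sqrt((xc**2).sum() * (data**2).sum(axis=0))
        r_hat = num / den
        z_err = np.abs(np.arctanh(r_hat) - np.arctanh(theory))
        within = z_err <= 3.0 / np.sqrt(348 - 3)
        assert within[truth.signal_mask].mean() >= 0.95


class TestGppPairAndMasks:
    def test_pair_has_independent_beta_fields(self):
        cfg_sun = SimulationConfig(**SMALL, beta_field=-1.0)
        cfg_shade = SimulationConfig(**SMALL, beta_field=0.0)
        idx = generate_index(cfg_sun)
        (sun, t_sun), (shade, t_shade) = generate_gpp_pair(cfg_sun, cfg_shade, idx)
        assert t_sun.signal_mask.all() and not t_shade.signal_mask.any()
        assert sun.attrs["variable"] == "gpp_sun"

    def test_mismatched_pair_rejected(self):
        idx = generate_index(SimulationConfig(**SMALL))
        with pytest.raises(ValueError):
            generate_gpp_pair(SimulationConfig(**SMALL),
                              SimulationConfig(n_months=48, grid_shape=(4, 4)),
                              idx)

    def test_masks_deterministic_and_bounded(self):
        s1, l1 = generate_masks((8, 8), 0.5, 0.1, 4, seed=5)
        s2, l2 = generate_masks((8, 8), 0.5, 0.1, 4, seed=5)
        assert np.array_equal(s1, s2) and np.array_equal(l1, l2)
        assert l1.shape == (32, 32)
        assert set(np.unique(l1)) <= {0, 1}

    def test_degenerate_fractions(self):
        suit, loss = generate_masks((5, 5), 1.0, 0.0, 2, seed=0)
        assert suit.all()
        assert not loss.any()

    def test_invalid_mask_parameters(self):
        with pytest.raises(ValueError):
            generate_masks((5, 5), 1.5, 0.0, 2, seed=0)
        with pytest.raises(ValueError):
            generate_masks((5, 5), 0.5, 0.0, 0, seed=0)


def test_default_scenario_is_reproducible_and_complete():
    a = default_scenario(seed=2, n_months=60, grid_shape=(8, 8))
    b = default_scenario(seed=2, n_months=60, grid_shape=(8, 8))
    assert set(a["climate"]) == {"tmax", "tmin", "vpd", "pr", "soil", "pdsi"}
    assert np.array_equal(a["index"].values, b["index"].values)
    for name in a["climate"]:
        assert np.array_equal(a["climate"][name][0].values,
                              b["climate"][name][0].values)
    assert a["gpp_shade"][1].lag_field.max() == 1
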
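"""The synthetic landscape generator: closed-form oracles, sampling
bounds, label consistency and determinism."""

import numpy as np
import pytest

from mcfmap.climatology import FOG, INVALID
from mcfmap.raster import RasterGrid
from mcfmap.synthetic import (
    BandSpectra,
    ConfigurationError,
    FogParams,
    LandscapeConfig,
    Massif,
    McfRule,
    SimulationError,
    generate_dem,
    generate_fog_probability,
    generate_labels_and_plots,
    generate_reflectance,
    generate_world,
    isolation_score,
    simulate_fog_masks,
    windwardness,
)
from mcfmap.texture import texture_raster
from tests.conftest import small_landscape_config


def tiny_config(**overrides) -> LandscapeConfig:
    defaults = dict(
        grid_rows=24,
        grid_cols=24,
        cell_size_m=30.0,
        coarse_factor=8,
        n_scenes=12,
        n_plots=40,
        n_forest_points=20,
        min_plots_per_stratum=1,
        seed=3,
        relief=[Massif((360.0, 360.0), 3000.0, 200.0)],
        fog_params=FogParams(isolation_radius_m=300.0, isolation_norm_m=500.0),
    )
    defaults.update(overrides)
    return LandscapeConfig(**defaults)


class TestDem:
    def test_single_massif_peak_height(self):
        cfg = tiny_config(base_min_m=0.0, base_max_m=0.0,
                          relief=[Massif((375.0, 375.0), 3000.0, 150.0)])
        dem = generate_dem(cfg)
        r, c = dem.cell_at(375.0, 375.0)
        assert dem.data[r, c] == pytest.approx(3000.0, rel=0.01)
        assert dem.data.min() >= 0.0

    def test_flat_world_without_relief_is_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dem(tiny_config(relief=[]))

    def test_nonpositive_massif_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dem(tiny_config(relief=[Massif((100.0, 100.0), -5.0, 100.0)]))
        with pytest.raises(ConfigurationError):
            generate_dem(tiny_config(relief=[Massif((100.0, 100.0), 100.0, 0.0)]))

    def test_overlapping_massifs_match_closed_form_oracle(self):
        cfg = tiny_config(
            base_min_m=10.0,
            base_max_m=100.0,
            relief=[Massif((200.0, 300.0), 1000.0, 150.0),
                    Massif((400.0, 350.0), 700.0, 120.0)],
        )
        dem = generate_dem(cfg)
        width = cfg.grid_cols * cfg.cell_size_m
        height = cfg.grid_rows * cfg.cell_size_m
        for r in range(0, 24, 5):
            for c in range(0, 24, 5):
                x = (c + 0.5) * 30.0
                y = height - (r + 0.5) * 30.0
                expected = 10.0 + 90.0 * x / width
                for m in cfg.relief:
                    cx, cy = m.center_xy
                    expected += m.height_m * np.exp(
                        -((x - cx) ** 2 + (y - cy) ** 2) / (2 * m.radius_m**2)
                    )
                assert dem.data[r, c] == pytest.approx(expected, abs=1e-9)


class TestFogProbability:
    def test_peak_at_bell_center_on_flat_lee_terrain(self):
        # terrain plateau at the bell center altitude: flat => windwardness 0
        cfg = tiny_config()
        fp = cfg.fog_params
        dem = RasterGrid(data=np.full((24, 24), fp.center_altitude_m),
                         cell_size=30.0, origin=(0.0, 720.0))
        grids = generate_fog_probability(dem, cfg)
        january = grids[0]
        assert january.data[12, 12] == pytest.approx(fp.base_rate + fp.peak_winter)

    def test_windward_exceeds_leeward_at_low_altitude_in_winter(self):
        cfg = tiny_config(relief=[Massif((360.0, 360.0), 2000.0, 150.0)])
        dem = generate_dem(cfg)
        w = windwardness(dem, cfg.windward_azimuth_deg)
        grids = generate_fog_probability(dem, cfg)
        january = grids[0].data
        alt = dem.data
        low = (alt > 800) & (alt < 1200)
        wind = low & (w > 0.6)
        lee = low & (w < 0.05)
        assert wind.any() and lee.any()
        assert january[wind].mean() > january[lee].mean()

    def test_summer_flatter_and_weaker_than_winter(self):
        cfg = tiny_config()
        dem = generate_dem(cfg)
        grids = generate_fog_probability(dem, cfg)
        january, july = grids[0].data, grids[6].data
        assert july.max() < january.max()

    def test_matches_independent_closed_form_loop(self):
        """Re-evaluate the documented law with explicit per-cell loops."""
        cfg = tiny_config(relief=[Massif((300.0, 400.0), 2400.0, 180.0)])
        fp = cfg.fog_params
        dem = generate_dem(cfg)
        z = dem.data
        cell = 30.0
        grids = generate_fog_probability(dem, cfg)

        # independent Horn gradient -> aspect, slope
        zp = np.pad(z, 1, mode="edge")
        n, m = z.shape
        w_oracle = np.zeros_like(z)
        for r in range(n):
            for c in range(m):
                win = zp[r : r + 3, c : c + 3]
                gx = (win[0, 2] + 2 * win[1, 2] + win[2, 2]
                      - win[0, 0] - 2 * win[1, 0] - win[2, 0]) / (8 * cell)
                gy = (win[0, 0] + 2 * win[0, 1] + win[0, 2]
                      - win[2, 0] - 2 * win[2, 1] - win[2, 2]) / (8 * cell)
                aspect = np.degrees(np.arctan2(-gx, -gy)) % 360
                slope = np.degrees(np.arctan(np.hypot(gx, gy)))
                cosw = np.cos(np.radians(aspect - cfg.windward_azimuth_deg))
                w_oracle[r, c] = max(0.0, cosw) * min(1.0, slope / fp.slope_saturation_deg)

        # independent annulus isolation with explicit loops
        iso_oracle = np.zeros_like(z)
        rad_cells = int(fp.isolation_radius_m // cell)
        for r in range(n):
            for c in range(m):
                acc, cnt = 0.0, 0
                for dr in range(-rad_cells, rad_cells + 1):
                    for dc in range(-rad_cells, rad_cells + 1):
                        d = np.hypot(dr, dc) * cell
                        if not (fp.isolation_radius_m / 3 <= d <= fp.isolation_radius_m):
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < n and 0 <= cc < m:
                            acc += z[rr, cc]
                            cnt += 1
                iso_oracle[r, c] = np.clip((z[r, c] - acc / cnt) / fp.isolation_norm_m, 0, 1)

        january = fp.base_rate + fp.peak_winter * np.exp(
            -((z - (fp.center_altitude_m
                    - fp.windward_lowering_m * w_oracle
                    - fp.isolation_lowering_m * iso_oracle)) ** 2)
            / (2 * fp.width_winter_m**2)
        )
        july = fp.base_rate + fp.peak_summer * np.exp(
            -((z - fp.center_altitude_m) ** 2) / (2 * fp.width_summer_m**2)
        )
        np.testing.assert_allclose(grids[6].data, np.clip(july, 0, 1), atol=1e-12)
        np.testing.assert_allclose(grids[0].data, np.clip(january, 0, 1), atol=1e-3)

    def test_probabilities_in_unit_interval(self, small_world):
        for g in small_world.truth.fog_prob_monthly:
            assert g.data.min() >= 0 and g.data.max() <= 1


def uniform_prob_grids(p, shape=(8, 8)):
    base = RasterGrid(data=np.full(shape, float(p)), cell_size=240.0,
                      origin=(0.0, shape[0] * 240.0))
    return [base.copy() for _ in range(12)]


class TestFogMasks:
    def _prob_grids(self, p, shape=(8, 8)):
        return uniform_prob_grids(p, shape)

    def test_certain_fog_gives_all_fog(self):
        cfg = tiny_config(invalid_fraction=0.0)
        series = simulate_fog_masks(self._prob_grids(1.0), cfg, n_scenes=6)
        assert (series.codes == FOG).all()

    def test_zero_probability_gives_no_fog(self):
        cfg = tiny_config(invalid_fraction=0.0)
        series = simulate_fog_masks(self._prob_grids(0.0), cfg, n_scenes=6)
        assert (series.codes != FOG).all()

    def test_empirical_frequency_within_binomial_bound(self):
        cfg = tiny_config(invalid_fraction=0.0)
        n = 500
        series = simulate_fog_masks(self._prob_grids(0.3), cfg, n_scenes=n)
        freq = (series.codes == FOG).mean(axis=0)
        bound = 4 * np.sqrt(0.3 * 0.7 / n)
        assert np.abs(freq - 0.3).max() < bound

    def test_invalid_fraction_realized(self):
        cfg = tiny_config(invalid_fraction=0.25)
        series = simulate_fog_masks(self._prob_grids(0.5), cfg, n_scenes=200)
        frac = (series.codes == INVALID).mean()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_invalid_fraction_validation(self):
        with pytest.raises(ConfigurationError):
            tiny_config(invalid_fraction=1.0)


class TestLabelsAndPlots:
    def test_degenerate_rule_marks_every_cell(self):
        cfg = tiny_config(
            mcf_rule=McfRule(fog_threshold=0.0, floor_m=0.0, ceiling_m=np.inf,
                             treeline_m=np.inf,
                             cleared_rects=[(0.0, 100.0, 0.0, 100.0)]),
        )
        dem = generate_dem(cfg)
        fog = generate_fog_probability(dem, cfg)
        truth = generate_labels_and_plots(dem, fog, cfg)
        assert truth.mcf_truth.data.all()

    def test_empty_class_raises_simulation_error(self):
        cfg = tiny_config(mcf_rule=McfRule(fog_threshold=1.1))
        dem = generate_dem(cfg)
        fog = generate_fog_probability(dem, cfg)
        with pytest.raises(SimulationError):
            generate_labels_and_plots(dem, fog, cfg)

    def test_plot_labels_agree_with_truth_grid(self, small_world):
        truth = small_world.truth
        plots = truth.plots
        grid_labels = truth.mcf_truth.data[plots["row"], plots["col"]]
        np.testing.assert_array_equal(plots["label"].to_numpy(), grid_labels)
        forest_pts = truth.forest_points
        grid_forest = truth.forest_truth.data[forest_pts["row"], forest_pts["col"]]
        np.testing.assert_array_equal(forest_pts["label"].to_numpy(), grid_forest)

    def test_windward_fringe_dominates_low_altitude_mcf(self):
        """Below the leeward fringe altitude, MCF occurs essentially
        only on windward slopes (direct grid-count oracle)."""
        world = generate_world(LandscapeConfig(seed=5))
        truth = world.truth
        cfg = world.config
        w = windwardness(truth.dem, cfg.windward_azimuth_deg)
        alt = truth.dem.data
        mcf = truth.mcf_truth.data > 0
        low = (alt >= cfg.mcf_rule.floor_m) & (alt < 1300.0)
        wind, lee = low & (w > 0.5), low & (w < 0.1)
        assert wind.sum() > 100 and lee.sum() > 100
        frac_wind = mcf[wind].mean()
        frac_lee = mcf[lee].mean()
        assert frac_wind >= 5 * max(frac_lee, 1e-9)

    def test_two_altitudinal_regimes(self):
        """Clean altitude-driven upper boundary; fog-driven lower fringe."""
        world = generate_world(LandscapeConfig(seed=5))
        truth, cfg = world.truth, world.config
        alt = truth.dem.data
        fogp = truth.annual_fog_prob.data
        mcf = truth.mcf_truth.data > 0
        # above the ceiling: never MCF
        above = alt > cfg.mcf_rule.ceiling_m
        assert above.any() and not mcf[above].any()
        # below the bell center: every MCF cell owes it to fog
        below = alt < cfg.fog_params.center_altitude_m
        assert (fogp[below & mcf] >= cfg.mcf_rule.fog_threshold).all()

    def test_class_balance_near_configured_fraction(self, small_world):
        frac = small_world.truth.plots["label"].mean()
        assert frac == pytest.approx(small_world.config.mcf_plot_fraction, abs=0.05)


class TestReflectance:
    def test_zero_noise_yields_class_means(self):
        cfg = tiny_config(band_spectra=BandSpectra(sd=0.0))
        dem = generate_dem(cfg)
        fog = generate_fog_probability(dem, cfg)
        truth = generate_labels_and_plots(dem, fog, cfg)
        bands = generate_reflectance(truth, cfg)
        from mcfmap.synthetic import class_map

        classes = class_map(truth)
        for b, name in enumerate(("b1", "b2", "b3", "b4", "b5", "b7")):
            data = bands[name].data
            for ci, cname in enumerate(("non_forest", "forest", "mcf")):
                if (classes == ci).any():
                    expected = cfg.band_spectra.means[cname][b]
                    np.testing.assert_allclose(data[classes == ci], expected)

    def test_values_clipped_to_reflectance_range(self, small_world):
        for g in small_world.bands.values():
            assert g.data.min() >= 0 and g.data.max() <= 1

    def test_correlation_length_separates_window_variogram(self):
        """Equal means, different correlation lengths: lag-1 variogram
        distinguishes the classes beyond its sampling spread."""
        spectra = BandSpectra(
            means={"non_forest": (0.5,) * 6, "forest": (0.5,) * 6, "mcf": (0.5,) * 6},
            sd=0.05,
            correlation_length_cells={"non_forest": 1.0, "forest": 6.0, "mcf": 2.0},
        )
        cfg = small_landscape_config(seed=9)
        from dataclasses import replace

        cfg = replace(cfg, band_spectra=spectra)
        world = generate_world(cfg)
        from mcfmap.synthetic import class_map
        from scipy.ndimage import binary_erosion

        classes = class_map(world.truth)
        gamma = texture_raster(world.bands["b4"], None, "variogram", 1, 7).data
        interior = {
            ci: binary_erosion(classes == ci, iterations=4) for ci in (1, 2)
        }
        m_forest, m_mcf = gamma[interior[1]], gamma[interior[2]]
        gap = abs(m_mcf.mean() - m_forest.mean())
        spread = max(
            m_mcf.std() / np.sqrt(len(m_mcf)), m_forest.std() / np.sqrt(len(m_forest))
        )
        assert m_mcf.mean() > m_forest.mean()  # shorter correlation, rougher
        assert gap > 4 * spread

    def test_single_class_histogram_is_gaussian(self):
        """All-one-class world: band values match the configured normal
        (KS distance small at this sample size)."""
        from scipy import stats

        cfg = tiny_config(
            mcf_rule=McfRule(fog_threshold=0.0, floor_m=0.0, ceiling_m=np.inf,
                             treeline_m=np.inf,
                             cleared_rects=[(0.0, 100.0, 0.0, 100.0)]),
            band_spectra=BandSpectra(
                means={"non_forest": (0.5,) * 6, "forest": (0.5,) * 6, "mcf": (0.5,) * 6},
                sd=0.03,
                correlation_length_cells={"non_forest": 1.0, "forest": 1.0, "mcf": 1.0},
            ),
            grid_rows=64, grid_cols=64,
        )
        dem = generate_dem(cfg)
        fog = generate_fog_probability(dem, cfg)
        truth = generate_labels_and_plots(dem, fog, cfg)
        band = generate_reflectance(truth, cfg)["b1"].data.ravel()
        # correlated noise: thin to roughly independent samples
        sample = band[:: 7]
        d, _ = stats.kstest(sample, "norm", args=(0.5, 0.03))
        assert d < 0.08


class TestDeterminism:
    def test_identical_seed_and_config_bitwise_identical(self):
        cfg = small_landscape_config(seed=21)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        np.testing.assert_array_equal(w1.truth.dem.data, w2.truth.dem.data)
        np.testing.assert_array_equal(w1.truth.mcf_truth.data, w2.truth.mcf_truth.data)
        np.testing.assert_array_equal(w1.masks.codes, w2.masks.codes)
        for name in w1.bands:
            np.testing.assert_array_equal(w1.bands[name].data, w2.bands[name].data)
        assert w1.truth.plots.equals(w2.truth.plots)

    def test_different_seed_changes_stochastic_stages(self):
        from dataclasses import replace

        cfg = small_landscape_config(seed=21)
        w1 = generate_world(cfg)
        w2 = generate_world(replace(cfg, seed=22))
        np.testing.assert_array_equal(w1.truth.dem.data, w2.truth.dem.data)  # deterministic
        assert not np.array_equal(w1.masks.codes, w2.masks.codes)
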
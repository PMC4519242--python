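"""Synthetic landscape generator: composition, determinism, planted signal."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare
from shapely.ops import unary_union

import pantherscape.synth as psynth
from pantherscape.cover import (
    CATEGORIES,
    DEFAULT_COVER_MIX,
    OPEN_FRESHWATER_WETLAND,
    SALTWATER_WETLAND,
    URBAN,
)
from pantherscape.synth import (
    SyntheticConfig,
    generate_anthropogenic,
    generate_cover,
    generate_hydrology,
    simulate_telemetry,
    utilization_weights,
)


class TestConfig:
    def test_bad_mix_sum_rejected(self):
        mix = dict(DEFAULT_COVER_MIX)
        mix[URBAN] += 0.01
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(cover_mix=mix)

    def test_missing_category_rejected(self):
        mix = dict(DEFAULT_COVER_MIX)
        mix.pop(URBAN)
        with pytest.raises(ValueError, match="10 cover categories"):
            SyntheticConfig(cover_mix=mix)

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError, match="fixes_per_animal"):
            SyntheticConfig(fixes_per_animal=10)


class TestGenerateCover:
    def test_too_small_landscape_rejected(self):
        with pytest.raises(ValueError, match="landscape too small"):
            generate_cover(SyntheticConfig(extent_km=4))

    def test_degenerate_single_category_mix(self):
        mix = {c: 0.0 for c in CATEGORIES}
        mix[OPEN_FRESHWATER_WETLAND] = 1.0
        layer = generate_cover(SyntheticConfig(extent_km=10, cover_mix=mix, seed=0))
        areas = layer.total_area_by_category()
        assert areas[OPEN_FRESHWATER_WETLAND] == pytest.approx(1e8, rel=1e-6)
        assert set(layer.categories) == {OPEN_FRESHWATER_WETLAND}

    def test_realized_fractions_near_targets(self, small_world):
        """Region growing hits the configured mix within 5 percentage points."""
        layer = small_world["layer"]
        total = sum(g.area for g in layer.geometries)
        fracs = layer.total_area_by_category() / total
        for cat, target in small_world["config"].cover_mix.items():
            assert abs(fracs[cat] - target) <= 0.05

    def test_tessellation_gap_and_overlap_free(self, small_world):
        layer = small_world["layer"]
        total = sum(g.area for g in layer.geometries)
        L = small_world["config"].extent_m
        union = unary_union(layer.geometries)
        # no overlaps: union area equals summed area; no gaps: covers extent
        assert union.area == pytest.approx(total, rel=1e-9)
        assert union.area == pytest.approx(L * L, rel=1e-9)

    def test_urban_concentrated_in_corner(self, small_world):
        layer = small_world["layer"]
        cfg = small_world["config"]
        ux, uy = cfg.urban_corner
        urban = [g for g, c in zip(layer.geometries, layer.categories) if c == URBAN]
        centroid = unary_union(urban).centroid
        d_corner = np.hypot(centroid.x - ux, centroid.y - uy)
        assert d_corner < 0.5 * cfg.extent_m

    def test_saltwater_hugs_south_edge(self, small_world):
        layer = small_world["layer"]
        salt = [g for g, c in zip(layer.geometries, layer.categories) if c == SALTWATER_WETLAND]
        centroid = unary_union(salt).centroid
        assert centroid.y < 0.4 * small_world["config"].extent_m

    def test_same_seed_identical_layer(self):
        cfg = SyntheticConfig(extent_km=8, seed=42)
        a = generate_cover(cfg)
        b = generate_cover(cfg)
        assert a.codes == b.codes
        assert all(g1.equals_exact(g2, 0) for g1, g2 in zip(a.geometries, b.geometries))


class TestGenerateHydrology:
    def test_gauges_inside_and_outside_extent(self, small_world):
        cfg = small_world["config"]
        gauges = small_world["gauges"]
        L = cfg.extent_m
        inside = [g for g in gauges if 0 <= g.x <= L and 0 <= g.y <= L]
        outside = [g for g in gauges if not (0 <= g.x <= L and 0 <= g.y <= L)]
        assert len(inside) >= 4 and len(outside) >= 1

    def test_true_depth_span_realistic(self):
        """Default-extent seasonal depths span roughly -5.2 to +2.6 m."""
        _, _, truth = generate_hydrology(SyntheticConfig(seed=0))
        lo = min(truth["true_dry_depth"].min(), truth["true_wet_depth"].min())
        hi = max(truth["true_dry_depth"].max(), truth["true_wet_depth"].max())
        assert lo == pytest.approx(-5.2, abs=0.7)
        assert hi == pytest.approx(2.6, abs=0.7)

    def test_wet_minus_dry_about_point_three(self, small_world):
        t = small_world["table"]
        assert (t["wet_depth"] - t["dry_depth"]).mean() == pytest.approx(0.3, abs=0.1)

    def test_wet_dry_highly_correlated(self, small_world):
        t = small_world["table"]
        r2 = np.corrcoef(t["wet_depth"], t["dry_depth"])[0, 1] ** 2
        assert r2 >= 0.9

    def test_pipeline_depths_track_generating_field(self, small_world):
        """IDW-from-gauges estimates recover the analytic truth closely."""
        cfg = small_world["config"]
        _, _, truth = generate_hydrology(cfg)
        t = small_world["table"]
        merged = t.join(truth)
        for est, true in (("dry_depth", "true_dry_depth"), ("wet_depth", "true_wet_depth")):
            r2 = np.corrcoef(merged[est], merged[true])[0, 1] ** 2
            assert r2 >= 0.9

    def test_too_few_gauges_rejected(self):
        with pytest.raises(ValueError, match="4 gauges"):
            generate_hydrology(SyntheticConfig(n_gauges=3))


class TestGenerateAnthropogenic:
    def test_wilderness_config_unpopulated_and_roadless(self):
        mix = dict(DEFAULT_COVER_MIX)
        mix[OPEN_FRESHWATER_WETLAND] += mix.pop(URBAN)
        mix[URBAN] = 0.0
        cfg = SyntheticConfig(extent_km=10, cover_mix=mix, seed=0)
        blocks, roads = generate_anthropogenic(cfg)
        assert all(pop == 0.0 for _, pop in blocks)
        assert all(cls in ("bike_trail", "four_wheel_drive", "pedestrian_trail") for _, cls in roads)

    def test_urban_corner_dominates_interior(self):
        # default-extent landscape: the wild interior is far from any town
        cfg = SyntheticConfig(seed=0)
        blocks, _ = generate_anthropogenic(cfg)
        ux, uy = cfg.urban_corner
        dens = np.array([pop / (g.area / 1e6) for g, pop in blocks])
        d = np.array([np.hypot(g.centroid.x - ux, g.centroid.y - uy) for g, _ in blocks])
        corner = dens[np.argmin(d)]
        interior_median = np.median(dens[d > 0.5 * cfg.extent_m])
        assert corner > 100 * max(interior_median, 1e-9)

    def test_excluded_road_class_present_and_ignored_downstream(self, small_world):
        from pantherscape.features import DEFAULT_EXCLUDED_ROAD_CLASSES, road_density

        roads = small_world["roads"]
        classes = {cls for _, cls in roads}
        assert classes & DEFAULT_EXCLUDED_ROAD_CLASSES
        grid = small_world["grid"]
        with_trails = road_density(grid, roads)
        without = road_density(grid, [r for r in roads if r[1] not in DEFAULT_EXCLUDED_ROAD_CLASSES])
        pd.testing.assert_series_equal(with_trails, without)


class TestSimulateTelemetry:
    def test_null_preferences_give_uniform_use(self, small_world):
        """With no planted preferences, one animal's fixes are uniform over
        its movement-accessible cells (chi-square GOF)."""
        coefs = {k: 0.0 for k in psynth.DEFAULT_PREFERENCE_COEFS}
        cfg = SyntheticConfig(
            extent_km=20,
            n_animals=1,
            fixes_per_animal=2000,
            preference_coefs=coefs,
            depth_curvature=0.0,
            seed=1,
        )
        table = small_world["table"]
        fixes, truth = simulate_telemetry(cfg, table)
        w = truth.utilization
        assert w.nunique() == 1  # constant utilisation under the null
        grid = cfg.grid
        cells = grid.assign_many(fixes[["x", "y"]].to_numpy())
        counts = pd.Series(map(tuple, cells)).value_counts()
        cx, cy = truth.home_range_centers[0]
        centers = np.array([grid.cell_center(c, r) for c, r in table.index])
        accessible = [
            tuple(cid)
            for cid, (x, y) in zip(table.index, centers)
            if np.hypot(x - cx, y - cy) <= cfg.movement_radius_km * 1000
        ]
        observed = counts.reindex(accessible, fill_value=0)
        assert chisquare(observed).pvalue > 0.01

    def test_positive_wetland_forest_preference_visible_in_labels(self, small_world):
        table = small_world["table"]
        pres = table["presence"].astype(bool)
        assert table.loc[pres, "Wet_For"].mean() > table.loc[~pres, "Wet_For"].mean()

    def test_planted_signs_all_visible_in_group_means(self, small_world):
        """Presence/absence group means differ in the planted direction for
        every nonzero coefficient."""
        table = small_world["table"]
        pres = table["presence"].astype(bool)
        for name, beta in small_world["config"].preference_coefs.items():
            if beta == 0.0:
                continue
            diff = table.loc[pres, name].mean() - table.loc[~pres, name].mean()
            assert np.sign(diff) == np.sign(beta), name

    def test_every_animal_has_configured_fixes(self, small_world):
        counts = small_world["fixes"].groupby("animal_id").size()
        assert (counts >= 50).all()
        assert len(counts) == small_world["config"].n_animals

    def test_fixes_within_study_window_and_adult(self, small_world):
        f = small_world["fixes"]
        assert f["fix_datetime"].min() >= pd.Timestamp("2004-01-01")
        assert f["fix_datetime"].max() <= pd.Timestamp("2013-12-31")
        age = (f["fix_datetime"] - f["birth_date"]).dt.days / 365.25
        assert (age >= 3.0).all()

    def test_same_seed_identical_fixes(self, small_world):
        cfg = small_world["config"]
        table = small_world["table"]
        f1, _ = simulate_telemetry(cfg, table)
        f2, _ = simulate_telemetry(cfg, table)
        pd.testing.assert_frame_equal(f1, f2)

    def test_all_zero_utilization_rejected(self, small_world):
        table = small_world["table"].copy()
        cfg = SyntheticConfig(
            extent_km=20, intercept=-60.0, depth_curvature=0.0, seed=0
        )
        with pytest.raises(ValueError, match="no habitable cells"):
            simulate_telemetry(cfg, table)

    def test_ground_truth_invariants(self, small_world):
        truth = small_world["truth"]
        w = truth.utilization.to_numpy()
        assert np.isfinite(w).all() and (w >= 0).all() and (w > 0).any()
        assert len(truth.home_range_centers) == small_world["config"].n_animals
        # two designated null covariates are recorded in the ground truth
        nulls = [k for k, v in truth.preference_coefs.items() if v == 0.0]
        assert len(nulls) == 2

    def test_utilization_is_logistic_of_planted_terms(self, small_world):
        """Spot-check the weight formula against a hand computation."""
        cfg = small_world["config"]
        table = small_world["table"]
        w = utilization_weights(cfg, table)
        eta = np.full(len(table), cfg.intercept)
        for name, beta in cfg.preference_coefs.items():
            if beta == 0.0:
                continue
            x = table[name].to_numpy()
            eta += beta * (x - x.mean()) / x.std()
        eta -= cfg.depth_curvature * (table["dry_depth"].to_numpy() - cfg.depth_optimum_m) ** 2
        assert np.allclose(w.to_numpy(), 1 / (1 + np.exp(-eta)))
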
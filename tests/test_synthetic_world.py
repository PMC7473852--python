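import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from mangrove_typology.errors import ConfigError
from mangrove_typology.geo_core import area_km2
from mangrove_typology.synthetic_world import (
    CLASS_TO_TYPE,
    SceneConfig,
    generate_scene,
    generate_sediment_fields,
    generate_timesteps,
    sample_sediment_sites,
    simulate_unit_means,
)

from conftest import make_patch_scene


class TestSceneConfig:
    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError, match="n_deltas"):
            SceneConfig(n_deltas=-1).validate()

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ConfigError, match="cell_km"):
            SceneConfig(cell_km=0).validate()

    def test_loss_rate_bounds(self):
        with pytest.raises(ConfigError, match="loss_rate"):
            SceneConfig(loss_rate={"deltaic": 1.5}).validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SceneConfig(n_bays=5, cell_km=0.25)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SceneConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("bogus_key: 3\n")
        with pytest.raises(ConfigError, match="bogus_key"):
            SceneConfig.from_yaml(tmp_path / "c.yaml")


class TestGenerateScene:
    def test_degenerate_no_embayments(self):
        cfg = SceneConfig(
            n_deltas=0, n_estuaries=0, n_lagoons=0, n_bays=0, n_open_coast_strips=0
        )
        scene = generate_scene(cfg, seed=0)
        assert scene.truth.embayment_class == {}
        assert len(scene.embayments) == 0
        # straight coast: land is the plain rectangle
        land = scene.land
        assert land.equals(box(0, 0, land.bounds[2], land.bounds[3]))

    def test_planted_delta_distributaries(self):
        cfg = SceneConfig(
            n_deltas=3,
            n_estuaries=0,
            n_lagoons=0,
            n_bays=0,
            n_distributaries=(4, 4),
            n_open_coast_strips=0,
        )
        scene = generate_scene(cfg, seed=3)
        classes = list(scene.truth.embayment_class.values())
        assert classes == ["delta"] * 3
        # every delta embayment contains exactly 4 distributary outlets
        for geom, attrs in scene.embayments:
            zone = geom.buffer(1.0)
            outlets = sum(
                1
                for _, fa in scene.flowlines
                if fa.get("next_fid") == -1
                and zone.contains(Point(fa["outlet_x"], fa["outlet_y"]))
            )
            assert outlets == 4

    def test_seed_contract(self):
        cfg = SceneConfig(n_open_coast_strips=0)
        s1 = generate_scene(cfg, seed=1)
        s2 = generate_scene(cfg, seed=2)
        c1 = sorted(s1.truth.embayment_class.values())
        c2 = sorted(s2.truth.embayment_class.values())
        assert c1 == c2  # same class counts
        assert not s1.land.equals(s2.land)  # different geometry

    def test_determinism(self):
        cfg = SceneConfig(n_deltas=1, n_estuaries=1, n_lagoons=1, n_bays=1)
        a = generate_scene(cfg, seed=7)
        b = generate_scene(cfg, seed=7)
        assert a.land.equals(b.land)
        np.testing.assert_array_equal(a.precip.values, b.precip.values)
        np.testing.assert_array_equal(a.agb.values, b.agb.values)
        assert a.truth.sediment_class == b.truth.sediment_class

    def test_invariants(self, default_scene):
        scene = default_scene
        land = scene.land
        boundary = land.boundary
        # flowline outlets on the coastline boundary (grid tolerance)
        for _, attrs in scene.flowlines:
            if attrs.get("next_fid") == -1:
                pt = Point(attrs["outlet_x"], attrs["outlet_y"])
                assert boundary.distance(pt) < scene.config.cell_km
        # mangrove patches near the coast
        for geom, _ in scene.patches:
            assert geom.distance(boundary) < 5.0
        # every watershed intersects its flowline
        flow_by_fid = {a["fid"]: g for g, a in scene.flowlines}
        for geom, attrs in scene.watersheds:
            assert geom.intersects(flow_by_fid[attrs["fid"]])
        # rasters share one geotransform
        for name in ("precip", "tide", "spm", "agb"):
            raster = getattr(scene, name)
            assert raster.origin == scene.precip.origin
            assert raster.cell == scene.precip.cell

    def test_patches_disjoint(self, default_scene):
        geoms = default_scene.patches.geometries
        total = sum(g.area for g in geoms)
        from shapely.ops import unary_union

        assert unary_union(geoms).area == pytest.approx(total, rel=1e-9)


class TestTimesteps:
    def test_zero_loss_identity(self):
        scene = make_patch_scene([(box(10, 48, 20, 50), "open_coast")])
        generate_timesteps(scene, {"open_coast": 0.0}, seed=0)
        areas = {
            lab: sum(g.area for g in layer.geometries)
            for lab, layer in scene.extents.items()
        }
        assert len(set(areas.values())) == 1

    def test_planted_lagoonal_loss(self):
        # 100 km² lagoonal unit, 6.9% loss: final area 93.1 ± one cell
        scene = make_patch_scene([(box(10, 40, 20, 50), "lagoonal")])
        generate_timesteps(scene, {"lagoonal": 0.069}, seed=0)
        final = sum(g.area for g in scene.extents["2016"].geometries)
        cell_area = scene.config.cell_km**2
        assert abs(final - 93.1) <= cell_area

    def test_total_loss_annihilation(self):
        scene = make_patch_scene([(box(10, 48, 20, 50), "deltaic")])
        generate_timesteps(scene, {"deltaic": 1.0}, seed=0)
        assert len(scene.extents["2016"]) == 0

    def test_monotone_subsets_and_union(self, default_scene):
        scene = default_scene
        labels = sorted(scene.config.timesteps, key=lambda k: scene.config.timesteps[k])
        from shapely.ops import unary_union

        prev = None
        for lab in labels:
            cur = unary_union(scene.extents[lab].geometries)
            if prev is not None:
                assert cur.difference(prev).area < 1e-6
            prev = cur
        union_all = unary_union(
            [g for lab in labels for g in scene.extents[lab].geometries]
        )
        baseline = unary_union(scene.patches.geometries)
        assert union_all.symmetric_difference(baseline).area < 1e-6

    def test_invalid_rate_rejected(self):
        scene = make_patch_scene([(box(10, 48, 20, 50), "deltaic")])
        with pytest.raises(ConfigError):
            generate_timesteps(scene, {"deltaic": -0.1}, seed=0)

    def test_realized_rate_within_tolerance(self, default_scene):
        scene = default_scene
        cell_area = scene.config.cell_km**2
        truth_rate = scene.truth.loss_rate
        for geom, attrs in scene.patches:
            pid = attrs["patch_id"]
            base = geom.area
            final = sum(
                g.area
                for g, a in scene.extents["2016"].features
                if a["patch_id"] == pid
            )
            target = base * (1 - truth_rate[attrs["truth_type"]])
            assert abs(final - target) <= cell_area


class TestSedimentFields:
    def _many_patch_scene(self):
        specs = []
        for i in range(200):
            x = 2 + (i % 40) * 2.0
            y = 44 + (i // 40) * 1.2
            specs.append((box(x, y, x + 1.4, y + 0.8), "open_coast"))
        return make_patch_scene(specs)

    def test_saturated_logit_all_terrigenous(self):
        scene = self._many_patch_scene()
        generate_sediment_fields(scene, (50.0, 0.0, 0.0), seed=0)
        assert set(scene.truth.sediment_class.values()) == {"terrigenous"}

    def test_symmetric_logit_half_carbonate(self):
        scene = self._many_patch_scene()
        generate_sediment_fields(scene, (0.0, 0.0, 0.0), seed=0)
        frac = np.mean(
            [v == "carbonate" for v in scene.truth.sediment_class.values()]
        )
        # binomial 99.9% CI around 0.5 at n=200
        assert 0.38 < frac < 0.62

    def test_deltaic_estuarine_forced_terrigenous(self, default_scene):
        truth_type = {a["patch_id"]: a["truth_type"] for _, a in default_scene.patches}
        for pid, label in default_scene.truth.sediment_class.items():
            if truth_type[pid] in ("deltaic", "estuarine"):
                assert label == "terrigenous"

    def test_fields_positive(self, default_scene):
        assert (default_scene.tide.values > 0).all()
        assert (default_scene.spm.values > 0).all()

    def test_bad_beta_rejected(self):
        scene = self._many_patch_scene()
        with pytest.raises(ConfigError):
            generate_sediment_fields(scene, (0.0, 1.0), seed=0)


class TestSimulators:
    def test_simulate_unit_means_planted(self):
        means = {"a": 100.0, "b": 50.0}
        sds = {"a": 10.0, "b": 5.0}
        v, t = simulate_unit_means(means, sds, 2000, seed=0)
        assert v[t == "a"].mean() == pytest.approx(100.0, rel=0.02)
        assert v[t == "b"].mean() == pytest.approx(50.0, rel=0.02)

    def test_sample_sites_schema(self, default_scene):
        sites = sample_sediment_sites(default_scene, 50, (-2, 1.5, 0.1), seed=0)
        assert len(sites) == 50
        assert {s["sediment_label"] for s in sites} <= {"terrigenous", "carbonate"}
        assert all(s["tide_m"] >= 0 and s["spm_gm3"] >= 0 for s in sites)


def test_area_bookkeeping(default_scene):
    """Per-type truth areas sum to total baseline extent area."""
    per_type = {}
    total = 0.0
    for geom, attrs in default_scene.patches:
        per_type[attrs["truth_type"]] = per_type.get(attrs["truth_type"], 0.0) + geom.area
        total += geom.area
    assert sum(per_type.values()) == pytest.approx(total, rel=1e-12)
    assert set(per_type) <= set(CLASS_TO_TYPE.values())
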
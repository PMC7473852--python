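import numpy as np
import pytest
from shapely.geometry import LineString, box

from mangrove_typology.cep_builder import CEP
from mangrove_typology.geo_core import VectorLayer
from mangrove_typology.synthetic_world import (
    CoastScene,
    SceneConfig,
    TruthLabels,
    generate_scene,
)


@pytest.fixture(scope="session")
def default_scene():
    """One shared default scene (12 embayments, 3 per class, seed 1)."""
    return generate_scene(SceneConfig(), seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_scene):
    from mangrove_typology.pipeline import run_pipeline

    return run_pipeline(seed=1, scene=default_scene)


@pytest.fixture()
def empty_flowlines():
    return VectorLayer(geometry_type="polyline")


@pytest.fixture()
def empty_watersheds():
    return VectorLayer(geometry_type="polygon")


def make_cep(cep_id=1, geometry=None, mouth=None, **kwargs) -> CEP:
    geometry = geometry if geometry is not None else box(0, 0, 10, 10)
    if mouth is None:
        minx, miny, maxx, maxy = geometry.bounds
        mouth = LineString([(minx, maxy), (maxx, maxy)])
    return CEP(id=cep_id, geometry=geometry, mouth=mouth, **kwargs)


def ceps_from_table(df):
    """Lightweight CEP stand-ins carrying covariates from a table row."""
    from mangrove_typology.cep_covariates import COVARIATE_COLUMNS

    ceps = []
    for _, row in df.iterrows():
        cep = make_cep(int(row["cep_id"]), box(0, 0, 1, 1))
        cep.covariates = {c: float(row[c]) for c in COVARIATE_COLUMNS}
        ceps.append(cep)
    return ceps


def make_patch_scene(patch_specs, config=None, seed=0):
    """Scene with hand-placed mangrove patches and no embayments.

    ``patch_specs`` is a list of (geometry, truth_type). The coastline is a
    plain rectangle spanning the template's land zone.
    """
    config = config or SceneConfig(
        n_deltas=0, n_estuaries=0, n_lagoons=0, n_bays=0
    )
    H = config.land_depth_km
    W = 2 * config.margin_km + config.spacing_km * max(config.n_embayments, 1)
    coast = VectorLayer(geometry_type="polygon")
    coast.add(box(0, 0, W, H), landmass_id=1, area_km2=W * H)
    patches = VectorLayer(geometry_type="polygon")
    for i, (geom, ttype) in enumerate(patch_specs):
        patches.add(geom, patch_id=i + 1, truth_type=ttype, emb_id=None)
    return CoastScene(
        config=config,
        coastline=coast,
        flowlines=VectorLayer(geometry_type="polyline"),
        watersheds=VectorLayer(geometry_type="polygon"),
        embayments=VectorLayer(geometry_type="polygon"),
        patches=patches,
        truth=TruthLabels(),
    )
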
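"""Per-CEP classification covariates.

Ten variables per embayment spanning three families: polygon shape (area,
perimeter, compactness, mouth width, elongation, closure ratio), upstream
catchment (aggregated watershed area, flowline count), and precipitation
routed through the network (annual total, seasonality). The exact variable
set is a declared default, replaceable via configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .cep_builder import CEP
from .errors import MangroveTypologyError, TopologyError
from .geo_core import RasterField, VectorLayer, covered_cells, line_parts

COVARIATE_COLUMNS = [
    "v1_area_km2",
    "v2_perimeter_km",
    "v3_compactness",
    "v4_mouth_width_km",
    "v5_elongation",
    "v6_closure_ratio",
    "v7_catchment_area_km2",
    "v8_n_flowlines",
    "v9_annual_precip_mm",
    "v10_precip_seasonality",
]


@dataclass
class Catchment:
    cep_id: int
    geometry: BaseGeometry
    area_km2: float
    n_flowlines: int


def _upstream_closure(selected: set[int], downstream: dict[int, int]) -> set[int]:
    """All flowline ids whose downstream chain reaches the selected set."""
    out = set(selected)
    changed = True
    while changed:
        changed = False
        for fid, nxt in downstream.items():
            if fid not in out and nxt in out:
                out.add(fid)
                changed = True
    return out


def build_catchment(
    cep: CEP, flowlines: VectorLayer, watersheds: VectorLayer
) -> Catchment:
    """Aggregate whole watersheds drained by flowlines that meet the CEP.

    The catchment is the union of watersheds linked to any flowline that
    intersects the CEP, plus watersheds of all flowlines upstream of those.
    """
    downstream: dict[int, int] = {}
    geoms_by_fid: dict[int, BaseGeometry] = {}
    for geom, attrs in flowlines:
        fid = attrs["fid"]
        downstream[fid] = attrs.get("next_fid", -1)
        geoms_by_fid[fid] = geom
    for fid, nxt in downstream.items():
        if nxt != -1 and nxt not in downstream:
            raise TopologyError(f"flowline {fid} has dangling downstream pointer {nxt}")

    touching = {
        fid
        for fid, geom in geoms_by_fid.items()
        if geom.intersects(cep.geometry) or geom.intersects(cep.mouth)
    }
    n_flow = len(touching)
    closure = _upstream_closure(touching, downstream)

    shed_geoms = [
        geom for geom, attrs in watersheds if attrs.get("fid") in closure
    ]
    # also include watersheds spatially intersecting selected flowlines but
    # linked to none (defensive; synthetic data always carries the link)
    if shed_geoms:
        geometry = unary_union(shed_geoms)
    else:
        geometry = Polygon()
    return Catchment(
        cep_id=cep.id,
        geometry=geometry,
        area_km2=float(geometry.area),
        n_flowlines=n_flow,
    )


def route_precipitation(
    catchment: Catchment, precip: RasterField
) -> tuple[float, float]:
    """(annual mm, seasonality) of catchment-masked monthly precipitation.

    annual = sum of monthly catchment means; seasonality = max month / mean
    month. Empty catchments route nothing: (0, 0).
    """
    if precip.n_bands != 12:
        raise MangroveTypologyError(
            f"precipitation raster must have 12 monthly bands, got {precip.n_bands}"
        )
    if catchment.geometry.is_empty or catchment.area_km2 == 0:
        return 0.0, 0.0
    rows, cols = covered_cells(catchment.geometry, precip)
    if len(rows) == 0:
        return 0.0, 0.0
    monthly = []
    for b in range(12):
        vals = precip.values[b, rows, cols]
        valid = ~np.isclose(vals, precip.nodata) & np.isfinite(vals)
        monthly.append(float(vals[valid].mean()) if valid.any() else 0.0)
    annual = float(sum(monthly))
    mean_m = annual / 12.0
    seasonality = float(max(monthly) / mean_m) if mean_m > 0 else 0.0
    return annual, seasonality


def _mouth_direction(mouth: BaseGeometry) -> tuple[float, float]:
    """Unit vector of the dominant mouth direction (longest segment chord)."""
    segs = line_parts(mouth)
    if not segs:
        return (1.0, 0.0)
    longest = max(segs, key=lambda s: s.length)
    (x0, y0), (x1, y1) = longest.coords[0], longest.coords[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    if norm == 0:
        return (1.0, 0.0)
    return (dx / norm, dy / norm)


def _extent_along(geom: BaseGeometry, direction: tuple[float, float]) -> float:
    coords = []
    for poly in (
        geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    ):
        coords.extend(poly.exterior.coords)
    arr = np.asarray(coords)
    proj = arr[:, 0] * direction[0] + arr[:, 1] * direction[1]
    return float(proj.max() - proj.min())


def shape_metrics(cep: CEP) -> dict:
    """Shape covariates v1–v6 for one CEP."""
    if cep.mouth is None or cep.mouth.is_empty:
        raise MangroveTypologyError(f"CEP {cep.id} has no mouth; malformed upstream")
    geom = cep.geometry
    area = float(geom.area)
    perim = float(geom.length)
    compact = 4 * math.pi * area / perim**2 if perim > 0 else 0.0
    mouth_w = float(cep.mouth.length)
    rect = geom.minimum_rotated_rectangle
    if rect.geom_type == "Polygon":
        xs = list(rect.exterior.coords)
        e1 = math.hypot(xs[1][0] - xs[0][0], xs[1][1] - xs[0][1])
        e2 = math.hypot(xs[2][0] - xs[1][0], xs[2][1] - xs[1][1])
        length = max(e1, e2)
    else:
        length = max(geom.bounds[2] - geom.bounds[0], geom.bounds[3] - geom.bounds[1])
    mean_width = area / length if length > 0 else 0.0
    elongation = length / mean_width if mean_width > 0 else 0.0
    direction = _mouth_direction(cep.mouth)
    max_interior = _extent_along(geom, direction)
    closure = mouth_w / max_interior if max_interior > 0 else 0.0
    return {
        "v1_area_km2": area,
        "v2_perimeter_km": perim,
        "v3_compactness": min(compact, 1.0),
        "v4_mouth_width_km": mouth_w,
        "v5_elongation": elongation,
        "v6_closure_ratio": closure,
    }


def covariate_table(
    ceps: list[CEP],
    flowlines: VectorLayer,
    watersheds: VectorLayer,
    precip: RasterField,
) -> pd.DataFrame:
    """One covariate row per CEP (columns fixed to COVARIATE_COLUMNS)."""
    ids = [cep.id for cep in ceps]
    if len(set(ids)) != len(ids):
        raise MangroveTypologyError("duplicate cep_id in covariate table input")
    rows = []
    for cep in ceps:
        row = {"cep_id": cep.id}
        row.update(shape_metrics(cep))
        catch = build_catchment(cep, flowlines, watersheds)
        annual, season = route_precipitation(catch, precip)
        row["v7_catchment_area_km2"] = catch.area_km2
        row["v8_n_flowlines"] = catch.n_flowlines
        row["v9_annual_precip_mm"] = annual
        row["v10_precip_seasonality"] = season
        cep.covariates = {k: row[k] for k in COVARIATE_COLUMNS}
        rows.append(row)
    df = pd.DataFrame(rows, columns=["cep_id"] + COVARIATE_COLUMNS)
    if not df.empty and not np.isfinite(df[COVARIATE_COLUMNS].to_numpy()).all():
        raise MangroveTypologyError("non-finite covariate produced")
    return df
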
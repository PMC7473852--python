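"""Delineation of coastal embayment polygons (CEPs).

A generalized "outer" coastline is produced by morphological closing of the
land (buffer out then in by the same radius). Water enclosed between the
generalized and the actual coastline — the indents — is split into connected
components; components with several well-separated openings to the sea are
partitioned by Euclidean allocation of raster cells to the nearest mouth
segment. CEPs are then filtered to mangrove-relevant landmasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import linemerge, unary_union

from .errors import ConfigError, MangroveTypologyError
from .geo_core import (
    RasterField,
    VectorLayer,
    cells_to_polygon,
    covered_cells,
    ensure_valid,
    line_parts,
    logger,
    polygon_parts,
)

UNASSIGNED = "unassigned"


@dataclass
class CEP:
    """One coastal embayment polygon: a water indent and its sea opening."""

    id: int
    geometry: BaseGeometry
    mouth: BaseGeometry
    source_landmass_area: float = float("nan")
    dist_to_mangrove: float = float("nan")
    cep_class: str = UNASSIGNED
    covariates: dict = field(default_factory=dict)
    edge_flag: bool = False
    provenance: str = ""

    @property
    def mouth_length_km(self) -> float:
        return float(self.mouth.length)


def generalize_coastline(coast: VectorLayer, closing_radius: float) -> VectorLayer:
    """Morphological closing of the land by ``closing_radius`` km.

    The result always contains the original land; straight coasts are fixed
    points of the operation.
    """
    if closing_radius <= 0:
        raise ConfigError(f"closing_radius must be > 0, got {closing_radius}")
    land = ensure_valid(unary_union(coast.geometries))
    closed = land.buffer(closing_radius, quad_segs=16).buffer(
        -closing_radius, quad_segs=16
    )
    # guard against numeric slivers: closing must contain the input
    closed = ensure_valid(unary_union([closed, land]))
    out = VectorLayer(geometry_type="polygon")
    for i, poly in enumerate(polygon_parts(closed)):
        out.add(poly, landmass_id=i + 1)
    return out


def _mouth_of(component: BaseGeometry, generalized_boundary: BaseGeometry):
    return component.boundary.intersection(generalized_boundary)


def _cluster_mouth_segments(mouth: BaseGeometry, gap_km: float) -> list:
    """Group mouth line segments into openings separated by > gap_km."""
    raw = line_parts(mouth)
    if not raw:
        return []
    merged = linemerge(raw) if len(raw) > 1 else raw[0]
    segs = line_parts(merged)
    clusters: list[list] = []
    for seg in segs:
        placed = False
        for cl in clusters:
            if any(seg.distance(other) <= gap_km for other in cl):
                cl.append(seg)
                placed = True
                break
        if not placed:
            clusters.append([seg])
    # merge clusters that became adjacent through later additions
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    a.distance(b) <= gap_km for a in clusters[i] for b in clusters[j]
                ):
                    clusters[i].extend(clusters.pop(j))
                    merged = True
                    break
            if merged:
                break
    return [unary_union(cl) for cl in clusters]


def _allocate_split(
    component: BaseGeometry, mouths: list, alloc_res: float
) -> list[tuple[BaseGeometry, BaseGeometry]]:
    """Split a component by nearest-mouth Euclidean allocation on a grid."""
    minx, miny, maxx, maxy = component.bounds
    pad = alloc_res
    nx = max(int(np.ceil((maxx - minx + 2 * pad) / alloc_res)), 1)
    ny = max(int(np.ceil((maxy - miny + 2 * pad) / alloc_res)), 1)
    template = RasterField(
        np.zeros((ny, nx)), (minx - pad, maxy + pad), alloc_res
    )
    rows, cols = covered_cells(component, template)
    if len(rows) == 0:
        return [(component, unary_union(mouths))]
    x0, y0 = template.origin
    xs = x0 + (cols + 0.5) * alloc_res
    ys = y0 - (rows + 0.5) * alloc_res
    from shapely import points as shp_points

    pts = shp_points(np.column_stack([xs, ys]))
    dists = np.column_stack([[m.distance(p) for p in pts] for m in mouths])
    owner = dists.argmin(axis=1)
    pieces = []
    for k, mouth in enumerate(mouths):
        sel = owner == k
        if not sel.any():
            continue
        cellpoly = cells_to_polygon(rows[sel], cols[sel], template)
        geom = cellpoly.intersection(component)
        for part in polygon_parts(geom):
            pieces.append((part, mouth))
    return pieces


def extract_embayments(
    coast: VectorLayer,
    generalized: VectorLayer,
    min_area: float = 1.0,
    alloc_res: float = 0.5,
    mouth_gap_km: float = 3.0,
) -> list[CEP]:
    """Connected components of (generalized minus coast) as CEPs.

    Components with more than one opening to the open sea are partitioned
    by Euclidean allocation to the nearest mouth segment. Components
    touching the domain edge are flagged.
    """
    land = ensure_valid(unary_union(coast.geometries))
    gen = ensure_valid(unary_union(generalized.geometries))
    indents = gen.difference(land)
    gen_boundary = gen.boundary
    domain_minx, domain_miny, domain_maxx, domain_maxy = gen.bounds

    ceps: list[CEP] = []
    next_id = 1
    for comp in polygon_parts(indents):
        if comp.area < min_area:
            continue
        mouth = _mouth_of(comp, gen_boundary)
        mouths = _cluster_mouth_segments(mouth, mouth_gap_km)
        if len(mouths) > 1:
            pieces = _allocate_split(comp, mouths, alloc_res)
        else:
            pieces = [(comp, mouth if mouths else mouth)]
        for geom, m in pieces:
            if geom.area < min_area:
                continue
            minx, miny, maxx, maxy = geom.bounds
            tol = alloc_res
            edge = (
                minx - domain_minx < tol
                or domain_maxx - maxx < tol
                or miny - domain_miny < tol
                or domain_maxy - maxy < tol
            )
            ceps.append(
                CEP(id=next_id, geometry=geom, mouth=m, edge_flag=bool(edge))
            )
            next_id += 1
    logger.info("extracted %d embayments (min_area=%.2f km2)", len(ceps), min_area)
    return ceps


def filter_ceps(
    ceps: list[CEP],
    landmasses: VectorLayer,
    mangrove_extent: VectorLayer | BaseGeometry,
    min_landmass_km2: float = 30.0,
    max_dist_km: float = 20.0,
) -> list[CEP]:
    """Keep CEPs on large-enough landmasses near the mangrove extent."""
    if mangrove_extent is None:
        raise MangroveTypologyError("mangrove extent layer is required")
    if isinstance(mangrove_extent, VectorLayer):
        if len(mangrove_extent) == 0:
            raise MangroveTypologyError("mangrove extent layer is empty")
        mang = unary_union(mangrove_extent.geometries)
    else:
        mang = mangrove_extent
    land_geoms = landmasses.geometries
    land_areas = [
        attrs.get("area_km2", geom.area) for geom, attrs in landmasses.features
    ]
    kept = []
    for cep in ceps:
        dists = [cep.geometry.distance(g) for g in land_geoms]
        i = int(np.argmin(dists)) if dists else -1
        cep.source_landmass_area = float(land_areas[i]) if i >= 0 else 0.0
        cep.dist_to_mangrove = float(cep.geometry.distance(mang))
        if (
            cep.source_landmass_area >= min_landmass_km2
            and cep.dist_to_mangrove <= max_dist_km
        ):
            kept.append(cep)
    logger.info("filtered CEPs: %d -> %d", len(ceps), len(kept))
    return kept


def ceps_to_layer(ceps: list[CEP]) -> VectorLayer:
    layer = VectorLayer(geometry_type="polygon")
    for cep in ceps:
        layer.add(
            cep.geometry,
            id=cep.id,
            **{"class": cep.cep_class},
            mouth_length_km=cep.mouth_length_km,
            landmass_km2=cep.source_landmass_area,
            dist_km=cep.dist_to_mangrove,
            provenance=cep.provenance,
        )
    return layer
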
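"""Attribution of mangrove patches to typological units.

Three stages mirror the stepwise attribution aims: (1) split patches that
straddle several CEPs along the Euclidean-allocation boundary so each patch
meets at most one CEP; (2) assign directly intersecting patches; (3) assign
orphans by catchment containment, then proximity, falling back to open
coast. Finally patches are merged into typological units with per-timestep
areas and regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .cep_builder import CEP
from .cep_covariates import Catchment
from .errors import MangroveTypologyError
from .geo_core import RasterField, VectorLayer, covered_cells, ensure_valid, logger

CEP_CLASS_TO_TYPE = {
    "delta": "deltaic",
    "estuary": "estuarine",
    "lagoon": "lagoonal",
    "bay": "open_coast",
}

#: single-CEP patches above this area only warn (criterion unstated upstream)
VERY_LARGE_PATCH_KM2 = 7000.0


@dataclass
class Patch:
    patch_id: int
    geometry: BaseGeometry
    attrs: dict = field(default_factory=dict)


@dataclass
class Assignment:
    patch: Patch
    geomorphic_type: str
    cep_id: int | None
    path: str  # direct | catchment | distance | fallback


@dataclass
class TypologyUnit:
    unit_id: int
    geometry: BaseGeometry
    geomorphic_type: str
    sediment_type: str = "pending"
    cep_id: int | None = None
    region: str = "global"
    area_by_timestep: dict = field(default_factory=dict)
    mean_agb: float | None = None
    member_patch_ids: list = field(default_factory=list)
    sediment_prob: float | None = None


def _layer_to_patches(layer: VectorLayer) -> list[Patch]:
    out = []
    for i, (geom, attrs) in enumerate(layer.features):
        out.append(Patch(attrs.get("patch_id", i + 1), geom, dict(attrs)))
    return out


def _intersecting_ceps(geom: BaseGeometry, ceps: list[CEP]) -> list[CEP]:
    hits = []
    for cep in ceps:
        if geom.intersects(cep.geometry):
            inter = geom.intersection(cep.geometry)
            if inter.area > 0:  # touching boundaries do not count
                hits.append(cep)
    return hits


def split_patches(
    patches: VectorLayer | list[Patch], ceps: list[CEP], alloc_res: float = 0.5
) -> list[Patch]:
    """Split multi-CEP patches by nearest-CEP allocation; conserve area.

    Each straddling patch is diced into raster-cell pieces, each piece owned
    by the CEP nearest its cell centre, and the pieces are dissolved per
    owner. Output patch ids extend the input ids.
    """
    if isinstance(patches, VectorLayer):
        patches = _layer_to_patches(patches)
    if not ceps:
        return list(patches)
    out: list[Patch] = []
    next_id = max((p.patch_id for p in patches), default=0) + 1
    for patch in patches:
        hits = _intersecting_ceps(patch.geometry, ceps)
        if len(hits) <= 1:
            if patch.geometry.area > VERY_LARGE_PATCH_KM2:
                logger.warning(
                    "patch %d is very large (%.0f km2); not split",
                    patch.patch_id,
                    patch.geometry.area,
                )
            out.append(patch)
            continue
        pieces = _allocation_pieces(patch.geometry, hits, alloc_res)
        total = sum(g.area for g, _ in pieces)
        if abs(total - patch.geometry.area) > 1e-6 * max(patch.geometry.area, 1.0):
            raise MangroveTypologyError(
                f"area not conserved splitting patch {patch.patch_id}"
            )
        for k, (geom, cep) in enumerate(pieces):
            geom = ensure_valid(geom)
            attrs = dict(patch.attrs)
            attrs["parent_patch_id"] = patch.patch_id
            attrs["alloc_cep_id"] = cep.id
            pid = patch.patch_id if k == 0 else next_id
            if k > 0:
                next_id += 1
            attrs["patch_id"] = pid
            out.append(Patch(pid, geom, attrs))
    return out


def _allocation_pieces(geom, ceps, alloc_res):
    """Cut ``geom`` into per-CEP pieces along the nearest-CEP boundary."""
    minx, miny, maxx, maxy = geom.bounds
    pad = alloc_res
    nx = max(int(np.ceil((maxx - minx + 2 * pad) / alloc_res)), 1)
    ny = max(int(np.ceil((maxy - miny + 2 * pad) / alloc_res)), 1)
    template = RasterField(np.zeros((ny, nx)), (minx - pad, maxy + pad), alloc_res)
    rows, cols = covered_cells(geom, template)
    # cover every part of the patch: cells whose centre is outside still get
    # assigned via the cell polygon intersection below
    all_rows, all_cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    all_rows, all_cols = all_rows.ravel(), all_cols.ravel()
    x0, y0 = template.origin
    xs = x0 + (all_cols + 0.5) * alloc_res
    ys = y0 - (all_rows + 0.5) * alloc_res
    from shapely import points as shp_points

    pts = shp_points(np.column_stack([xs, ys]))
    dists = np.column_stack([[c.geometry.distance(p) for p in pts] for c in ceps])
    owner = dists.argmin(axis=1)
    pieces = []
    for k, cep in enumerate(ceps):
        sel = owner == k
        if not sel.any():
            continue
        from .geo_core import cells_to_polygon

        cellpoly = cells_to_polygon(all_rows[sel], all_cols[sel], template)
        part = cellpoly.intersection(geom)
        if part.is_empty or part.area == 0:
            continue
        pieces.append((part, cep))
    return pieces


def assign_direct(
    patches: list[Patch], ceps: list[CEP], delta_units=None
) -> tuple[list[Assignment], list[Patch]]:
    """Assign patches that overlap a CEP; return (assignments, orphans)."""
    delta_unit_by_cep = {}
    for unit in delta_units or []:
        for cid in unit.member_cep_ids:
            delta_unit_by_cep[cid] = unit
    assignments, orphans = [], []
    for patch in patches:
        hits = _intersecting_ceps(patch.geometry, ceps)
        if len(hits) > 1:
            raise MangroveTypologyError(
                f"patch {patch.patch_id} still intersects {len(hits)} CEPs; "
                "split contract violated"
            )
        if not hits:
            orphans.append(patch)
            continue
        cep = hits[0]
        gtype = CEP_CLASS_TO_TYPE.get(cep.cep_class)
        if gtype is None:
            raise MangroveTypologyError(
                f"CEP {cep.id} unclassified ({cep.cep_class}); classify first"
            )
        assignments.append(Assignment(patch, gtype, cep.id, "direct"))
    return assignments, orphans


def assign_orphans(
    patches: list[Patch],
    ceps: list[CEP],
    catchments: dict[int, Catchment] | None,
    max_dist_km: float = 20.0,
) -> list[Assignment]:
    """Assign non-intersecting patches by catchment, then distance.

    A patch inside the catchment of one or more CEPs inherits the nearest
    such CEP's type; otherwise the nearest CEP within ``max_dist_km``;
    otherwise open coast with no CEP. Ties break toward the catchment-
    sharing CEP, then the lower CEP id (logged).
    """
    catchments = catchments or {}
    out = []
    for patch in patches:
        rep = patch.geometry.representative_point()
        containing = [
            cep
            for cep in ceps
            if cep.id in catchments
            and not catchments[cep.id].geometry.is_empty
            and catchments[cep.id].geometry.contains(rep)
        ]
        chosen, path = None, "fallback"
        if containing:
            dists = [(patch.geometry.distance(c.geometry), c.id, c) for c in containing]
            dists.sort(key=lambda t: (t[0], t[1]))
            if len(dists) > 1 and dists[0][0] == dists[1][0]:
                logger.info(
                    "patch %d equidistant CEPs; lower id %d wins",
                    patch.patch_id,
                    dists[0][1],
                )
            chosen, path = dists[0][2], "catchment"
        else:
            dists = [(patch.geometry.distance(c.geometry), c.id, c) for c in ceps]
            dists.sort(key=lambda t: (t[0], t[1]))
            if dists and dists[0][0] <= max_dist_km:
                chosen, path = dists[0][2], "distance"
        if chosen is None:
            out.append(Assignment(patch, "open_coast", None, "fallback"))
        else:
            gtype = CEP_CLASS_TO_TYPE.get(chosen.cep_class)
            if gtype is None:
                raise MangroveTypologyError(f"CEP {chosen.id} unclassified")
            out.append(Assignment(patch, gtype, chosen.id, path))
    return out


def finalize_units(
    assignments: list[Assignment],
    extents_by_timestep: dict[str, VectorLayer],
    regions: VectorLayer | None = None,
) -> list[TypologyUnit]:
    """Merge same-type patches sharing a CEP; compute per-timestep areas.

    Region comes from majority-area overlap with the region layer (or
    "global" if none supplied).
    """
    groups: dict[tuple, list[Assignment]] = {}
    for a in assignments:
        if a.geomorphic_type is None:
            raise MangroveTypologyError(f"patch {a.patch.patch_id} unassigned")
        key = (a.geomorphic_type, a.cep_id) if a.cep_id is not None else (
            a.geomorphic_type,
            f"patch-{a.patch.patch_id}",
        )
        groups.setdefault(key, []).append(a)
    units = []
    uid = 0
    for (gtype, _key), group in sorted(
        groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        uid += 1
        geom = unary_union([a.patch.geometry for a in group])
        unit = TypologyUnit(
            unit_id=uid,
            geometry=geom,
            geomorphic_type=gtype,
            cep_id=group[0].cep_id,
            member_patch_ids=[a.patch.patch_id for a in group],
        )
        for label, layer in extents_by_timestep.items():
            ext = unary_union(layer.geometries) if len(layer) else None
            unit.area_by_timestep[label] = (
                float(geom.intersection(ext).area) if ext is not None else 0.0
            )
        if regions is not None and len(regions):
            overlaps = [
                (geom.intersection(rg).area, attrs.get("region", "global"))
                for rg, attrs in regions.features
                if geom.intersects(rg)
            ]
            if overlaps:
                unit.region = max(overlaps)[1]
        units.append(unit)
    logger.info("finalized %d typological units from %d patches",
                len(units), len(assignments))
    return units


def assign_all(
    patch_layer: VectorLayer,
    ceps: list[CEP],
    delta_units,
    catchments: dict[int, Catchment] | None,
    extents_by_timestep: dict[str, VectorLayer],
    regions: VectorLayer | None = None,
    max_dist_km: float = 20.0,
) -> tuple[list[TypologyUnit], list[Assignment]]:
    """Full attribution pipeline: split, direct, orphans, finalize."""
    patches = split_patches(patch_layer, ceps)
    direct, orphans = assign_direct(patches, ceps, delta_units)
    rest = assign_orphans(orphans, ceps, catchments, max_dist_km)
    assignments = direct + rest
    units = finalize_units(assignments, extents_by_timestep, regions)
    return units, assignments
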
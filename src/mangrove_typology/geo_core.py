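"""Shared geometry and raster primitives.

All coordinates live in a planar equal-area frame with km units, so polygon
area in frame units is area in km². Rasters use the upper-left-origin,
half-open pixel convention: cell (row, col) covers
``[x0 + col*cell, x0 + (col+1)*cell) x (y0 - (row+1)*cell, y0 - row*cell]``
and point lookups are by containing cell (no interpolation).

Vector I/O is GeoJSON (text); raster I/O is ESRI ASCII grid (single band,
text) or TIFF with a JSON sidecar description (multi-band).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .errors import GeometryError, IOFormatError, UndefinedValueError

logger = logging.getLogger("mangrove_typology")

_GEOM_FAMILY = {
    "Polygon": "polygon",
    "MultiPolygon": "polygon",
    "LineString": "polyline",
    "MultiLineString": "polyline",
    "Point": "point",
    "MultiPoint": "point",
}


# ---------------------------------------------------------------------------
# Vector layers
# ---------------------------------------------------------------------------

@dataclass
class VectorLayer:
    """A list of (geometry, attributes) features of one geometry family."""

    features: list[tuple[BaseGeometry, dict]] = field(default_factory=list)
    geometry_type: str | None = None  # polygon | polyline | point

    def __post_init__(self) -> None:
        if self.geometry_type is None and self.features:
            self.geometry_type = _GEOM_FAMILY[self.features[0][0].geom_type]
        for i, (geom, _) in enumerate(self.features):
            fam = _GEOM_FAMILY.get(geom.geom_type)
            if fam != self.geometry_type:
                raise IOFormatError(
                    f"mixed geometry types: feature {i} is {geom.geom_type}, "
                    f"layer is {self.geometry_type}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]

    def add(self, geom: BaseGeometry, **attrs) -> None:
        fam = _GEOM_FAMILY.get(geom.geom_type)
        if self.geometry_type is None:
            self.geometry_type = fam
        if fam != self.geometry_type:
            raise IOFormatError(
                f"mixed geometry types: got {geom.geom_type} in a "
                f"{self.geometry_type} layer"
            )
        self.features.append((geom, dict(attrs)))


def read_vector(path: str | Path) -> VectorLayer:
    """Read a GeoJSON FeatureCollection into a :class:`VectorLayer`."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"vector file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IOFormatError(f"cannot parse {path} as GeoJSON: {exc}") from exc
    if data.get("type") != "FeatureCollection":
        raise IOFormatError(f"{path}: expected a GeoJSON FeatureCollection")
    layer = VectorLayer()
    for i, feat in enumerate(data.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # malformed geometry dict
            raise IOFormatError(f"{path}: feature {i} has bad geometry: {exc}") from exc
        if not geom.is_valid:
            geom = make_valid(geom)
        layer.add(geom, **feat.get("properties", {}))
    return layer


def write_vector(layer: VectorLayer, path: str | Path) -> None:
    """Write a layer as a GeoJSON FeatureCollection (full float precision)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOFormatError(f"parent directory does not exist: {path.parent}")
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
        for geom, attrs in layer.features
    ]
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Raster fields
# ---------------------------------------------------------------------------

@dataclass
class RasterField:
    """A gridded field: ``values[band, row, col]`` with row 0 at the top.

    ``origin`` is the (x, y) of the upper-left corner of pixel (0, 0);
    ``cell`` is the square cell size in km.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell: float
    nodata: float = -9999.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[np.newaxis, :, :]
        if self.values.ndim != 3:
            raise IOFormatError("raster values must be 2-D or 3-D (band, row, col)")
        if self.cell <= 0:
            raise IOFormatError("raster cell size must be > 0")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def band(self, i: int) -> np.ndarray:
        return self.values[i]

    def valid_mask(self, band: int = 0) -> np.ndarray:
        v = self.values[band]
        return ~np.isclose(v, self.nodata) & np.isfinite(v)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell))
        row = int(math.floor((y0 - y) / self.cell))
        return row, col

    def in_bounds(self, row: int, col: int) -> bool:
        ny, nx = self.shape
        return 0 <= row < ny and 0 <= col < nx

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell, y0 - (row + 0.5) * self.cell)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of all cell-centre coordinates, shape (ny, nx)."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell
        ys = y0 - (np.arange(ny) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def cell_polygon(self, row: int, col: int):
        from shapely.geometry import box

        x0, y0 = self.origin
        return box(
            x0 + col * self.cell,
            y0 - (row + 1) * self.cell,
            x0 + (col + 1) * self.cell,
            y0 - row * self.cell,
        )

    def sample_nearest(
        self, x: float, y: float, band: int = 0, search_radius_km: float = 10.0
    ) -> float | None:
        """Value of the nearest valid cell to (x, y) within a search radius.

        The containing cell wins if valid; otherwise cells are scanned in
        expanding rings and the valid cell with the smallest centre-to-point
        distance is returned. ``None`` if no valid cell within the radius.
        """
        row, col = self.xy_to_rowcol(x, y)
        mask = self.valid_mask(band)
        if self.in_bounds(row, col) and mask[row, col]:
            return float(self.values[band, row, col])
        max_ring = int(math.ceil(search_radius_km / self.cell)) + 1
        best: tuple[float, float] | None = None
        for ring in range(1, max_ring + 1):
            cand: list[tuple[float, float]] = []
            for r in range(row - ring, row + ring + 1):
                for c in range(col - ring, col + ring + 1):
                    if max(abs(r - row), abs(c - col)) != ring:
                        continue
                    if self.in_bounds(r, c) and mask[r, c]:
                        cx, cy = self.cell_center(r, c)
                        d = math.hypot(cx - x, cy - y)
                        if d <= search_radius_km:
                            cand.append((d, float(self.values[band, r, c])))
            if cand:
                ring_best = min(cand)
                if best is None or ring_best[0] < best[0]:
                    best = ring_best
                # one extra ring guards against diagonal-vs-axial distance
                if best is not None and ring >= 1 and best[0] <= ring * self.cell:
                    return best[1]
        return best[1] if best is not None else None

    def band_mean(self, band: int = 0) -> float:
        mask = self.valid_mask(band)
        if not mask.any():
            raise UndefinedValueError("mean over all-nodata raster band")
        return float(self.values[band][mask].mean())


def read_raster(path: str | Path) -> RasterField:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"raster file not found: {path}")
    if path.suffix.lower() == ".asc":
        return _read_ascii_grid(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path)
    raise IOFormatError(f"unsupported raster format: {path} (use .asc or .tif)")


def write_raster(fieldr: RasterField, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOFormatError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() == ".asc":
        _write_ascii_grid(fieldr, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(fieldr, path)
    else:
        raise IOFormatError(f"unsupported raster format: {path} (use .asc or .tif)")


def _read_ascii_grid(path: Path) -> RasterField:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
        xll = header["xllcorner"]
        yll = header["yllcorner"]
    except KeyError as exc:
        raise IOFormatError(f"{path}: missing ASCII grid header key {exc}") from exc
    nodata = header.get("nodata_value", -9999.0)
    values = np.array(rows, dtype=float)
    if values.shape != (nrows, ncols):
        raise IOFormatError(
            f"{path}: grid shape {values.shape} != header ({nrows}, {ncols})"
        )
    return RasterField(values, (xll, yll + nrows * cell), cell, nodata=nodata)


def _write_ascii_grid(fieldr: RasterField, path: Path) -> None:
    if fieldr.n_bands != 1:
        raise IOFormatError("ASCII grid supports a single band; use .tif")
    ny, nx = fieldr.shape
    x0, y0 = fieldr.origin
    lines = [
        f"ncols {nx}",
        f"nrows {ny}",
        f"xllcorner {float(x0)!r}",
        f"yllcorner {float(y0 - ny * fieldr.cell)!r}",
        f"cellsize {float(fieldr.cell)!r}",
        f"NODATA_value {float(fieldr.nodata)!r}",
    ]
    for row in fieldr.values[0]:
        lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _write_tiff(fieldr: RasterField, path: Path) -> None:
    import tifffile

    meta = {
        "origin": list(fieldr.origin),
        "cell": fieldr.cell,
        "nodata": fieldr.nodata,
        "units": fieldr.units,
    }
    tifffile.imwrite(path, fieldr.values, description=json.dumps(meta))


def _read_tiff(path: Path) -> RasterField:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if "origin" not in meta:
        raise IOFormatError(f"{path}: TIFF lacks the JSON geotransform description")
    return RasterField(
        values,
        tuple(meta["origin"]),
        float(meta["cell"]),
        nodata=float(meta.get("nodata", -9999.0)),
        units=meta.get("units", ""),
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def ensure_valid(geom: BaseGeometry) -> BaseGeometry:
    """Return a valid geometry, attempting one repair; raise if impossible."""
    if geom.is_valid:
        return geom
    repaired = make_valid(geom)
    if not repaired.is_valid:
        raise GeometryError(f"geometry invalid after repair: {geom.geom_type}")
    return repaired


def area_km2(geom: BaseGeometry) -> float:
    """Area in km² of a geometry in the planar equal-area frame."""
    geom = ensure_valid(geom)
    return float(geom.area)


def polygon_parts(geom: BaseGeometry) -> list:
    """Flatten a (multi)polygon / collection into its polygonal parts."""
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        parts = []
        for g in geom.geoms:
            parts.extend(polygon_parts(g))
        return parts
    return []


def line_parts(geom: BaseGeometry) -> list:
    if geom.is_empty:
        return []
    if geom.geom_type == "LineString":
        return [geom]
    if geom.geom_type in ("MultiLineString", "GeometryCollection"):
        parts = []
        for g in geom.geoms:
            parts.extend(line_parts(g))
        return parts
    return []


def covered_cells(
    geom: BaseGeometry, template: RasterField
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of template cells whose centres fall inside ``geom``."""
    from shapely import contains_xy, prepare

    minx, miny, maxx, maxy = geom.bounds
    r0, c0 = template.xy_to_rowcol(minx, maxy)
    r1, c1 = template.xy_to_rowcol(maxx, miny)
    ny, nx = template.shape
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, ny - 1), min(c1, nx - 1)
    if r1 < r0 or c1 < c0:
        return np.array([], dtype=int), np.array([], dtype=int)
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cgrid, rgrid = np.meshgrid(cols, rows)
    x0, y0 = template.origin
    xs = x0 + (cgrid + 0.5) * template.cell
    ys = y0 - (rgrid + 0.5) * template.cell
    prepare(geom)
    inside = contains_xy(geom, xs.ravel(), ys.ravel()).reshape(rgrid.shape)
    return rgrid[inside], cgrid[inside]


def cells_to_polygon(
    rows: Iterable[int], cols: Iterable[int], template: RasterField
):
    """Union of whole raster cells (row, col) as one (multi)polygon."""
    from shapely import box as shp_box
    from shapely.ops import unary_union

    x0, y0 = template.origin
    cell = template.cell
    boxes = [
        shp_box(
            x0 + c * cell, y0 - (r + 1) * cell, x0 + (c + 1) * cell, y0 - r * cell
        )
        for r, c in zip(rows, cols)
    ]
    if not boxes:
        from shapely.geometry import Polygon

        return Polygon()
    return unary_union(boxes)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (matches printed-table rounding)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
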
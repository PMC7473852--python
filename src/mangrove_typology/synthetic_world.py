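"""Synthetic coastal world generator with known ground truth.

Builds a planar (km-unit) scene: a rectangular landmass whose northern edge
is the coast, with planted embayments of four classes carved into it —

* **bays**: simple rectangular indents, mouth as wide as the interior;
* **estuaries**: funnel indents tapering inland, fed by one trunk river with
  a chain of upstream watersheds;
* **lagoons**: shore-parallel basins connected to the sea by a narrow inlet,
  with no river;
* **deltas**: gently protruding coastal fans with a distributary channel
  carved through the crest and >2 river outlets fanning into it.

Mangrove patches fringe each embayment (straddling the land/water boundary)
plus a few open-coast strips. Rasters (monthly precipitation, M2 tide, SPM,
AGB) share one grid. Truth labels record the planted classes, sediment
settings, loss rates and AGB means so downstream stages can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import nearest_points, unary_union

from .errors import ConfigError
from .geo_core import (
    RasterField,
    VectorLayer,
    cells_to_polygon,
    covered_cells,
    logger,
)

GEOMORPHIC_TYPES = ("deltaic", "estuarine", "lagoonal", "open_coast")
EMBAYMENT_CLASSES = ("delta", "estuary", "lagoon", "bay")
SEDIMENT_CLASSES = ("terrigenous", "carbonate")

#: embayment class -> geomorphic type of mangroves attached to it
CLASS_TO_TYPE = {
    "delta": "deltaic",
    "estuary": "estuarine",
    "lagoon": "lagoonal",
    "bay": "open_coast",
}


@dataclass
class SceneConfig:
    """Knobs for :func:`generate_scene`; all distances in km."""

    n_deltas: int = 3
    n_estuaries: int = 3
    n_lagoons: int = 3
    n_bays: int = 3
    cell_km: float = 0.5
    spacing_km: float = 40.0
    margin_km: float = 25.0
    land_depth_km: float = 50.0
    sea_width_km: float = 25.0

    # per-class geometry ranges (sampled uniformly)
    bay_width: tuple[float, float] = (9.0, 16.0)
    bay_depth: tuple[float, float] = (4.0, 8.0)
    estuary_mouth: tuple[float, float] = (6.0, 11.0)
    estuary_depth: tuple[float, float] = (15.0, 24.0)
    lagoon_length: tuple[float, float] = (10.0, 20.0)
    lagoon_width: tuple[float, float] = (2.5, 4.0)
    lagoon_inlet: tuple[float, float] = (0.9, 1.4)
    lagoon_offset_km: float = 2.0
    delta_bump_height: tuple[float, float] = (4.0, 5.5)
    delta_bump_halfwidth: tuple[float, float] = (13.0, 16.0)
    delta_mouth: tuple[float, float] = (5.0, 7.5)
    n_distributaries: tuple[int, int] = (3, 5)

    mangrove_fringe_km: float = 1.5
    mangrove_overlap_km: float = 0.8
    n_open_coast_strips: int = 2
    strip_length_km: float = 8.0

    timesteps: dict = field(
        default_factory=lambda: {"1996": 1996, "2007": 2007, "2010": 2010, "2016": 2016}
    )
    loss_rate: dict = field(
        default_factory=lambda: {
            "deltaic": 0.04,
            "estuarine": 0.035,
            "lagoonal": 0.069,
            "open_coast": 0.03,
        }
    )
    sediment_beta: tuple[float, float, float] = (-9.0, 6.0, 0.35)
    agb_mean: dict = field(
        default_factory=lambda: {
            "deltaic": 117.3,
            "estuarine": 126.3,
            "lagoonal": 73.5,
            "open_coast": 111.5,
        }
    )
    agb_sd: dict = field(
        default_factory=lambda: {
            "deltaic": 73.6,
            "estuarine": 76.3,
            "lagoonal": 59.8,
            "open_coast": 73.7,
        }
    )

    def validate(self) -> None:
        for name in ("n_deltas", "n_estuaries", "n_lagoons", "n_bays"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cell_km <= 0:
            raise ConfigError(f"cell_km must be > 0, got {self.cell_km}")
        for t, r in self.loss_rate.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"loss_rate[{t}]={r} outside [0, 1]")

    @property
    def n_embayments(self) -> int:
        return self.n_deltas + self.n_estuaries + self.n_lagoons + self.n_bays

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in raw.items():
            default = getattr(cls(), k)
            kwargs[k] = tuple(v) if isinstance(default, tuple) else v
        return cls(**kwargs)


@dataclass
class TruthLabels:
    embayment_class: dict = field(default_factory=dict)  # emb_id -> class
    sediment_class: dict = field(default_factory=dict)  # patch_id -> setting
    agb_mean: dict = field(default_factory=dict)  # type -> Mg/ha
    loss_rate: dict = field(default_factory=dict)  # type -> fraction

    def validate(self) -> None:
        bad = set(self.embayment_class.values()) - set(EMBAYMENT_CLASSES)
        if bad:
            raise ConfigError(f"unknown embayment classes in truth: {bad}")
        bad = set(self.sediment_class.values()) - set(SEDIMENT_CLASSES)
        if bad:
            raise ConfigError(f"unknown sediment classes in truth: {bad}")
        for t, r in self.loss_rate.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"loss_rate[{t}]={r} outside [0, 1]")


@dataclass
class CoastScene:
    """One synthetic study area with rasters, vectors and truth labels."""

    config: SceneConfig
    coastline: VectorLayer  # land polygons
    flowlines: VectorLayer  # attrs: fid, next_fid (-1 = sea outlet), outlet_x/y
    watersheds: VectorLayer  # attrs: wid, fid
    embayments: VectorLayer  # planted indent polygons; attrs: emb_id, cls
    patches: VectorLayer  # baseline mangrove patches; attrs: patch_id, truth_type, emb_id
    precip: RasterField | None = None
    tide: RasterField | None = None
    spm: RasterField | None = None
    agb: RasterField | None = None
    extents: dict = field(default_factory=dict)  # timestep label -> VectorLayer
    truth: TruthLabels = field(default_factory=TruthLabels)

    @property
    def land(self):
        return unary_union(self.coastline.geometries)

    def mangrove_union(self):
        geoms = []
        for layer in self.extents.values():
            geoms.extend(layer.geometries)
        if not geoms:
            geoms = self.patches.geometries
        return unary_union(geoms)

    def raster_template(self) -> RasterField:
        c = self.config
        w = 2 * c.margin_km + c.spacing_km * max(c.n_embayments, 1)
        h = c.land_depth_km + c.sea_width_km
        nx = int(round(w / c.cell_km))
        ny = int(round(h / c.cell_km))
        return RasterField(np.zeros((ny, nx)), (0.0, h), c.cell_km)


# ---------------------------------------------------------------------------
# embayment geometry builders (one per class)
# ---------------------------------------------------------------------------

def _build_bay(cx: float, H: float, cfg: SceneConfig, rng) -> dict:
    w = rng.uniform(*cfg.bay_width)
    d = rng.uniform(*cfg.bay_depth)
    carve = box(cx - w / 2, H - d, cx + w / 2, H)
    return {"carve": carve, "bump": None, "flowlines": [], "watersheds": []}


def _build_estuary(cx: float, H: float, cfg: SceneConfig, rng, fid0: int) -> dict:
    w = rng.uniform(*cfg.estuary_mouth)
    d = rng.uniform(*cfg.estuary_depth)
    head_w = 0.8
    carve = Polygon(
        [
            (cx - w / 2, H),
            (cx + w / 2, H),
            (cx + head_w / 2, H - d),
            (cx - head_w / 2, H - d),
        ]
    )
    # trunk river with two chained upstream segments and their watersheds
    head = (cx, H - d + 0.3)
    seg_len = (H - d) / 3.0
    pts = [
        (cx, H - d - 3 * seg_len + 0.5),
        (cx + rng.uniform(-2, 2), H - d - 2 * seg_len),
        (cx + rng.uniform(-2, 2), H - d - seg_len),
        head,
    ]
    flows, sheds = [], []
    # most upstream first; each drains into the next (downstream pointer)
    for i in range(3):
        fid = fid0 + i
        nxt = fid + 1 if i < 2 else -1
        line = LineString([pts[i], pts[i + 1]])
        attrs = {"fid": fid, "next_fid": nxt}
        if nxt == -1:
            attrs["outlet_x"], attrs["outlet_y"] = head
        flows.append((line, attrs))
        shed = box(
            min(pts[i][0], pts[i + 1][0]) - 6,
            min(pts[i][1], pts[i + 1][1]),
            max(pts[i][0], pts[i + 1][0]) + 6,
            max(pts[i][1], pts[i + 1][1]),
        )
        sheds.append((shed, {"fid": fid}))
    return {"carve": carve, "bump": None, "flowlines": flows, "watersheds": sheds}


def _build_lagoon(cx: float, H: float, cfg: SceneConfig, rng) -> dict:
    length = rng.uniform(*cfg.lagoon_length)
    width = rng.uniform(*cfg.lagoon_width)
    inlet_w = rng.uniform(*cfg.lagoon_inlet)
    off = cfg.lagoon_offset_km
    basin = box(cx - length / 2, H - off - width, cx + length / 2, H - off)
    inlet_cx = cx + rng.uniform(-length / 4, length / 4)
    inlet = box(inlet_cx - inlet_w / 2, H - off, inlet_cx + inlet_w / 2, H)
    return {
        "carve": unary_union([basin, inlet]),
        "bump": None,
        "flowlines": [],
        "watersheds": [],
    }


def _bump_polygon(cx: float, H: float, a: float, b: float) -> Polygon:
    """Smooth coastal fan: y = H + b*cos²(πx'/2a), tangent to the coast."""
    xs = np.linspace(cx - a, cx + a, 121)
    top = [(x, H + b * math.cos(math.pi * (x - cx) / (2 * a)) ** 2) for x in xs]
    return Polygon([(cx - a, H - 0.5)] + top + [(cx + a, H - 0.5)])


def _build_delta(cx: float, H: float, cfg: SceneConfig, rng, fid0: int) -> dict:
    a = rng.uniform(*cfg.delta_bump_halfwidth)
    b = rng.uniform(*cfg.delta_bump_height)
    mouth_w = rng.uniform(*cfg.delta_mouth)
    k = int(rng.integers(cfg.n_distributaries[0], cfg.n_distributaries[1] + 1))
    bump = _bump_polygon(cx, H, a, b)
    head_depth = 2.5
    carve = Polygon(
        [
            (cx - mouth_w / 2, H + b + 1.0),
            (cx + mouth_w / 2, H + b + 1.0),
            (cx + 0.8, H - head_depth),
            (cx - 0.8, H - head_depth),
        ]
    )
    junction = (cx, H - head_depth - 0.5)
    flows, sheds = [], []
    trunk_src = (cx + rng.uniform(-3, 3), H - head_depth - 18)
    trunk_fid = fid0
    flows.append(
        (
            LineString([trunk_src, junction]),
            {"fid": trunk_fid, "next_fid": fid0 + 1},
        )
    )
    sheds.append(
        (
            box(
                min(trunk_src[0], cx) - 7,
                trunk_src[1],
                max(trunk_src[0], cx) + 7,
                junction[1],
            ),
            {"fid": trunk_fid},
        )
    )
    # distributary outlets fan across the channel at mid-bump height
    out_y = H + 0.45 * b
    half_at = 0.8 + (mouth_w / 2 - 0.8) * ((out_y - (H - head_depth)) / (b + 1 + head_depth))
    out_xs = np.linspace(cx - 0.85 * half_at, cx + 0.85 * half_at, k)
    for i, ox in enumerate(out_xs):
        fid = fid0 + 1 + i
        attrs = {"fid": fid, "next_fid": -1, "outlet_x": ox, "outlet_y": out_y}
        flows.append((LineString([junction, (ox, out_y)]), attrs))
    # trunk drains into the first distributary; re-point its next_fid
    flows[0][1]["next_fid"] = fid0 + 1
    return {"carve": carve, "bump": bump, "flowlines": flows, "watersheds": sheds}


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def generate_scene(config: SceneConfig, seed: int) -> CoastScene:
    """Build a complete scene (geometry, rasters, timesteps, truth labels).

    Identical ``(config, seed)`` pairs reproduce bit-identical scenes.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    H = config.land_depth_km
    n = config.n_embayments
    W = 2 * config.margin_km + config.spacing_km * max(n, 1)

    classes = (
        ["delta"] * config.n_deltas
        + ["estuary"] * config.n_estuaries
        + ["lagoon"] * config.n_lagoons
        + ["bay"] * config.n_bays
    )
    rng.shuffle(classes)

    base = box(0, 0, W, H)
    carves, bumps = [], []
    flow_layer = VectorLayer(geometry_type="polyline")
    shed_layer = VectorLayer(geometry_type="polygon")
    emb_layer = VectorLayer(geometry_type="polygon")
    truth = TruthLabels(
        loss_rate=dict(config.loss_rate), agb_mean=dict(config.agb_mean)
    )

    fid_counter = 1
    builders = {
        "bay": lambda cx: _build_bay(cx, H, config, rng),
        "lagoon": lambda cx: _build_lagoon(cx, H, config, rng),
        "estuary": lambda cx: _build_estuary(cx, H, config, rng, fid_counter),
        "delta": lambda cx: _build_delta(cx, H, config, rng, fid_counter),
    }
    parts = []
    for i, cls in enumerate(classes):
        cx = config.margin_km + config.spacing_km * (i + 0.5)
        part = builders[cls](cx)
        part["cls"] = cls
        part["emb_id"] = i + 1
        parts.append(part)
        fid_counter += len(part["flowlines"])
        if part["bump"] is not None:
            bumps.append(part["bump"])
        carves.append(part["carve"])

    land_solid = unary_union([base] + bumps)
    land = land_solid.difference(unary_union(carves)) if carves else land_solid
    coast_layer = VectorLayer(geometry_type="polygon")
    coast_layer.add(land, landmass_id=1, area_km2=float(land.area))

    boundary = land.boundary
    for part in parts:
        indent = part["carve"].intersection(land_solid)
        emb_layer.add(indent, emb_id=part["emb_id"], cls=part["cls"])
        truth.embayment_class[part["emb_id"]] = part["cls"]
        for line, attrs in part["flowlines"]:
            if attrs.get("next_fid") == -1:
                # snap the sea outlet onto the coastline boundary
                raw = Point(attrs["outlet_x"], attrs["outlet_y"])
                snapped = nearest_points(boundary, raw)[0]
                attrs["outlet_x"], attrs["outlet_y"] = snapped.x, snapped.y
                coords = list(line.coords)
                coords[-1] = (snapped.x, snapped.y)
                line = LineString(coords)
            flow_layer.add(line, **attrs)
        for shed, attrs in part["watersheds"]:
            shed_layer.add(shed, **attrs)

    scene = CoastScene(
        config=config,
        coastline=coast_layer,
        flowlines=flow_layer,
        watersheds=shed_layer,
        embayments=emb_layer,
        patches=VectorLayer(geometry_type="polygon"),
        truth=truth,
    )
    template = scene.raster_template()
    _plant_patches(scene, parts, template, rng)
    scene.precip = _precip_raster(template, config, rng)
    generate_sediment_fields(scene, config.sediment_beta, int(rng.integers(2**31)))
    generate_timesteps(scene, config.loss_rate, int(rng.integers(2**31)))
    generate_agb(scene, config.agb_mean, config.agb_sd, int(rng.integers(2**31)))
    scene.truth.validate()
    logger.info(
        "generated scene: %d embayments, %d patches, land %.0f km2",
        n,
        len(scene.patches),
        land.area,
    )
    return scene


def _plant_patches(scene, parts, template: RasterField, rng) -> None:
    cfg = scene.config
    H = cfg.land_depth_km
    W = 2 * cfg.margin_km + cfg.spacing_km * max(cfg.n_embayments, 1)
    pid = 0
    for part in parts:
        indent = part["carve"]
        ring = indent.buffer(cfg.mangrove_fringe_km).difference(
            indent.buffer(-cfg.mangrove_overlap_km)
        )
        rows, cols = covered_cells(ring, template)
        if len(rows) == 0:
            continue
        pid += 1
        poly = cells_to_polygon(rows, cols, template)
        scene.patches.add(
            poly,
            patch_id=pid,
            truth_type=CLASS_TO_TYPE[part["cls"]],
            emb_id=part["emb_id"],
        )
    # open-coast strips live in the far margins, away from any embayment,
    # so the distance-based assignment fallback leaves them open coast
    for j in range(cfg.n_open_coast_strips):
        if j % 2 == 0:
            xs = 2.0 + rng.uniform(0, 2) + (j // 2) * (cfg.strip_length_km + 2)
        else:
            xs = (
                W
                - 2.0
                - cfg.strip_length_km
                - rng.uniform(0, 2)
                - (j // 2) * (cfg.strip_length_km + 2)
            )
        strip = box(xs, H - 1.0, xs + cfg.strip_length_km, H + 0.4)
        rows, cols = covered_cells(strip, template)
        if len(rows) == 0:
            continue
        pid += 1
        poly = cells_to_polygon(rows, cols, template)
        scene.patches.add(poly, patch_id=pid, truth_type="open_coast", emb_id=None)


def _precip_raster(template: RasterField, cfg: SceneConfig, rng) -> RasterField:
    X, Y = template.cell_centers()
    phase = rng.uniform(0, 2 * math.pi)
    wavelen = rng.uniform(150, 400)
    base = 70 + 45 * np.sin(2 * math.pi * X / wavelen + phase) + 0.15 * Y
    base = np.clip(base, 5.0, None)
    months = np.arange(12)
    seasonal = 1.0 + 0.6 * np.cos(2 * math.pi * (months - rng.integers(0, 12)) / 12)
    values = np.stack([base * s for s in seasonal])
    return RasterField(
        values, template.origin, template.cell, nodata=-9999.0, units="mm/month"
    )


def _smooth_field(template, rng, base, amp_range, scale_range, n_bumps=6):
    X, Y = template.cell_centers()
    out = np.full(X.shape, base, dtype=float)
    minx, maxx = X.min(), X.max()
    miny, maxy = Y.min(), Y.max()
    for _ in range(n_bumps):
        cxy = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        amp = rng.uniform(*amp_range)
        s = rng.uniform(*scale_range)
        out += amp * np.exp(-(((X - cxy[0]) ** 2) + (Y - cxy[1]) ** 2) / (2 * s**2))
    return out


def generate_sediment_fields(
    scene: CoastScene, beta: Sequence[float], seed: int
) -> CoastScene:
    """Create smooth tide/SPM rasters and draw per-patch sediment truth.

    ``beta`` are logit-scale coefficients (intercept, tide, SPM) for the
    terrigenous=1 coding; each patch's setting is Bernoulli at its centroid.
    Deltaic/estuarine patches are terrigenous by definition.
    """
    if len(beta) != 3:
        raise ConfigError("sediment beta must be (intercept, tide, spm)")
    rng = np.random.default_rng(seed)
    template = scene.raster_template()
    tide = _smooth_field(template, rng, 0.25, (0.4, 2.2), (35, 90))
    spm = _smooth_field(template, rng, 0.8, (2.0, 14.0), (25, 70))
    scene.tide = RasterField(tide, template.origin, template.cell, units="m")
    scene.spm = RasterField(spm, template.origin, template.cell, units="g m-3")

    b0, bt, bs = beta
    for geom, attrs in scene.patches:
        c = geom.centroid
        tv = scene.tide.sample_nearest(c.x, c.y)
        sv = scene.spm.sample_nearest(c.x, c.y)
        eta = b0 + bt * (tv or 0.0) + bs * (sv or 0.0)
        p_terr = 1.0 / (1.0 + math.exp(-eta))
        if attrs["truth_type"] in ("deltaic", "estuarine"):
            label = "terrigenous"
        else:
            label = "terrigenous" if rng.random() < p_terr else "carbonate"
        scene.truth.sediment_class[attrs["patch_id"]] = label
    return scene


def generate_timesteps(scene: CoastScene, loss_rate: dict, seed: int) -> CoastScene:
    """Erode each patch cell-by-cell to realize per-type loss rates.

    Losses accumulate linearly in time from the first to the last timestep;
    the first timestep equals the baseline, so the union of all timesteps is
    the maximal extent. Erosion removes whole raster cells chosen uniformly
    at random within a patch, so realized loss matches the requested rate to
    within one cell per patch.
    """
    for t, r in loss_rate.items():
        if not (0.0 <= r <= 1.0):
            raise ConfigError(f"loss_rate[{t}]={r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = scene.config
    template = scene.raster_template()
    labels = sorted(cfg.timesteps, key=lambda k: cfg.timesteps[k])
    years = [cfg.timesteps[k] for k in labels]
    span = max(years[-1] - years[0], 1)

    scene.extents = {lab: VectorLayer(geometry_type="polygon") for lab in labels}
    for geom, attrs in scene.patches:
        rows, cols = covered_cells(geom, template)
        ncells = len(rows)
        if ncells == 0:
            continue
        order = rng.permutation(ncells)
        rate = loss_rate.get(attrs["truth_type"], 0.0)
        for lab, yr in zip(labels, years):
            frac = rate * (yr - years[0]) / span
            n_remove = int(round(frac * ncells))
            keep = order[n_remove:]
            if len(keep) == 0:
                continue
            poly = cells_to_polygon(rows[keep], cols[keep], template)
            scene.extents[lab].add(poly, patch_id=attrs["patch_id"])
    scene.truth.loss_rate = dict(loss_rate)
    return scene


def generate_agb(
    scene: CoastScene, means: dict, sds: dict, seed: int
) -> CoastScene:
    """AGB raster over the maximal extent, planted per geomorphic type.

    Each patch draws one square-root-scale level ``mu_p ~ Normal(sqrt(m_t),
    s_t / (2*sqrt(m_t)))`` (delta-method sd, so the between-patch spread of
    patch means approximates the planted original-scale sd ``s_t``); cells
    add only small within-patch noise, keeping the patch mean close to
    ``mu_p²`` and the planted type mean ``m_t``.
    """
    rng = np.random.default_rng(seed)
    template = scene.raster_template()
    values = np.full(template.shape, -9999.0)
    for geom, attrs in scene.patches:
        t = attrs["truth_type"]
        m, s = means[t], sds[t]
        rows, cols = covered_cells(geom, template)
        if len(rows) == 0:
            continue
        mu_p = rng.normal(math.sqrt(m), s / (2 * math.sqrt(m)))
        sqrt_vals = mu_p + rng.normal(0.0, 0.25, size=len(rows))
        values[rows, cols] = np.clip(sqrt_vals, 0.0, None) ** 2
    scene.agb = RasterField(
        values, template.origin, template.cell, nodata=-9999.0, units="Mg ha-1"
    )
    scene.truth.agb_mean = dict(means)
    return scene


def simulate_unit_means(means: dict, sds: dict, n_per_type: int, seed: int):
    """Per-unit mean AGB draws with planted type means and spreads.

    Units are drawn on the square-root scale around ``sqrt(m_t)`` with the
    delta-method sd ``s_t / (2*sqrt(m_t))`` (the same scheme as
    :func:`generate_agb`), so back-transformed type means equal the planted
    means in expectation. Returns (values, types) arrays.
    """
    rng = np.random.default_rng(seed)
    values, types = [], []
    for t in sorted(means):
        m, s = means[t], sds[t]
        draws = rng.normal(math.sqrt(m), s / (2 * math.sqrt(m)), size=n_per_type)
        values.extend(np.clip(draws, 0.0, None) ** 2)
        types.extend([t] * n_per_type)
    return np.asarray(values), np.asarray(types)


def simulate_covariate_table(
    n_per_class: dict, seed: int, overlap: float = 0.0
):
    """Covariate rows drawn from class-dependent shape distributions.

    A fast stand-in for full scene generation when many labelled embayments
    are needed (random-forest experiments): rows mimic the geometry the
    scene builders plant (bays compact with open mouths, estuaries
    elongated with one flowline, lagoons nearly closed). ``overlap`` in
    [0, 1] widens every distribution toward a common one, making classes
    harder to separate.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []

    def mix(a, common):
        return (1 - overlap) * a + overlap * common

    for cls, n in n_per_class.items():
        if cls not in ("bay", "estuary", "lagoon"):
            raise ConfigError(f"simulate_covariate_table covers RF classes only: {cls}")
        for _ in range(n):
            if cls == "bay":
                w = rng.uniform(9, 16)
                d = rng.uniform(4, 8)
                area, mouth = w * d, w
                elong = max(w, d) / min(w, d)
                closure = rng.uniform(0.85, 1.0)
                nflow = 0
                catch = 0.0
            elif cls == "estuary":
                w = rng.uniform(6, 11)
                d = rng.uniform(15, 24)
                area, mouth = 0.5 * w * d, w
                elong = d / (0.5 * w)
                closure = rng.uniform(0.8, 1.0)
                nflow = 1
                catch = rng.uniform(200, 700)
            else:  # lagoon
                L = rng.uniform(10, 20)
                wd = rng.uniform(2.5, 4)
                inlet = rng.uniform(0.9, 1.4)
                area, mouth = L * wd, inlet
                elong = L / wd
                closure = inlet / L
                nflow = 0
                catch = 0.0
            noise = 1 + overlap * rng.normal(0, 0.6)
            area = abs(area * noise) + 1e-3
            perim = 2 * (area / math.sqrt(area) + math.sqrt(area))
            closure = float(np.clip(mix(closure, rng.uniform(0, 1)), 1e-3, 5))
            elong = abs(mix(elong, rng.uniform(1, 10))) + 1.0
            if overlap > 0 and rng.random() < overlap * 0.5:
                nflow = int(rng.integers(0, 2))
            annual = rng.uniform(600, 2400)
            rows.append(
                {
                    "class": cls,
                    "v1_area_km2": area,
                    "v2_perimeter_km": perim,
                    "v3_compactness": float(
                        np.clip(4 * math.pi * area / perim**2, 0.01, 1.0)
                    ),
                    "v4_mouth_width_km": abs(mouth * noise),
                    "v5_elongation": elong,
                    "v6_closure_ratio": closure,
                    "v7_catchment_area_km2": catch * abs(noise),
                    "v8_n_flowlines": nflow,
                    "v9_annual_precip_mm": annual,
                    "v10_precip_seasonality": rng.uniform(1.0, 3.0),
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "cep_id", np.arange(1, len(df) + 1))
    return df


def sample_sediment_sites(
    scene: CoastScene, n: int, beta: Sequence[float], seed: int, max_dist_km: float = 10.0
):
    """Draw labelled training sites near the mangrove extent.

    Locations are uniform within ``max_dist_km`` of the mangrove union;
    labels are Bernoulli(logit⁻¹(beta · (1, tide, spm))) with terrigenous=1.
    Returns a list of dicts matching the sediment-site table schema.
    """
    if scene.tide is None or scene.spm is None:
        raise ConfigError("scene lacks tide/spm fields; run generate_sediment_fields")
    rng = np.random.default_rng(seed)
    zone = scene.mangrove_union().buffer(max_dist_km)
    minx, miny, maxx, maxy = zone.bounds
    b0, bt, bs = beta
    sites = []
    from shapely import contains_xy, prepare

    prepare(zone)
    while len(sites) < n:
        xs = rng.uniform(minx, maxx, size=n)
        ys = rng.uniform(miny, maxy, size=n)
        ok = contains_xy(zone, xs, ys)
        for x, y in zip(xs[ok], ys[ok]):
            if len(sites) >= n:
                break
            tv = scene.tide.sample_nearest(x, y)
            sv = scene.spm.sample_nearest(x, y)
            if tv is None or sv is None:
                continue
            eta = b0 + bt * tv + bs * sv
            p = 1.0 / (1.0 + math.exp(-eta))
            label = "terrigenous" if rng.random() < p else "carbonate"
            sites.append(
                {
                    "site_id": len(sites) + 1,
                    "x": float(x),
                    "y": float(y),
                    "typological_status": "non_riverine",
                    "sediment_label": label,
                    "tide_m": float(tv),
                    "spm_gm3": float(sv),
                }
            )
    return sites
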
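"""Disk layout for a generated scene (vectors GeoJSON, rasters TIFF, truth CSV)."""

from __future__ import annotations

import csv
from pathlib import Path

from .errors import IOFormatError
from .geo_core import read_raster, read_vector, write_raster, write_vector
from .synthetic_world import CoastScene, SceneConfig, TruthLabels

_VECTORS = ("coastline", "flowlines", "watersheds", "embayments", "patches")
_RASTERS = ("precip", "tide", "spm", "agb")


def write_scene(scene: CoastScene, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene.config.to_yaml(out / "config.yaml")
    for name in _VECTORS:
        write_vector(getattr(scene, name), out / f"{name}.geojson")
    for name in _RASTERS:
        raster = getattr(scene, name)
        if raster is not None:
            write_raster(raster, out / f"{name}.tif")
    for label, layer in scene.extents.items():
        write_vector(layer, out / f"extent_{label}.geojson")
    truth = scene.truth
    _write_map(out / "truth_embayments.csv", "id,class", truth.embayment_class)
    _write_map(out / "truth_sediment.csv", "id,class", truth.sediment_class)
    _write_map(out / "truth_agb_mean.csv", "id,class", truth.agb_mean)
    _write_map(out / "truth_loss_rate.csv", "id,class", truth.loss_rate)
    return out


def read_scene(scene_dir: str | Path) -> CoastScene:
    d = Path(scene_dir)
    if not (d / "config.yaml").exists():
        raise IOFormatError(f"not a scene directory (no config.yaml): {d}")
    config = SceneConfig.from_yaml(d / "config.yaml")
    vectors = {name: read_vector(d / f"{name}.geojson") for name in _VECTORS}
    scene = CoastScene(config=config, truth=TruthLabels(), **vectors)
    for name in _RASTERS:
        p = d / f"{name}.tif"
        if p.exists():
            setattr(scene, name, read_raster(p))
    for p in sorted(d.glob("extent_*.geojson")):
        label = p.stem.removeprefix("extent_")
        scene.extents[label] = read_vector(p)
    scene.truth.embayment_class = _read_map(d / "truth_embayments.csv", int)
    scene.truth.sediment_class = _read_map(d / "truth_sediment.csv", int)
    scene.truth.agb_mean = {
        k: float(v) for k, v in _read_map(d / "truth_agb_mean.csv", str).items()
    }
    scene.truth.loss_rate = {
        k: float(v) for k, v in _read_map(d / "truth_loss_rate.csv", str).items()
    }
    return scene


def _write_map(path: Path, header: str, mapping: dict) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header.split(","))
        for k, v in mapping.items():
            writer.writerow([k, v])


def _read_map(path: Path, key_type) -> dict:
    if not path.exists():
        return {}
    out = {}
    with open(path) as fh:
        reader = csv.reader(fh)
        next(reader, None)
        for row in reader:
            if row:
                out[key_type(row[0])] = row[1]
    return out
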
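"""End-to-end orchestration of the typology pipeline on a scene."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    agb_analysis,
    cep_builder,
    cep_covariates,
    extent_change,
    geomorphic_classifier,
    patch_assigner,
    sedimentary_classifier,
)
from .errors import MangroveTypologyError
from .geo_core import logger, write_vector
from .synthetic_world import CoastScene, SceneConfig, generate_scene, sample_sediment_sites


def match_ceps_to_truth(ceps, scene: CoastScene, iou_threshold: float = 0.5) -> dict:
    """Match extracted CEPs to planted embayments by best IoU.

    Returns {cep_id: {"emb_id", "class", "iou"}} for matches above the
    threshold; each planted embayment is matched to at most one CEP.
    """
    matches = {}
    taken = set()
    pairs = []
    for cep in ceps:
        for geom, attrs in scene.embayments:
            if not cep.geometry.intersects(geom):
                continue
            inter = cep.geometry.intersection(geom).area
            union = cep.geometry.union(geom).area
            iou = inter / union if union > 0 else 0.0
            if iou >= iou_threshold:
                pairs.append((iou, cep.id, attrs["emb_id"]))
    for iou, cid, eid in sorted(pairs, reverse=True):
        if cid in matches or eid in taken:
            continue
        matches[cid] = {
            "emb_id": eid,
            "class": scene.truth.embayment_class[eid],
            "iou": iou,
        }
        taken.add(eid)
    return matches


def run_pipeline(
    config: SceneConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    scene: CoastScene | None = None,
    closing_radius_km: float = 10.0,
    min_area_km2: float = 2.0,
    n_trees: int = 300,
    n_trees2: int = 200,
    review_error: float = 0.0,
    n_sediment_sites: int = 300,
) -> dict:
    """Run every stage on a (generated or supplied) scene; return artifacts."""
    if scene is None:
        config = config or SceneConfig()
        scene = generate_scene(config, seed)
    cfg = scene.config

    generalized = cep_builder.generalize_coastline(scene.coastline, closing_radius_km)
    ceps = cep_builder.extract_embayments(
        scene.coastline, generalized, min_area=min_area_km2, alloc_res=cfg.cell_km
    )
    ceps = cep_builder.filter_ceps(
        ceps, scene.coastline, scene.mangrove_union(), 30.0, 20.0
    )
    cov = cep_covariates.covariate_table(
        ceps, scene.flowlines, scene.watersheds, scene.precip
    )
    matches = match_ceps_to_truth(ceps, scene)
    truth_class = {cid: m["class"] for cid, m in matches.items()}

    deltas, pool = geomorphic_classifier.flag_deltas(
        ceps,
        scene.flowlines,
        confirm=lambda cep: truth_class.get(cep.id) == "delta",
    )
    delta_units = geomorphic_classifier.merge_delta_units(deltas)

    labeled_pool = [c for c in pool if c.id in truth_class]
    train_df = pd.DataFrame(
        [
            {"cep_id": c.id, "class": truth_class[c.id], **c.covariates}
            for c in labeled_pool
        ]
    )
    final_labels = None
    if not train_df.empty and train_df["class"].nunique() >= 2 and (
        train_df["class"].value_counts().min() >= 2
    ):
        run1 = geomorphic_classifier.train_rf(
            train_df, n_trees=n_trees, holdout_fraction=0.2, seed=seed
        )
        labels1 = geomorphic_classifier.classify_ceps(run1, pool)
        reviewer = lambda ids: geomorphic_classifier.review_hook(  # noqa: E731
            ids, truth_class, error_rate=review_error, seed=seed
        )
        final_labels = geomorphic_classifier.second_pass(
            run1, train_df, pool, labels1, reviewer, n_trees2=n_trees2, seed=seed
        )
    else:
        logger.warning("too few labelled CEPs for RF; assigning truth labels")
        for c in pool:
            c.cep_class = truth_class.get(c.id, "bay")

    catchments = {
        cep.id: cep_covariates.build_catchment(cep, scene.flowlines, scene.watersheds)
        for cep in ceps
    }
    units, assignments = patch_assigner.assign_all(
        scene.patches, ceps, delta_units, catchments, scene.extents
    )

    sites = pd.DataFrame(
        sample_sediment_sites(scene, n_sediment_sites, cfg.sediment_beta, seed + 1)
    )
    try:
        sediment_model = sedimentary_classifier.fit_sediment_glm(sites)
        sedimentary_classifier.classify_sediment(
            sediment_model, units, scene.tide, scene.spm
        )
    except MangroveTypologyError as exc:
        # e.g. a tiny scene where every sampled site lands in one class
        logger.warning("sediment model skipped (%s); majority class assigned", exc)
        sediment_model = None
        for u in units:
            u.sediment_type = "terrigenous"

    timesteps = sorted(cfg.timesteps, key=lambda k: cfg.timesteps[k])
    table = extent_change.tabulate_areas(units, timesteps)
    shares = extent_change.type_shares(table, timesteps[-1])
    changes = extent_change.percent_change(table, timesteps[0], timesteps[-1])
    losses = extent_change.rank_losses(units, timesteps[0], timesteps[-1])

    agb_analysis.unit_mean_agb(units, scene.agb)
    agb_df = agb_analysis.agb_table(units)
    agb_model = None
    if not agb_df.empty and agb_df["type"].nunique() >= 2 and (
        agb_df.groupby("type").size().min() >= 2
    ):
        agb_model = agb_analysis.fit_gls(agb_df["mean_agb"], agb_df["type"])
        agb_analysis.posthoc_contrasts(agb_model)

    result = {
        "scene": scene,
        "generalized": generalized,
        "ceps": ceps,
        "covariates": cov,
        "matches": matches,
        "delta_units": delta_units,
        "final_labels": final_labels,
        "catchments": catchments,
        "units": units,
        "assignments": assignments,
        "sediment_model": sediment_model,
        "change_table": table,
        "type_shares": shares,
        "percent_change": changes,
        "rank_losses": losses,
        "agb_model": agb_model,
    }
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_vector(cep_builder.ceps_to_layer(result["ceps"]), out / "ceps.geojson")
    result["covariates"].to_csv(out / "covariates.csv", index=False)
    if result["final_labels"] is not None:
        result["final_labels"].to_csv(out / "labels.csv", index=False)
    units = result["units"]
    rows = []
    unit_layer_rows = []
    for u in units:
        row = {
            "unit_id": u.unit_id,
            "geomorphic_type": u.geomorphic_type,
            "sediment_type": u.sediment_type,
            "cep_id": u.cep_id,
            "region": u.region,
            "mean_agb": u.mean_agb,
        }
        row.update({f"area_{k}": v for k, v in u.area_by_timestep.items()})
        rows.append(row)
        unit_layer_rows.append((u.geometry, row))
    pd.DataFrame(rows).to_csv(out / "units.csv", index=False)
    from .geo_core import VectorLayer

    layer = VectorLayer(geometry_type="polygon")
    for geom, attrs in unit_layer_rows:
        layer.add(geom, **{k: v for k, v in attrs.items() if v is not None})
    write_vector(layer, out / "units.geojson")
    result["change_table"].cells.to_csv(out / "change_table.csv", index=False)
    pd.Series(result["type_shares"]).rename("share_pct").to_csv(out / "shares.csv")
    pd.Series(result["percent_change"]).rename("change_pct").to_csv(out / "changes.csv")
    pd.DataFrame(
        [
            {"unit_id": u.unit_id, "loss_km2": loss}
            for u, loss in result["rank_losses"]
        ]
    ).to_csv(out / "losses.csv", index=False)
    if result["sediment_model"] is not None:
        (out / "sediment_model.json").write_text(
            json.dumps(result["sediment_model"].to_dict(), indent=2)
        )
    if result["agb_model"] is not None:
        (out / "agb_model.json").write_text(
            json.dumps(result["agb_model"].to_dict(), indent=2, default=float)
        )
    logger.info("pipeline outputs written to %s", out)
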
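"""Geomorphic classification of CEPs.

Deltas are identified first by a drainage-outlet rule (more than two sea
outlets) plus an optional configured list, confirmed through the review
hook, and removed from the pool. Remaining CEPs are classified into
bay/estuary/lagoon by a two-pass random forest: the first pass is reviewed
on a sample of predicted bays and all predicted estuaries/lagoons, a second
forest is trained on the original training data plus corrections, and
disagreements between the passes are routed back through review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from sklearn.ensemble import RandomForestClassifier

from .cep_builder import CEP
from .cep_covariates import COVARIATE_COLUMNS
from .errors import ConfigError, MangroveTypologyError
from .geo_core import VectorLayer, logger

RF_CLASSES = ("bay", "estuary", "lagoon")  # tie-break priority order


@dataclass
class RFRun:
    n_trees: int
    holdout_fraction: float
    seed: int
    training_counts: dict
    validation_accuracy: float
    per_class_recall: dict
    model_handle: object
    feature_columns: list


@dataclass
class DeltaUnit:
    unit_id: int
    member_cep_ids: list
    extent_geometry: BaseGeometry
    name: str | None = None


def count_outlets(cep: CEP, flowlines: VectorLayer, tol: float = 0.75) -> int:
    """Distinct flowline sea outlets inside the CEP or on its mouth."""
    zone = cep.geometry.buffer(tol)
    mouth_zone = cep.mouth.buffer(tol) if not cep.mouth.is_empty else None
    n = 0
    for _, attrs in flowlines:
        if attrs.get("next_fid", -1) != -1:
            continue
        if "outlet_x" not in attrs:
            continue
        pt = Point(attrs["outlet_x"], attrs["outlet_y"])
        if zone.contains(pt) or (mouth_zone is not None and mouth_zone.contains(pt)):
            n += 1
    return n


def flag_deltas(
    ceps: list[CEP],
    flowlines: VectorLayer,
    known_delta_list: list | None = None,
    confirm=None,
) -> tuple[list[CEP], list[CEP]]:
    """Split CEPs into confirmed deltas and the random-forest pool.

    ``known_delta_list`` holds CEP ids (the configured stand-in for
    literature-identified deltas). Outlet-rule candidates (>2 outlets) are
    confirmed through ``confirm(cep) -> bool`` (default: accept).
    """
    known = set(known_delta_list or [])
    missing = known - {c.id for c in ceps}
    for mid in missing:
        logger.warning("known delta id %s not found among CEPs", mid)
    deltas, pool = [], []
    for cep in ceps:
        is_delta = False
        if cep.id in known:
            is_delta = True
            cep.provenance = "listed"
        elif count_outlets(cep, flowlines) > 2:
            accepted = True if confirm is None else bool(confirm(cep))
            if accepted:
                is_delta = True
                cep.provenance = "outlet_rule"
        if is_delta:
            cep.cep_class = "delta"
            deltas.append(cep)
        else:
            pool.append(cep)
    logger.info("delta flagging: %d deltas, %d in RF pool", len(deltas), len(pool))
    return deltas, pool


def merge_delta_units(
    delta_ceps: list[CEP], delta_extents: VectorLayer | None = None
) -> list[DeltaUnit]:
    """Combine delta CEPs under shared extents into single units."""
    units: list[DeltaUnit] = []
    if delta_extents is None or len(delta_extents) == 0:
        for i, cep in enumerate(delta_ceps):
            units.append(DeltaUnit(i + 1, [cep.id], cep.geometry))
        return units
    assigned: dict[int, int] = {}
    members: dict[int, list[CEP]] = {i: [] for i in range(len(delta_extents))}
    for cep in delta_ceps:
        overlaps = [
            (cep.geometry.intersection(geom).area, k)
            for k, (geom, _) in enumerate(delta_extents.features)
            if cep.geometry.intersects(geom)
        ]
        overlaps = [(a, k) for a, k in overlaps if a > 0]
        if not overlaps:
            continue
        if len(overlaps) > 1:
            logger.warning(
                "delta CEP %d claimed by %d extents; assigning to largest overlap",
                cep.id,
                len(overlaps),
            )
        _, k = max(overlaps)
        members[k].append(cep)
        assigned[cep.id] = k
    uid = 0
    for k, (geom, attrs) in enumerate(delta_extents.features):
        if not members[k]:
            continue
        uid += 1
        geoms = [c.geometry for c in members[k]] + [geom]
        units.append(
            DeltaUnit(
                uid,
                [c.id for c in members[k]],
                unary_union(geoms),
                name=attrs.get("name"),
            )
        )
    for cep in delta_ceps:
        if cep.id not in assigned:
            uid += 1
            units.append(DeltaUnit(uid, [cep.id], cep.geometry))
    return units


def _features(df: pd.DataFrame, columns: list) -> np.ndarray:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MangroveTypologyError(f"covariate columns missing: {missing}")
    return df[columns].to_numpy(dtype=float)


def train_rf(
    table: pd.DataFrame,
    n_trees: int = 100_000,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    feature_columns: list | None = None,
) -> RFRun:
    """Train a random forest on labelled covariate rows.

    ``table`` must carry a ``class`` column with values in RF_CLASSES. A
    fraction of rows is held out for validation; forest hyperparameters
    other than tree count are library defaults (logged).
    """
    if not (0.0 < holdout_fraction < 1.0):
        raise ConfigError(f"holdout_fraction must be in (0,1), got {holdout_fraction}")
    feature_columns = feature_columns or COVARIATE_COLUMNS
    counts = table["class"].value_counts().to_dict()
    if len(counts) < 2:
        raise MangroveTypologyError("need at least 2 classes to train")
    for cls, cnt in counts.items():
        if cnt < 2:
            raise MangroveTypologyError(f"class '{cls}' has {cnt} training rows (<2)")
    rng = np.random.default_rng(seed)
    n = len(table)
    order = rng.permutation(n)
    n_hold = max(int(round(holdout_fraction * n)), 1)
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    X = _features(table, feature_columns)
    y = table["class"].to_numpy()
    import sklearn

    logger.info(
        "training RandomForestClassifier (scikit-learn %s, defaults) "
        "n_trees=%d counts=%s",
        sklearn.__version__,
        n_trees,
        counts,
    )
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**32)
    )
    model.fit(X[train_idx], y[train_idx])
    pred = model.predict(X[hold_idx])
    acc = float((pred == y[hold_idx]).mean())
    recall = {}
    for cls in counts:
        sel = y[hold_idx] == cls
        recall[cls] = float((pred[sel] == cls).mean()) if sel.any() else float("nan")
    return RFRun(
        n_trees=n_trees,
        holdout_fraction=holdout_fraction,
        seed=seed,
        training_counts=counts,
        validation_accuracy=acc,
        per_class_recall=recall,
        model_handle=model,
        feature_columns=list(feature_columns),
    )


def classify_ceps(run: RFRun, ceps: list[CEP]) -> pd.DataFrame:
    """Predict classes and vote fractions for non-delta CEPs.

    Ties in vote fractions break by class priority bay > estuary > lagoon.
    """
    if not ceps:
        return pd.DataFrame(
            columns=["cep_id", "class"] + [f"vote_{c}" for c in RF_CLASSES]
        )
    df = pd.DataFrame([{"cep_id": c.id, **c.covariates} for c in ceps])
    X = _features(df, run.feature_columns)
    model = run.model_handle
    proba = model.predict_proba(X)
    model_classes = list(model.classes_)
    votes = np.zeros((len(ceps), len(RF_CLASSES)))
    for j, cls in enumerate(RF_CLASSES):
        if cls in model_classes:
            votes[:, j] = proba[:, model_classes.index(cls)]
    # argmax over priority-ordered columns: first max wins => priority tie-break
    winners = [RF_CLASSES[j] for j in votes.argmax(axis=1)]
    out = pd.DataFrame({"cep_id": [c.id for c in ceps], "class": winners})
    for j, cls in enumerate(RF_CLASSES):
        out[f"vote_{cls}"] = votes[:, j]
    for cep, cls in zip(ceps, winners):
        cep.cep_class = cls
    return out


def review_hook(
    flagged_ids: list,
    truth: dict | None,
    error_rate: float = 0.0,
    seed: int = 0,
    classes: tuple = RF_CLASSES,
) -> dict:
    """Mechanised stand-in for visual review: truth with random flips.

    Returns {cep_id: label}; each label is the truth flipped independently
    to a uniformly chosen other class with probability ``error_rate``.
    """
    if truth is None:
        raise MangroveTypologyError(
            "review hook requires truth labels in synthetic mode"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for cid in flagged_ids:
        label = truth[cid]
        if error_rate > 0 and rng.random() < error_rate:
            others = [c for c in classes if c != label]
            label = others[int(rng.integers(len(others)))]
        out[cid] = label
    return out


def second_pass(
    first: RFRun,
    training_table: pd.DataFrame,
    pool: list[CEP],
    first_labels: pd.DataFrame,
    reviewer,
    n_trees2: int = 75_000,
    bay_sample: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Review, retrain, re-predict, reconcile.

    ``reviewer(flagged_ids) -> {cep_id: label}`` corrects a random sample of
    predicted bays plus all predicted estuaries/lagoons; a second forest is
    trained on the original training rows and the corrected CEPs and applied
    to the remaining (non-reviewed, bay-labelled) CEPs. Pass-1/pass-2
    disagreements go back through the reviewer. Returns the final label
    frame with provenance in {pass1, pass2, review}.
    """
    rng = np.random.default_rng(seed)
    by_id = {c.id: c for c in pool}
    lab = first_labels.set_index("cep_id")["class"].to_dict()

    bay_ids = [cid for cid, cls in lab.items() if cls == "bay"]
    other_ids = [cid for cid, cls in lab.items() if cls != "bay"]
    n_sample = min(bay_sample, len(bay_ids))
    sampled_bays = list(rng.choice(bay_ids, size=n_sample, replace=False)) if n_sample else []
    review_ids = [int(i) for i in sampled_bays] + other_ids
    corrections = reviewer(review_ids) if review_ids else {}
    if not corrections:
        logger.warning("empty corrections set; second pass retrains on pass-1 data")

    corr_rows = []
    for cid, cls in corrections.items():
        cep = by_id[cid]
        corr_rows.append({"cep_id": cid, "class": cls, **cep.covariates})
    train2 = pd.concat(
        [training_table, pd.DataFrame(corr_rows)], ignore_index=True
    ) if corr_rows else training_table.copy()

    run2 = train_rf(
        train2,
        n_trees=n_trees2,
        holdout_fraction=first.holdout_fraction,
        seed=seed,
        feature_columns=first.feature_columns,
    )
    remaining = [by_id[cid] for cid in bay_ids if cid not in corrections]
    final = dict(corrections)
    provenance = {cid: "review" for cid in corrections}
    n_disagreements = 0
    if remaining:
        pred2 = classify_ceps(run2, remaining).set_index("cep_id")["class"].to_dict()
        disagreements = [cid for cid, cls in pred2.items() if cls != lab[cid]]
        n_disagreements = len(disagreements)
        for cid, cls in pred2.items():
            if cid not in disagreements:
                final[cid] = cls
                provenance[cid] = "pass2" if cls != lab[cid] else "pass1"
        if disagreements:
            resolved = reviewer(disagreements)
            for cid, cls in resolved.items():
                final[cid] = cls
                provenance[cid] = "review"
    # anything untouched keeps its pass-1 label
    for cid, cls in lab.items():
        if cid not in final:
            final[cid] = cls
            provenance[cid] = "pass1"
    for cid, cls in final.items():
        by_id[cid].cep_class = cls
        by_id[cid].provenance = provenance[cid]
    out = pd.DataFrame(
        {
            "cep_id": list(final),
            "class": [final[c] for c in final],
            "provenance": [provenance[c] for c in final],
        }
    ).sort_values("cep_id", ignore_index=True)
    out.attrs["n_disagreements"] = n_disagreements
    n_flags = int((out["provenance"] == "review").sum())
    logger.info("second pass: %d reviewed, %d final labels", n_flags, len(out))
    return out
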
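"""Sedimentary setting: terrigenous vs carbonate.

A binomial GLM (logit link) of sediment label on M2 tidal amplitude and
mean inorganic SPM is fitted to non-riverine training sites and applied to
lagoonal and open-coast units at their representative points. Deltaic and
estuarine units are terrigenous unconditionally. Response coding is
terrigenous = 1, so tidal amplitude carries a positive coefficient in
high-tidal-energy minerogenic settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MangroveTypologyError
from .geo_core import RasterField, logger
from .patch_assigner import TypologyUnit

#: documented cap applied to coefficients under complete separation
SEPARATION_CAP = 50.0


@dataclass
class SedimentModel:
    beta0: float
    beta_tide: float
    beta_spm: float
    se: dict = field(default_factory=dict)
    z: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    d_null: float = float("nan")
    d_resid: float = float("nan")
    pseudo_r2: float = float("nan")
    n_fit: int = 0
    confusion: dict = field(default_factory=dict)
    separation_flag: bool = False
    threshold: float = 0.5

    def predict_prob(self, tide_m: float, spm_gm3: float) -> float:
        eta = self.beta0 + self.beta_tide * tide_m + self.beta_spm * spm_gm3
        return float(1.0 / (1.0 + np.exp(-eta)))

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                "intercept": self.beta0,
                "tide_m": self.beta_tide,
                "spm_gm3": self.beta_spm,
            },
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "null_deviance": self.d_null,
            "residual_deviance": self.d_resid,
            "pseudo_r2": self.pseudo_r2,
            "n_fit": self.n_fit,
            "confusion": self.confusion,
            "separation_flag": self.separation_flag,
            "threshold": self.threshold,
        }


def deviance_pseudo_r2(d_null: float, d_resid: float) -> float:
    """(null deviance − residual deviance) / null deviance."""
    if d_null == 0:
        raise MangroveTypologyError("null deviance is zero; pseudo-R2 undefined")
    return (d_null - d_resid) / d_null


def sample_fields_at_sites(
    sites: pd.DataFrame,
    tide: RasterField,
    spm_monthly: RasterField,
    search_radius_km: float = 10.0,
) -> pd.DataFrame:
    """Attach tide and across-band mean SPM from the nearest valid cells.

    Sites with no valid cell within the search radius are dropped (warned).
    """
    if spm_monthly.n_bands < 1:
        raise MangroveTypologyError("SPM raster needs at least one band")
    spm_mean = _across_band_mean(spm_monthly)
    rows = []
    for _, site in sites.iterrows():
        tv = tide.sample_nearest(site["x"], site["y"], search_radius_km=search_radius_km)
        sv = spm_mean.sample_nearest(site["x"], site["y"], search_radius_km=search_radius_km)
        if tv is None or sv is None:
            logger.warning("site %s has no valid raster cell in range; dropped",
                           site.get("site_id"))
            continue
        row = site.to_dict()
        row["tide_m"] = tv
        row["spm_gm3"] = sv
        rows.append(row)
    return pd.DataFrame(rows)


def _across_band_mean(raster: RasterField) -> RasterField:
    vals = raster.values
    mask = ~np.isclose(vals, raster.nodata) & np.isfinite(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(
            mask.any(axis=0),
            np.nansum(np.where(mask, vals, 0.0), axis=0) / mask.sum(axis=0).clip(1),
            raster.nodata,
        )
    return RasterField(mean, raster.origin, raster.cell, nodata=raster.nodata,
                       units=raster.units)


def fit_sediment_glm(sites: pd.DataFrame, threshold: float = 0.5) -> SedimentModel:
    """Logistic fit of sediment label on tide and SPM over non-riverine sites.

    Both predictors are always retained regardless of significance.
    Riverine (estuarine/deltaic) sites are excluded before fitting.
    """
    nonriv = sites[sites.get("typological_status", "non_riverine") != "riverine"]
    labels = set(nonriv["sediment_label"])
    if len(labels) < 2:
        raise MangroveTypologyError(
            f"need both sediment classes among non-riverine sites, got {labels}"
        )
    y = (nonriv["sediment_label"] == "terrigenous").to_numpy(dtype=float)
    X = sm.add_constant(nonriv[["tide_m", "spm_gm3"]].to_numpy(dtype=float))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            d_null, d_resid = float(res.null_deviance), float(res.deviance)
        except Exception as exc:  # perfect separation raises in some versions
            logger.warning("GLM fit failed (%s); flagging separation", exc)
            separation = True
            params = np.array([0.0, SEPARATION_CAP, 0.0])
            bse = np.full(3, np.inf)
            d_null = d_resid = float("nan")
    if not separation and (
        np.abs(params).max() > SEPARATION_CAP
        or (np.isfinite(d_resid) and d_resid < 1e-6 * max(d_null, 1.0))
    ):
        separation = True
        if np.abs(params).max() > SEPARATION_CAP:
            # rescale the whole vector: keeps the boundary, caps magnitude
            params = params * (SEPARATION_CAP / np.abs(params).max())
        logger.warning("complete separation suspected; flagged (cap %.0f)",
                       SEPARATION_CAP)
    zvals = params / np.where(bse > 0, bse, np.inf)
    from scipy.stats import norm

    pvals = 2 * norm.sf(np.abs(zvals))
    names = ["intercept", "tide_m", "spm_gm3"]
    model = SedimentModel(
        beta0=float(params[0]),
        beta_tide=float(params[1]),
        beta_spm=float(params[2]),
        se=dict(zip(names, map(float, bse))),
        z=dict(zip(names, map(float, zvals))),
        p=dict(zip(names, map(float, pvals))),
        d_null=d_null,
        d_resid=d_resid,
        pseudo_r2=deviance_pseudo_r2(d_null, d_resid)
        if d_null and np.isfinite(d_null)
        else float("nan"),
        n_fit=int(len(nonriv)),
        separation_flag=separation,
        threshold=threshold,
    )
    prob = np.array([model.predict_prob(t, s) for t, s in
                     nonriv[["tide_m", "spm_gm3"]].to_numpy()])
    pred = prob >= threshold
    model.confusion = {
        "tp": int(((pred == 1) & (y == 1)).sum()),
        "fn": int(((pred == 0) & (y == 1)).sum()),
        "fp": int(((pred == 1) & (y == 0)).sum()),
        "tn": int(((pred == 0) & (y == 0)).sum()),
    }
    logger.info(
        "sediment GLM: n=%d, pseudoR2=%.3f, z(tide)=%.2f z(spm)=%.2f",
        model.n_fit, model.pseudo_r2, model.z["tide_m"], model.z["spm_gm3"],
    )
    return model


def classify_sediment(
    model: SedimentModel,
    units: list[TypologyUnit],
    tide: RasterField,
    spm: RasterField,
    threshold: float | None = None,
    search_radius_km: float = 10.0,
) -> list[TypologyUnit]:
    """Set each unit's sediment type (threshold inclusive for terrigenous).

    Deltaic/estuarine units are forced terrigenous; unsampled units fall
    back to the majority class (terrigenous) with a warning.
    """
    thr = model.threshold if threshold is None else threshold
    spm_mean = _across_band_mean(spm) if spm.n_bands > 1 else spm
    for unit in units:
        if unit.geomorphic_type in ("deltaic", "estuarine"):
            unit.sediment_type = "terrigenous"
            unit.sediment_prob = None
            continue
        largest = max(
            (p for p in _polys(unit.geometry)), key=lambda p: p.area, default=None
        )
        if largest is None:
            unit.sediment_type = "terrigenous"
            continue
        rep = largest.representative_point()
        tv = tide.sample_nearest(rep.x, rep.y, search_radius_km=search_radius_km)
        sv = spm_mean.sample_nearest(rep.x, rep.y, search_radius_km=search_radius_km)
        if tv is None or sv is None:
            logger.warning("unit %d unsampled; defaulting to terrigenous", unit.unit_id)
            unit.sediment_type = "terrigenous"
            unit.sediment_prob = None
            continue
        p_terr = model.predict_prob(tv, sv)
        unit.sediment_prob = p_terr
        unit.sediment_type = "terrigenous" if p_terr >= thr else "carbonate"
    return units


def _polys(geom):
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_polys(g))
        return out
    return []
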
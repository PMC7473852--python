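"""Above-ground biomass by geomorphic type.

Unit mean AGB is computed from raster cell centres falling in each unit.
Differences between types are tested with a one-way model of sqrt(mean AGB)
fitted by maximum likelihood with a distinct residual variance per type
(heteroscedastic "variance structure"). The type effect is a Wald F test
against the common-mean model with the same variance structure; explanatory
power is summarized by the Nagelkerke pseudo-R²; pairwise differences of
the estimated marginal means use Tukey family-wise adjustment and a compact
letter display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MangroveTypologyError
from .geo_core import RasterField, covered_cells, logger
from .patch_assigner import TypologyUnit

TYPE_ORDER = ("deltaic", "estuarine", "lagoonal", "open_coast")


@dataclass
class AGBModel:
    transform: str
    coefficients: dict  # type -> mean on transformed scale
    variance_multipliers: dict  # type -> sd ratio vs reference type
    group_counts: dict
    group_sd: dict  # ML residual sd per type (transformed scale)
    F_stat: float
    df_num: int
    df_den: int
    p_value: float
    loglik: float
    loglik_null: float
    n_obs: int
    fitted_by: str = "ML"
    nagelkerke: float | None = None
    contrasts: list = field(default_factory=list)
    letters: dict = field(default_factory=dict)

    def back_transformed_means(self) -> dict:
        return {t: m**2 for t, m in self.coefficients.items()}

    def to_dict(self) -> dict:
        return {
            "transform": self.transform,
            "coefficients": self.coefficients,
            "back_transformed_means": self.back_transformed_means(),
            "variance_multipliers": self.variance_multipliers,
            "group_counts": self.group_counts,
            "F_stat": self.F_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "nagelkerke_r2": self.nagelkerke,
            "contrasts": self.contrasts,
            "letters": self.letters,
        }


def unit_mean_agb(units: list[TypologyUnit], agb: RasterField) -> list[TypologyUnit]:
    """Mean AGB over raster cell centres inside each unit.

    Units covering no valid cell get ``mean_agb = None`` and are excluded
    downstream (count logged).
    """
    excluded = 0
    for unit in units:
        rows, cols = covered_cells(unit.geometry, agb)
        if len(rows) == 0:
            unit.mean_agb = None
            excluded += 1
            continue
        vals = agb.values[0, rows, cols]
        valid = ~np.isclose(vals, agb.nodata) & np.isfinite(vals)
        if not valid.any():
            unit.mean_agb = None
            excluded += 1
            continue
        unit.mean_agb = float(vals[valid].mean())
    if excluded:
        logger.info("unit_mean_agb: %d units with no AGB coverage excluded", excluded)
    return units


def _group_stats(y: np.ndarray, g: np.ndarray) -> tuple[list, dict, dict, dict]:
    types = sorted(set(g), key=lambda t: (TYPE_ORDER.index(t) if t in TYPE_ORDER else 99, t))
    means, var_ml, counts = {}, {}, {}
    for t in types:
        vals = y[g == t]
        counts[t] = len(vals)
        means[t] = float(vals.mean())
        var_ml[t] = float(((vals - vals.mean()) ** 2).mean())
    return types, means, var_ml, counts


def _loglik(y: np.ndarray, g: np.ndarray, means: dict, var: dict) -> float:
    ll = 0.0
    for t, v in var.items():
        vals = y[g == t]
        ll += -0.5 * len(vals) * math.log(2 * math.pi * v) - 0.5 * (
            ((vals - means[t]) ** 2).sum() / v
        )
    return ll


def _fit_null(y: np.ndarray, g: np.ndarray, types: list) -> tuple[float, dict, float]:
    """ML common mean with per-type variances (fixed-point iteration)."""
    mu = float(y.mean())
    var = {t: float(((y[g == t] - mu) ** 2).mean()) for t in types}
    for _ in range(200):
        w = np.array([len(y[g == t]) / var[t] for t in types])
        gm = np.array([y[g == t].mean() for t in types])
        mu_new = float((w * gm).sum() / w.sum())
        var_new = {t: float(((y[g == t] - mu_new) ** 2).mean()) for t in types}
        if abs(mu_new - mu) < 1e-12:
            mu, var = mu_new, var_new
            break
        mu, var = mu_new, var_new
    ll = _loglik(y, g, {t: mu for t in types}, var)
    return mu, var, ll


def fit_gls(unit_means, types, transform: str = "sqrt") -> AGBModel:
    """Heteroscedastic one-way ML fit of transformed unit mean AGB on type."""
    y_raw = np.asarray(unit_means, dtype=float)
    g = np.asarray(types)
    if len(y_raw) != len(g):
        raise MangroveTypologyError("unit_means and types length mismatch")
    mask = np.isfinite(y_raw)
    y_raw, g = y_raw[mask], g[mask]
    if transform == "sqrt":
        if (y_raw < 0).any():
            raise MangroveTypologyError("negative AGB mean; cannot sqrt-transform")
        y = np.sqrt(y_raw)
    elif transform == "identity":
        y = y_raw
    else:
        raise MangroveTypologyError(f"unknown transform: {transform}")

    tlist, means, var_ml, counts = _group_stats(y, g)
    if len(tlist) < 2:
        raise MangroveTypologyError("need >= 2 types to fit")
    for t, cnt in counts.items():
        if cnt < 2:
            raise MangroveTypologyError(f"type '{t}' has a single unit; cannot fit")
    for t, v in var_ml.items():
        if v <= 0:
            raise MangroveTypologyError(
                f"zero residual variance in type '{t}' (degenerate data)"
            )

    n = len(y)
    k = len(tlist)
    df_num, df_den = k - 1, n - k
    ll1 = _loglik(y, g, means, var_ml)
    _, _, ll0 = _fit_null(y, g, tlist)

    # Wald F of the type effect under the fitted variance structure
    w = np.array([counts[t] / var_ml[t] for t in tlist])
    gm = np.array([means[t] for t in tlist])
    mu_w = (w * gm).sum() / w.sum()
    F = float(((w * (gm - mu_w) ** 2).sum()) / df_num)
    p = float(stats.f.sf(F, df_num, df_den))

    ref = tlist[0]
    sd = {t: math.sqrt(var_ml[t]) for t in tlist}
    multipliers = {t: sd[t] / sd[ref] for t in tlist}

    model = AGBModel(
        transform=transform,
        coefficients=means,
        variance_multipliers=multipliers,
        group_counts=counts,
        group_sd=sd,
        F_stat=F,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        loglik=ll1,
        loglik_null=ll0,
        n_obs=n,
    )
    model.nagelkerke = nagelkerke_r2(model)
    logger.info(
        "AGB model: F_%d,%d = %.2f (p=%.3g), NagelkerkeR2=%.3f",
        df_num, df_den, F, p, model.nagelkerke,
    )
    return model


def nagelkerke_r2(model: AGBModel, null_model: AGBModel | None = None) -> float:
    """Likelihood-ratio pseudo-R² normalized to a maximum of 1.

    ``R² = [1 − (L0/L1)^(2/n)] / [1 − L0^(2/n)]``. Requires ML fits.
    """
    if model.fitted_by != "ML" or (null_model and null_model.fitted_by != "ML"):
        raise MangroveTypologyError("Nagelkerke requires ML (not REML) fits")
    ll1 = model.loglik
    ll0 = null_model.loglik if null_model is not None else model.loglik_null
    n = model.n_obs
    num = 1.0 - math.exp(min(2.0 / n * (ll0 - ll1), 0.0))
    den = 1.0 - math.exp(2.0 / n * ll0)
    if den <= 0:
        logger.warning("Nagelkerke denominator <= 0 (density > 1); clipping to 1")
        return float(min(max(num, 0.0), 1.0))
    return float(min(max(num / den, 0.0), 1.0))


def posthoc_contrasts(
    model: AGBModel, alpha: float = 0.05, adjust: str = "tukey"
) -> AGBModel:
    """All pairwise contrasts of type means with multiplicity adjustment.

    SEs use the per-type fitted variances; p-values come from the
    studentized range (Tukey family) by default, or Bonferroni/none.
    """
    tlist = list(model.coefficients)
    k = len(tlist)
    df = model.df_den
    contrasts = []
    sig_pairs = set()
    for a, b in itertools.combinations(tlist, 2):
        est = model.coefficients[a] - model.coefficients[b]
        se = math.sqrt(
            model.group_sd[a] ** 2 / model.group_counts[a]
            + model.group_sd[b] ** 2 / model.group_counts[b]
        )
        tval = est / se if se > 0 else math.inf
        if adjust == "tukey":
            pval = float(stats.studentized_range.sf(abs(tval) * math.sqrt(2), k, df))
        elif adjust == "bonferroni":
            pval = float(min(2 * stats.t.sf(abs(tval), df) * (k * (k - 1) / 2), 1.0))
        elif adjust == "none":
            pval = float(2 * stats.t.sf(abs(tval), df))
        else:
            raise MangroveTypologyError(f"unknown adjustment: {adjust}")
        significant = pval < alpha
        if significant:
            sig_pairs.add(frozenset((a, b)))
        contrasts.append(
            {
                "pair": f"{a} - {b}",
                "estimate": float(est),
                "se": float(se),
                "t": float(tval),
                "p_adj": pval,
                "significant": bool(significant),
            }
        )
    model.contrasts = contrasts
    model.letters = _compact_letters(tlist, model.coefficients, sig_pairs)
    return model


def _compact_letters(groups: list, means: dict, sig_pairs: set) -> dict:
    """Insert-and-absorb compact letter display."""
    ordered = sorted(groups, key=lambda t: means[t])
    columns = [set(ordered)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns that are subsets of another
        columns = []
        for col in new_cols:
            if not any(col < other for other in new_cols if col is not other) and (
                col not in columns
            ):
                columns.append(col)
    letters = {g: "" for g in ordered}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    columns.sort(key=lambda col: min(ordered.index(g) for g in col) if col else 99)
    for i, col in enumerate(columns):
        for g in ordered:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def agb_table(units: list[TypologyUnit]) -> pd.DataFrame:
    rows = [
        {
            "unit_id": u.unit_id,
            "type": u.geomorphic_type,
            "mean_agb": u.mean_agb,
        }
        for u in units
        if u.mean_agb is not None
    ]
    return pd.DataFrame(rows)
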
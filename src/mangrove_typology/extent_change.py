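"""Extent-change accounting: areas by type x region x timestep.

Percentages destined for tables are rounded half-up to one decimal (the
printing convention of the source tables); raw doubles are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MangroveTypologyError, UndefinedValueError
from .geo_core import VectorLayer, round_half_up
from .patch_assigner import TypologyUnit

GEOMORPHIC_TYPES = ("deltaic", "estuarine", "lagoonal", "open_coast")


@dataclass
class ChangeTable:
    """Long-format area table with derived margins and shares."""

    cells: pd.DataFrame  # columns: region, type, timestep, km2

    def __post_init__(self) -> None:
        required = {"region", "type", "timestep", "km2"}
        if set(self.cells.columns) < required:
            raise MangroveTypologyError(f"ChangeTable needs columns {required}")
        if (self.cells["km2"] < 0).any():
            raise MangroveTypologyError("negative area cell")

    def total(self, timestep: str) -> float:
        sel = self.cells[self.cells["timestep"] == timestep]
        return float(sel["km2"].sum())

    def by_type(self, timestep: str) -> dict:
        sel = self.cells[self.cells["timestep"] == timestep]
        return sel.groupby("type")["km2"].sum().to_dict()

    def by_region(self, timestep: str) -> dict:
        sel = self.cells[self.cells["timestep"] == timestep]
        return sel.groupby("region")["km2"].sum().to_dict()

    def by_group(self, timestep: str, grouping: str) -> dict:
        if grouping == "type":
            return self.by_type(timestep)
        if grouping == "region":
            return self.by_region(timestep)
        if grouping in self.cells.columns:
            sel = self.cells[self.cells["timestep"] == timestep]
            return sel.groupby(grouping)["km2"].sum().to_dict()
        raise MangroveTypologyError(f"unknown grouping: {grouping}")

    @property
    def timesteps(self) -> list:
        return sorted(self.cells["timestep"].unique())


def tabulate_areas(
    units: list[TypologyUnit],
    timesteps: list[str],
    region_layer: VectorLayer | None = None,
) -> ChangeTable:
    """Aggregate unit areas into (region, type, timestep) cells.

    Regions present in the layer but without mangrove appear as zero rows.
    """
    regions = {"global"}
    if region_layer is not None:
        regions = {attrs.get("region", "global") for _, attrs in region_layer.features}
    rows = []
    acc: dict[tuple, float] = {}
    for unit in units:
        for ts in timesteps:
            if ts not in unit.area_by_timestep:
                raise MangroveTypologyError(
                    f"unit {unit.unit_id} missing area for timestep {ts}"
                )
            key = (unit.region, unit.geomorphic_type, ts)
            acc[key] = acc.get(key, 0.0) + unit.area_by_timestep[ts]
        regions.add(unit.region)
    for region in sorted(regions):
        for gtype in GEOMORPHIC_TYPES:
            for ts in timesteps:
                rows.append(
                    {
                        "region": region,
                        "type": gtype,
                        "timestep": ts,
                        "km2": acc.get((region, gtype, ts), 0.0),
                    }
                )
    return ChangeTable(pd.DataFrame(rows))


def type_shares(table: ChangeTable, timestep: str, ndigits: int = 1) -> dict:
    """Percentage share of each type in the global total (rounded half-up)."""
    totals = table.by_type(timestep)
    grand = sum(totals.values())
    if grand == 0:
        raise UndefinedValueError(f"zero global total at timestep {timestep}")
    return {t: round_half_up(100.0 * a / grand, ndigits) for t, a in totals.items()}


def percent_change(
    table: ChangeTable, t0: str, t1: str, grouping: str = "type", ndigits: int = 1
) -> dict:
    """Percent change per group between two timesteps; NA when A(t0) = 0."""
    if t0 == t1:
        import logging

        logging.getLogger("mangrove_typology").warning(
            "percent_change called with t0 == t1; returning zeros"
        )
    a0 = table.by_group(t0, grouping)
    a1 = table.by_group(t1, grouping)
    out = {}
    for g in sorted(set(a0) | set(a1)):
        base = a0.get(g, 0.0)
        if base == 0:
            out[g] = None  # not-applicable
        else:
            out[g] = round_half_up(100.0 * (a1.get(g, 0.0) - base) / base, ndigits)
    return out


def rank_losses(
    units: list[TypologyUnit], t0: str, t1: str, top_n: int | None = None
) -> list[tuple[TypologyUnit, float]]:
    """Units ranked by descending net area loss A(t0) - A(t1); ties by id."""
    losses = []
    for unit in units:
        if t0 not in unit.area_by_timestep or t1 not in unit.area_by_timestep:
            raise MangroveTypologyError(
                f"unit {unit.unit_id} missing timestep areas for ranking"
            )
        losses.append((unit, unit.area_by_timestep[t0] - unit.area_by_timestep[t1]))
    losses.sort(key=lambda t: (-t[1], t[0].unit_id))
    if top_n is not None:
        losses = losses[: max(top_n, 0)]
    return losses
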
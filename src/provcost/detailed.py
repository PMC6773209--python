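"""The detailed six-step reference costing method.

Starting from county-level micro-cost line items for a single base province,
the pipeline (1) inflates and currency-converts the amounts, (2) scales them
to township/provincial hospital levels with per-category multipliers,
(3) extrapolates the level costs to every other province in proportion to
province-average outpatient-visit / inpatient-bed-day unit costs,
(4-5) collapses hospital levels with hospital-seeking behaviour and the
urban/rural population split, and (6) aggregates provinces into regional and
national population-weighted averages.

The provincial weighted average for one procedure with level costs
A (township), B (county), C (provincial) is

    x * (a*A + b*B + c*C) + (1 - x) * (d*A + e*B + f*C)

where x is the urban population fraction and (a, b, c) / (d, e, f) are the
urban / rural hospital-seeking proportions over the three levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Bundle
from .types import (
    CATEGORIES,
    LEVELS,
    PROPORTION_TOL,
    SETTINGS,
    CostComponent,
    CostTable,
    LevelCosts,
    LevelMultiplierSet,
    PriceAdjustment,
    Province,
    SeekingBehavior,
    ValidationError,
    round_half_up,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedCostResult:
    """Provincial weighted average cost of one procedure, with the urban and
    rural strata it was combined from."""

    province: str
    procedure_id: str
    overall: float
    urban: float
    rural: float


def adjust_price(amount: float, adj: PriceAdjustment) -> float:
    """Inflate an amount through the chained medical-CPI factors and convert
    it to the target currency at ``fx_rate`` source units per target unit."""
    if amount < 0:
        raise ValidationError(f"cannot adjust a negative amount ({amount})",
                              rule="amount-nonnegative")
    return amount * adj.factor


def derive_level_multipliers(
    level_references: dict[tuple[str, str], float],
    category_map: dict[str, tuple[str, ...] | str],
) -> LevelMultiplierSet:
    """Build hospital-level multipliers from published reference series.

    ``level_references`` maps (reference_series, hospital_level) to a value
    (e.g. national average staff expenditure, or mean outpatient/inpatient
    cost, by hospital level).  ``category_map`` maps each (category) or
    (category, setting handled by the caller) to a reference series name;
    values may be a single series name applied to both settings or a
    ``(outpatient_series, inpatient_series)`` pair.  The multiplier for a
    level is the series value at that level divided by its county value, so
    county multipliers are exactly 1.
    """
    entries: dict[tuple[str, str, str], float] = {}
    for category in category_map:
        if category not in CATEGORIES:
            raise ValidationError(f"unmapped or unknown category {category!r}",
                                  rule="category-map")
    for category, series in category_map.items():
        per_setting = series if isinstance(series, tuple) else (series, series)
        for setting, series_name in zip(SETTINGS, per_setting):
            county = level_references.get((series_name, "county"))
            if county is None or not county > 0:
                raise ValidationError(
                    f"reference series {series_name!r} lacks a positive county "
                    f"baseline", rule="county-baseline")
            for level in LEVELS:
                if level == "county":
                    entries[(category, setting, level)] = 1.0
                    continue
                value = level_references.get((series_name, level))
                if value is not None:
                    entries[(category, setting, level)] = value / county
    return LevelMultiplierSet(entries)


def scale_to_level(
    components: list[CostComponent],
    multipliers: LevelMultiplierSet,
    target_level: str,
) -> tuple[float, dict[str, float]]:
    """Scale a county-level component set to another hospital level.

    Returns the total and the per-category breakdown.  All components must
    belong to one procedure and one setting.
    """
    if target_level not in LEVELS:
        raise ValidationError(f"unknown level {target_level!r}", rule="level-enum")
    if not components:
        return 0.0, {}
    settings = {c.setting for c in components}
    procedures = {c.procedure_id for c in components}
    if len(settings) > 1 or len(procedures) > 1:
        raise ValidationError(
            "components span multiple procedures/settings; scale one "
            "procedure at a time", rule="single-procedure")
    setting = settings.pop()
    breakdown = {
        c.category: c.amount * multipliers.get(c.category, setting, target_level)
        for c in components
    }
    return float(sum(breakdown.values())), breakdown


def extrapolate_to_province(
    base_costs: LevelCosts,
    base_unit_cost: float,
    target_unit_cost: float,
) -> LevelCosts:
    """Scale every hospital-level cost by the ratio of the target province's
    unit cost (outpatient visit or inpatient bed-day) to the base province's."""
    if not base_unit_cost > 0 or not target_unit_cost > 0:
        raise ValidationError(
            f"unit costs must be > 0 (base={base_unit_cost}, "
            f"target={target_unit_cost})", rule="unit-cost-positive")
    return base_costs.scaled(target_unit_cost / base_unit_cost)


def province_weighted_cost(
    level_costs: LevelCosts,
    province: Province,
    behavior: SeekingBehavior,
    setting: str,
) -> WeightedCostResult:
    """Collapse hospital levels into one provincial average via
    hospital-seeking behaviour and the urban/rural split."""
    strata = {}
    for residence in ("urban", "rural"):
        shares = behavior.vector(residence, setting)
        total = 0.0
        for share, level in zip(shares, LEVELS):
            if share <= PROPORTION_TOL:
                continue
            if level not in level_costs.costs:
                raise ValidationError(
                    f"behaviour places {share:.3f} of {residence} {setting} "
                    f"care at {level} hospitals but procedure "
                    f"{level_costs.procedure_id!r} has no cost there",
                    rule="behaviour-level-consistency")
            total += share * level_costs.costs[level]
        strata[residence] = total
    x = province.urban_fraction
    overall = x * strata["urban"] + (1.0 - x) * strata["rural"]
    return WeightedCostResult(province.name, level_costs.procedure_id,
                              overall, strata["urban"], strata["rural"])


def aggregate_costs(
    results: list[WeightedCostResult],
    provinces: list[Province],
    grouping: str,
) -> CostTable:
    """Population-weighted aggregation of provincial results into regions or
    the national total.

    Overall strata are weighted by total province population; the urban and
    rural strata use the urban / rural sub-populations, which keeps each
    group's overall value the population-weighted mean of its strata.
    """
    if grouping not in ("region", "national"):
        raise ValidationError(f"unknown grouping {grouping!r}", rule="grouping-enum")
    by_name = {p.name: p for p in provinces}
    missing = {r.province for r in results} - set(by_name)
    if missing:
        raise ValidationError(f"results reference unknown provinces {sorted(missing)}",
                              rule="province-present")

    def group_key(res: WeightedCostResult) -> str:
        return by_name[res.province].region if grouping == "region" else "national"

    rows = []
    groups: dict[tuple[str, str], list[WeightedCostResult]] = {}
    for res in results:
        groups.setdefault((group_key(res), res.procedure_id), []).append(res)
    if not groups:
        raise ValidationError("no results to aggregate", rule="group-nonempty")
    for (gid, procedure_id), members in groups.items():
        pops = np.array([by_name[m.province].population for m in members])
        urb = np.array([by_name[m.province].urban_fraction for m in members])
        overall = np.average([m.overall for m in members], weights=pops)
        w_urban = pops * urb
        w_rural = pops * (1.0 - urb)
        urban = np.average([m.urban for m in members], weights=w_urban) \
            if w_urban.sum() > 0 else float("nan")
        rural = np.average([m.rural for m in members], weights=w_rural) \
            if w_rural.sum() > 0 else float("nan")
        rows.append({"scope": "region" if grouping == "region" else "national",
                     "scope_id": gid, "procedure_id": procedure_id,
                     "overall": float(overall), "urban": float(urban),
                     "rural": float(rural)})
    return CostTable(pd.DataFrame(rows))


def base_level_costs(bundle: Bundle) -> dict[str, LevelCosts]:
    """Steps 1-2: price-adjust the micro-cost components and scale them to
    every allowed hospital level of the base province."""
    out: dict[str, LevelCosts] = {}
    for pid, proc in bundle.procedures.items():
        comps = [
            CostComponent(c.procedure_id, c.category, c.setting,
                          adjust_price(c.amount, bundle.adjustment))
            for c in bundle.components_for(pid)
        ]
        costs = {}
        for level in proc.allowed_levels:
            total, _ = scale_to_level(comps, bundle.multipliers, level)
            costs[level] = total
        out[pid] = LevelCosts(pid, costs)
    return out


def run_reference_pipeline(bundle: Bundle) -> CostTable:
    """Run the full detailed method: provincial, regional and national rows
    for every procedure."""
    base = bundle.province(bundle.base_province)
    level_costs = base_level_costs(bundle)
    log.info("reference pipeline: %d procedures, %d provinces, base=%s",
             len(level_costs), len(bundle.provinces), base.name)

    results: list[WeightedCostResult] = []
    for pid, proc in bundle.procedures.items():
        for prov in bundle.provinces:
            extrap = extrapolate_to_province(
                level_costs[pid],
                base.unit_cost(proc.setting),
                prov.unit_cost(proc.setting))
            results.append(province_weighted_cost(extrap, prov, bundle.behavior,
                                                  proc.setting))
    province_rows = pd.DataFrame(
        [{"scope": "province", "scope_id": r.province, "procedure_id": r.procedure_id,
          "overall": r.overall, "urban": r.urban, "rural": r.rural}
         for r in results])
    regional = aggregate_costs(results, bundle.provinces, "region").frame
    national = aggregate_costs(results, bundle.provinces, "national").frame
    table = CostTable(pd.concat([province_rows, regional, national],
                                ignore_index=True))
    log.info("reference pipeline: %d cost rows", len(table))
    return table


def summary_ratios(table: CostTable, presentation_decimals: int | None = None) -> dict:
    """Headline dispersion ratios of a cost table.

    Returns, computed on unrounded values:

    - ``urban_rural``: urban/rural ratio per (scope_id, procedure) where both
      strata are present;
    - ``eastern_western``: eastern/western overall ratio per procedure, when
      both regional rows exist;
    - ``max_min_province``: highest/lowest provincial overall cost per
      procedure, with the argmax/argmin province names.

    If ``presentation_decimals`` is given, ratios are additionally half-up
    rounded to that many decimals.
    """
    f = table.frame

    def finish(x: float) -> float:
        return round_half_up(x, presentation_decimals) \
            if presentation_decimals is not None else x

    urban_rural: dict[tuple[str, str], float] = {}
    both = f["urban"].notna() & f["rural"].notna()
    for _, row in f.loc[both].iterrows():
        if row["rural"] == 0:
            raise ValidationError(
                f"zero rural cost for ({row['scope_id']}, {row['procedure_id']})",
                rule="ratio-denominator")
        urban_rural[(row["scope_id"], row["procedure_id"])] = finish(
            row["urban"] / row["rural"])

    eastern_western: dict[str, float] = {}
    reg = f[f["scope"] == "region"]
    for pid in sorted(reg["procedure_id"].unique()):
        east = reg[(reg["scope_id"] == "eastern") & (reg["procedure_id"] == pid)]
        west = reg[(reg["scope_id"] == "western") & (reg["procedure_id"] == pid)]
        if len(east) and len(west):
            denom = float(west.iloc[0]["overall"])
            if denom == 0:
                raise ValidationError(f"zero western cost for {pid}",
                                      rule="ratio-denominator")
            eastern_western[pid] = finish(float(east.iloc[0]["overall"]) / denom)

    max_min_province: dict[str, dict] = {}
    prov = f[f["scope"] == "province"]
    for pid in sorted(prov["procedure_id"].unique()):
        sub = prov[prov["procedure_id"] == pid]
        hi = sub.loc[sub["overall"].idxmax()]
        lo = sub.loc[sub["overall"].idxmin()]
        if lo["overall"] == 0:
            raise ValidationError(f"zero minimum provincial cost for {pid}",
                                  rule="ratio-denominator")
        max_min_province[pid] = {
            "ratio": finish(float(hi["overall"]) / float(lo["overall"])),
            "max_province": hi["scope_id"], "min_province": lo["scope_id"],
        }

    return {"urban_rural": urban_rural, "eastern_western": eastern_western,
            "max_min_province": max_min_province}
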
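"""Delimited-text and config I/O for input bundles and cost tables.

A *bundle directory* holds the complete input set for a costing run, as
comma-delimited UTF-8 files with mandatory header rows plus one YAML config:

``components.csv``
    procedure_id, category, setting, amount — micro-cost line items observed
    at the county-level base hospital, in source currency.
``multipliers.csv``
    category, setting, target_level, multiplier — hospital-level scaling
    factors relative to county (county rows may be omitted; they are 1).
``provinces.csv``
    name, region, urban_fraction, population, outpatient_visit_cost,
    inpatient_bedday_cost, per_capita_gdp, hdi, plus any number of extra
    numeric index columns (household consumption, doctors per capita, ...).
    A blank region falls back to the configured default grouping.
``behavior.csv``
    residence, setting, township, county, provincial — hospital-seeking
    proportions (fractions summing to 1 per row).
``config.yaml``
    adjustment: {cpi_factors: [...], fx_rate: ...}; base_province: name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    CATEGORIES,
    COST_TABLE_COLUMNS,
    DEFAULT_REGIONS,
    LEVELS,
    RESIDENCES,
    SETTINGS,
    CostComponent,
    CostTable,
    LevelMultiplierSet,
    PriceAdjustment,
    Procedure,
    Province,
    SeekingBehavior,
    ValidationError,
    round_half_up,
)

PROVINCE_FIXED_COLUMNS = [
    "name", "region", "urban_fraction", "population",
    "outpatient_visit_cost", "inpatient_bedday_cost", "per_capita_gdp", "hdi",
]


@dataclass
class Bundle:
    """A validated, in-memory input set for one costing run."""

    procedures: dict[str, Procedure]
    components: list[CostComponent]
    multipliers: LevelMultiplierSet
    provinces: list[Province]
    behavior: SeekingBehavior
    adjustment: PriceAdjustment
    base_province: str

    def __post_init__(self):
        names = [p.name for p in self.provinces]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate province names", rule="province-unique")
        if self.base_province not in names:
            raise ValidationError(
                f"base province {self.base_province!r} not among provinces",
                rule="base-province-present")
        seen: set[tuple[str, str]] = set()
        for comp in self.components:
            key = (comp.procedure_id, comp.category)
            if key in seen:
                raise ValidationError(
                    f"duplicate component for {key}", rule="component-unique")
            seen.add(key)
            if comp.procedure_id not in self.procedures:
                raise ValidationError(
                    f"component references unknown procedure {comp.procedure_id!r}",
                    rule="component-procedure")
            if comp.setting != self.procedures[comp.procedure_id].setting:
                raise ValidationError(
                    f"component setting {comp.setting!r} disagrees with "
                    f"procedure {comp.procedure_id!r}", rule="component-setting")

    def province(self, name: str) -> Province:
        for p in self.provinces:
            if p.name == name:
                return p
        raise KeyError(name)

    def components_for(self, procedure_id: str) -> list[CostComponent]:
        return [c for c in self.components if c.procedure_id == procedure_id]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"input file not found", file=str(path), rule="file-exists")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing}", file=str(path),
                              rule="schema-columns")
    return frame


def _numeric(frame: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(frame[column], errors="coerce")
    bad = vals.isna() & frame[column].notna()
    if bad.any() or frame[column].isna().any():
        row = int(frame.index[vals.isna()][0])
        raise ValidationError(
            f"non-numeric or empty value in column {column!r}",
            file=str(path), row=row + 2, rule="numeric-cell")  # +2: header + 1-basing
    return vals.to_numpy(dtype=float)


def load_components(path: Path) -> tuple[list[CostComponent], dict[str, Procedure]]:
    frame = _read_csv(path, ["procedure_id", "category", "setting", "amount"])
    _numeric(frame, "amount", path)
    components, procedures = [], {}
    for i, rec in frame.iterrows():
        try:
            comp = CostComponent(str(rec["procedure_id"]), str(rec["category"]),
                                 str(rec["setting"]), float(rec["amount"]))
        except ValidationError as err:
            raise ValidationError(str(err), file=str(path), row=i + 2,
                                  rule=err.rule) from None
        components.append(comp)
        if comp.procedure_id not in procedures:
            procedures[comp.procedure_id] = Procedure(
                comp.procedure_id, comp.procedure_id, comp.setting,
                Procedure.default_levels(comp.setting))
    return components, procedures


def load_multipliers(path: Path) -> LevelMultiplierSet:
    frame = _read_csv(path, ["category", "setting", "target_level", "multiplier"])
    _numeric(frame, "multiplier", path)
    entries: dict[tuple[str, str, str], float] = {}
    for i, rec in frame.iterrows():
        key = (str(rec["category"]), str(rec["setting"]), str(rec["target_level"]))
        entries[key] = float(rec["multiplier"])
    # county entries default to 1 even if the file omits them
    for c in CATEGORIES:
        for s in SETTINGS:
            entries.setdefault((c, s, "county"), 1.0)
    try:
        return LevelMultiplierSet(entries)
    except ValidationError as err:
        raise ValidationError(str(err), file=str(path), rule=err.rule) from None


def load_provinces(path: Path, region_overrides: dict[str, str] | None = None) -> list[Province]:
    frame = _read_csv(path, [c for c in PROVINCE_FIXED_COLUMNS if c != "region"])
    extra_cols = [c for c in frame.columns if c not in PROVINCE_FIXED_COLUMNS]
    for col in PROVINCE_FIXED_COLUMNS[2:] + extra_cols:
        _numeric(frame, col, path)
    overrides = region_overrides or {}
    provinces = []
    for i, rec in frame.iterrows():
        name = str(rec["name"])
        region = overrides.get(name) or (
            str(rec["region"]) if "region" in frame.columns and pd.notna(rec.get("region"))
            and str(rec.get("region")).strip() else DEFAULT_REGIONS.get(name))
        if region is None:
            raise ValidationError(
                f"province {name!r}: region not given and not in the default grouping",
                file=str(path), row=i + 2, rule="region-known")
        try:
            provinces.append(Province(
                name=name, region=region,
                urban_fraction=float(rec["urban_fraction"]),
                population=float(rec["population"]),
                outpatient_visit_cost=float(rec["outpatient_visit_cost"]),
                inpatient_bedday_cost=float(rec["inpatient_bedday_cost"]),
                per_capita_gdp=float(rec["per_capita_gdp"]),
                hdi=float(rec["hdi"]),
                extra_indices={c: float(rec[c]) for c in extra_cols},
            ))
        except ValidationError as err:
            raise ValidationError(str(err), file=str(path), row=i + 2,
                                  rule=err.rule) from None
    return provinces


def load_behavior(path: Path) -> SeekingBehavior:
    frame = _read_csv(path, ["residence", "setting"] + list(LEVELS))
    for col in LEVELS:
        _numeric(frame, col, path)
    proportions: dict[tuple[str, str], np.ndarray] = {}
    for i, rec in frame.iterrows():
        key = (str(rec["residence"]), str(rec["setting"]))
        vec = np.array([float(rec[lvl]) for lvl in LEVELS])
        try:
            SeekingBehavior({key: vec})  # per-row validation with row context
        except ValidationError as err:
            raise ValidationError(str(err), file=str(path), row=i + 2,
                                  rule=err.rule) from None
        proportions[key] = vec
    missing = [(r, s) for r in RESIDENCES for s in SETTINGS if (r, s) not in proportions]
    if missing:
        raise ValidationError(f"behaviour rows missing for {missing}",
                              file=str(path), rule="behaviour-complete")
    return SeekingBehavior(proportions)


def load_config(path: Path) -> dict:
    if not path.exists():
        raise ValidationError("config file not found", file=str(path), rule="file-exists")
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    adj = cfg.get("adjustment", {})
    factors = adj.get("cpi_factors", [1.0])
    fx = adj.get("fx_rate", 1.0)
    if not isinstance(factors, (list, tuple)) or not all(
            isinstance(f, (int, float)) and math.isfinite(f) for f in factors):
        raise ValidationError("adjustment.cpi_factors must be a list of numbers",
                              file=str(path), rule="cpi-list")
    cfg["adjustment"] = {"cpi_factors": [float(f) for f in factors],
                         "fx_rate": float(fx)}
    return cfg


def load_bundle(directory: str | Path, config: dict | None = None) -> Bundle:
    """Read and validate a full bundle directory; ``config`` entries override
    those in the directory's ``config.yaml``."""
    directory = Path(directory)
    cfg = load_config(directory / "config.yaml") if (directory / "config.yaml").exists() \
        else {"adjustment": {"cpi_factors": [1.0], "fx_rate": 1.0}}
    if config:
        cfg = {**cfg, **config}
    components, procedures = load_components(directory / "components.csv")
    multipliers = load_multipliers(directory / "multipliers.csv")
    provinces = load_provinces(directory / "provinces.csv", cfg.get("regions"))
    behavior = load_behavior(directory / "behavior.csv")
    adjustment = PriceAdjustment(tuple(cfg["adjustment"]["cpi_factors"]),
                                 cfg["adjustment"]["fx_rate"])
    base = cfg.get("base_province", "Shanxi")
    return Bundle(procedures=procedures, components=components,
                  multipliers=multipliers, provinces=provinces,
                  behavior=behavior, adjustment=adjustment, base_province=base)


def write_bundle(bundle: Bundle, directory: str | Path) -> Path:
    """Write a bundle back to the delimited-text schemas (round-trip inverse
    of :func:`load_bundle`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"procedure_id": c.procedure_id, "category": c.category,
          "setting": c.setting, "amount": repr(c.amount)} for c in bundle.components]
    ).to_csv(directory / "components.csv", index=False)
    pd.DataFrame(
        [{"category": c, "setting": s, "target_level": l, "multiplier": repr(m)}
         for (c, s, l), m in sorted(bundle.multipliers.entries.items())]
    ).to_csv(directory / "multipliers.csv", index=False)
    extra_cols = sorted({k for p in bundle.provinces for k in p.extra_indices})
    pd.DataFrame(
        [{"name": p.name, "region": p.region,
          "urban_fraction": repr(p.urban_fraction), "population": repr(p.population),
          "outpatient_visit_cost": repr(p.outpatient_visit_cost),
          "inpatient_bedday_cost": repr(p.inpatient_bedday_cost),
          "per_capita_gdp": repr(p.per_capita_gdp), "hdi": repr(p.hdi),
          **{c: repr(p.extra_indices[c]) for c in extra_cols}}
         for p in bundle.provinces]
    ).to_csv(directory / "provinces.csv", index=False)
    pd.DataFrame(
        [{"residence": r, "setting": s,
          **{lvl: repr(float(v)) for lvl, v in zip(LEVELS, vec)}}
         for (r, s), vec in sorted(bundle.behavior.proportions.items())]
    ).to_csv(directory / "behavior.csv", index=False)
    with open(directory / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"adjustment": {"cpi_factors": list(bundle.adjustment.cpi_factors),
                            "fx_rate": bundle.adjustment.fx_rate},
             "base_province": bundle.base_province}, fh)
    return directory


def write_cost_table(table: CostTable, destination: str | Path,
                     presentation_decimals: int = 1) -> Path:
    """Write a cost table as CSV: full-precision value columns plus half-up
    rounded presentation columns (``*_display``)."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty cost table",
                              rule="table-nonempty")
    destination = Path(destination)
    frame = table.frame.copy()
    for col in ("overall", "urban", "rural"):
        frame[f"{col}_display"] = [
            "" if pd.isna(v) else f"{round_half_up(v, presentation_decimals):.{presentation_decimals}f}"
            for v in frame[col]]
        frame[col] = [("" if pd.isna(v) else repr(float(v))) for v in frame[col]]
    destination.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(destination, index=False)
    return destination


def read_cost_table(path: str | Path) -> CostTable:
    frame = _read_csv(Path(path), COST_TABLE_COLUMNS)
    for col in ("overall", "urban", "rural"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return CostTable(frame[COST_TABLE_COLUMNS])
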
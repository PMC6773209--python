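"""Domain types and validation for province-level healthcare cost estimation.

The model works with three administrative hospital levels (township, county,
provincial), two service settings (outpatient, inpatient), and five micro-cost
categories (supplies, equipment, staff, drugs, programmatic).  All proportions
are stored as fractions in [0, 1]; percent notation in input files is converted
at parse time.  Monetary amounts are kept unrounded internally; rounding is a
presentation concern only (see :func:`round_half_up`).
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS: tuple[str, ...] = ("township", "county", "provincial")
SETTINGS: tuple[str, ...] = ("outpatient", "inpatient")
CATEGORIES: tuple[str, ...] = ("supplies", "equipment", "staff", "drugs", "programmatic")
RESIDENCES: tuple[str, ...] = ("urban", "rural")
REGIONS: tuple[str, ...] = ("eastern", "middle", "western")

#: Hospital levels at which inpatient services can be delivered.  Inpatient
#: care is restricted to county and provincial hospitals; township facilities
#: provide outpatient services only.
INPATIENT_LEVELS: tuple[str, ...] = ("county", "provincial")

PROPORTION_TOL = 1e-9

#: Default region membership of the 31 mainland provinces
#: (11 eastern, 8 middle, 12 western).  Used when provinces.csv leaves the
#: region column blank; overridable through configuration.
DEFAULT_REGIONS: dict[str, str] = {
    **dict.fromkeys(
        ["Beijing", "Tianjin", "Hebei", "Liaoning", "Jiangsu", "Shanghai",
         "Zhejiang", "Fujian", "Guangdong", "Hainan", "Shandong"],
        "eastern",
    ),
    **dict.fromkeys(
        ["Jilin", "Heilongjiang", "Shanxi", "Henan", "Anhui", "Hubei",
         "Hunan", "Jiangxi"],
        "middle",
    ),
    **dict.fromkeys(
        ["Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Guizhou",
         "Yunnan", "Tibet", "Shaanxi", "Gansu", "Qinghai", "Ningxia",
         "Xinjiang"],
        "western",
    ),
}


class ValidationError(ValueError):
    """Input failed a structural or numeric validation rule.

    Carries enough context (file, row, rule) to point the user at the exact
    offending record.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | str | None = None, rule: str | None = None):
        self.file = file
        self.row = row
        self.rule = rule
        parts = []
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        if rule is not None:
            parts.append(f"rule={rule}")
        suffix = f" [{', '.join(parts)}]" if parts else ""
        super().__init__(message + suffix)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), the convention used for
    presentation values; numpy/python builtins use banker's rounding."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _check_enum(value: str, allowed: tuple[str, ...], what: str, **ctx) -> str:
    if value not in allowed:
        raise ValidationError(
            f"unknown {what} {value!r}; expected one of {allowed}",
            rule=f"{what}-enum", **ctx)
    return value


@dataclass(frozen=True)
class CostComponent:
    """One micro-cost line item: an amount attributed to a procedure, a cost
    category and a service setting, in the source currency of the costing
    study's base year (county-level observation)."""

    procedure_id: str
    category: str
    setting: str
    amount: float

    def __post_init__(self):
        _check_enum(self.category, CATEGORIES, "category")
        _check_enum(self.setting, SETTINGS, "setting")
        if not (self.amount >= 0 and math.isfinite(self.amount)):
            raise ValidationError(
                f"component amount must be >= 0 and finite, got {self.amount}",
                rule="amount-nonnegative")


@dataclass(frozen=True)
class Procedure:
    """A costed healthcare procedure with its delivery setting and the
    hospital levels at which it can be performed."""

    procedure_id: str
    display_name: str
    setting: str
    allowed_levels: tuple[str, ...]

    def __post_init__(self):
        _check_enum(self.setting, SETTINGS, "setting")
        if not self.allowed_levels:
            raise ValidationError(
                f"procedure {self.procedure_id}: allowed_levels empty",
                rule="allowed-levels-nonempty")
        for lvl in self.allowed_levels:
            _check_enum(lvl, LEVELS, "level")
        if self.setting == "inpatient" and not set(self.allowed_levels) <= set(INPATIENT_LEVELS):
            raise ValidationError(
                f"procedure {self.procedure_id}: inpatient services are "
                f"restricted to county/provincial hospitals, got {self.allowed_levels}",
                rule="inpatient-levels")

    @staticmethod
    def default_levels(setting: str) -> tuple[str, ...]:
        return INPATIENT_LEVELS if setting == "inpatient" else LEVELS


@dataclass(frozen=True)
class PriceAdjustment:
    """Inflation and currency conversion applied to historical micro-costs:
    a chain of annual medical-CPI factors followed by a single exchange rate
    (source currency units per target currency unit)."""

    cpi_factors: tuple[float, ...]
    fx_rate: float

    def __post_init__(self):
        if any(not (f > 0 and math.isfinite(f)) for f in self.cpi_factors):
            raise ValidationError("all CPI factors must be > 0",
                                  rule="cpi-positive")
        if not (self.fx_rate > 0 and math.isfinite(self.fx_rate)):
            raise ValidationError("exchange rate must be > 0", rule="fx-positive")

    @property
    def factor(self) -> float:
        """Combined scalar: product of CPI factors divided by the fx rate."""
        return float(np.prod(self.cpi_factors)) / self.fx_rate if self.cpi_factors \
            else 1.0 / self.fx_rate


@dataclass(frozen=True)
class LevelMultiplierSet:
    """Per-category, per-setting multipliers converting county-level cost
    items to another hospital level.  County multipliers are exactly 1 by
    construction (the micro-costing observation is county-level)."""

    entries: dict[tuple[str, str, str], float]

    def __post_init__(self):
        for (category, setting, level), m in self.entries.items():
            _check_enum(category, CATEGORIES, "category")
            _check_enum(setting, SETTINGS, "setting")
            _check_enum(level, LEVELS, "level")
            if not (m > 0 and math.isfinite(m)):
                raise ValidationError(
                    f"multiplier for ({category}, {setting}, {level}) must be > 0, got {m}",
                    rule="multiplier-positive")
            if level == "county" and m != 1.0:
                raise ValidationError(
                    f"county multiplier for ({category}, {setting}) must be exactly 1, got {m}",
                    rule="county-unity")

    def get(self, category: str, setting: str, level: str) -> float:
        if level == "county":
            return 1.0
        try:
            return self.entries[(category, setting, level)]
        except KeyError:
            raise ValidationError(
                f"no multiplier for ({category}, {setting}, {level})",
                rule="multiplier-missing") from None

    @classmethod
    def identity(cls) -> "LevelMultiplierSet":
        return cls({(c, s, l): 1.0 for c in CATEGORIES for s in SETTINGS for l in LEVELS})


@dataclass
class Province:
    """One province's demographic, economic and unit-cost attributes.

    ``outpatient_visit_cost`` and ``inpatient_bedday_cost`` are the
    province-average unit costs used as cross-province scaling anchors;
    ``per_capita_gdp``, ``hdi`` and ``extra_indices`` are candidate macro-index
    predictors for the simplified scaling method.
    """

    name: str
    region: str
    urban_fraction: float
    population: float
    outpatient_visit_cost: float
    inpatient_bedday_cost: float
    per_capita_gdp: float
    hdi: float
    extra_indices: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        _check_enum(self.region, REGIONS, "region")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValidationError(
                f"province {self.name}: urban_fraction must be in [0, 1], "
                f"got {self.urban_fraction}", rule="urban-fraction-range")
        if not self.population > 0:
            raise ValidationError(f"province {self.name}: population must be > 0",
                                  rule="population-positive")
        for attr in ("outpatient_visit_cost", "inpatient_bedday_cost", "per_capita_gdp"):
            if not getattr(self, attr) > 0:
                raise ValidationError(
                    f"province {self.name}: {attr} must be > 0",
                    rule=f"{attr.replace('_', '-')}-positive")
        if not 0.0 < self.hdi < 1.0:
            raise ValidationError(
                f"province {self.name}: hdi must be in (0, 1), got {self.hdi}",
                rule="hdi-range")

    def unit_cost(self, setting: str) -> float:
        """Scaling anchor for a setting: outpatient visit cost or inpatient
        bed-day cost."""
        _check_enum(setting, SETTINGS, "setting")
        return self.outpatient_visit_cost if setting == "outpatient" \
            else self.inpatient_bedday_cost

    def index_value(self, name: str) -> float:
        """Value of a named macro-index predictor for this province."""
        if name == "per_capita_gdp":
            return self.per_capita_gdp
        if name == "hdi":
            return self.hdi
        try:
            return self.extra_indices[name]
        except KeyError:
            raise ValidationError(
                f"province {self.name}: no index column {name!r}",
                rule="index-missing") from None


@dataclass(frozen=True)
class SeekingBehavior:
    """Hospital-seeking behaviour: for each (residence, setting) pair, the
    proportions of patients attending township, county and provincial
    hospitals.  Each vector sums to 1; the inpatient township share is
    structurally zero."""

    proportions: dict[tuple[str, str], np.ndarray]

    def __post_init__(self):
        object.__setattr__(
            self, "proportions",
            {k: np.asarray(v, dtype=float) for k, v in self.proportions.items()})
        for (residence, setting), vec in self.proportions.items():
            _check_enum(residence, RESIDENCES, "residence")
            _check_enum(setting, SETTINGS, "setting")
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,):
                raise ValidationError(
                    f"behaviour vector for ({residence}, {setting}) must have "
                    f"3 entries (township, county, provincial)", rule="behaviour-shape")
            if np.any(v < -PROPORTION_TOL) or np.any(v > 1 + PROPORTION_TOL):
                raise ValidationError(
                    f"behaviour proportions for ({residence}, {setting}) must "
                    f"lie in [0, 1], got {v.tolist()}", rule="proportion-range")
            if abs(v.sum() - 1.0) > PROPORTION_TOL:
                raise ValidationError(
                    f"behaviour proportions for ({residence}, {setting}) must "
                    f"sum to 1, got {v.sum():.10f}", rule="proportion-sum")
            if setting == "inpatient" and abs(v[0]) > PROPORTION_TOL:
                raise ValidationError(
                    f"inpatient services are restricted to county/provincial "
                    f"hospitals; township share for ({residence}, {setting}) "
                    f"must be 0, got {v[0]}", rule="inpatient-township-zero")

    def vector(self, residence: str, setting: str) -> np.ndarray:
        try:
            return self.proportions[(residence, setting)]
        except KeyError:
            raise ValidationError(
                f"no behaviour vector for ({residence}, {setting})",
                rule="behaviour-missing") from None


@dataclass(frozen=True)
class LevelCosts:
    """Cost of one procedure at each hospital level where it is offered."""

    procedure_id: str
    costs: dict[str, float]

    def __post_init__(self):
        for level, cost in self.costs.items():
            _check_enum(level, LEVELS, "level")
            if not (cost >= 0 and math.isfinite(cost)):
                raise ValidationError(
                    f"procedure {self.procedure_id}: cost at {level} must be "
                    f">= 0, got {cost}", rule="level-cost-nonnegative")

    def scaled(self, ratio: float) -> "LevelCosts":
        return LevelCosts(self.procedure_id,
                          {lvl: c * ratio for lvl, c in self.costs.items()})


# CostTable scope labels
SCOPES: tuple[str, ...] = ("province", "region", "national")

COST_TABLE_COLUMNS = ["scope", "scope_id", "procedure_id", "overall", "urban", "rural"]


@dataclass
class CostTable:
    """Procedure costs by scope (province / region / national) with overall,
    urban and rural strata.

    Backed by a DataFrame with columns ``scope, scope_id, procedure_id,
    overall, urban, rural``.  The urban/rural strata may be absent (NaN) for
    tables produced by the simplified scaling method, which yields overall
    costs only.  Where both strata are present, the overall value must lie
    between them (it is their population-weighted mean).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COST_TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"cost table missing columns {missing}",
                                  rule="cost-table-columns")
        self.frame = self.frame[COST_TABLE_COLUMNS].reset_index(drop=True)
        bad_scope = set(self.frame["scope"]) - set(SCOPES)
        if bad_scope:
            raise ValidationError(f"unknown scope values {sorted(bad_scope)}",
                                  rule="scope-enum")
        dup = self.frame.duplicated(subset=["scope", "scope_id", "procedure_id"])
        if dup.any():
            raise ValidationError("duplicate (scope, scope_id, procedure_id) rows",
                                  rule="cost-table-unique")
        self.validate()

    def validate(self) -> None:
        f = self.frame
        for col in ("overall", "urban", "rural"):
            vals = f[col].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] < 0):
                raise ValidationError(f"negative cost in column {col}",
                                      rule="cost-nonnegative")
        both = f["urban"].notna() & f["rural"].notna()
        if both.any():
            sub = f.loc[both]
            lo = np.minimum(sub["urban"], sub["rural"]) - 1e-9
            hi = np.maximum(sub["urban"], sub["rural"]) + 1e-9
            bad = ~((sub["overall"] >= lo) & (sub["overall"] <= hi))
            if bad.any():
                row = sub.loc[bad].iloc[0]
                raise ValidationError(
                    f"overall cost outside [min(urban, rural), max(urban, rural)] "
                    f"for ({row['scope']}, {row['scope_id']}, {row['procedure_id']})",
                    rule="overall-between-strata")

    def value(self, scope: str, scope_id: str, procedure_id: str,
              stratum: str = "overall") -> float:
        f = self.frame
        sel = f[(f["scope"] == scope) & (f["scope_id"] == scope_id)
                & (f["procedure_id"] == procedure_id)]
        if sel.empty:
            raise KeyError((scope, scope_id, procedure_id))
        return float(sel.iloc[0][stratum])

    def subset(self, scope: str) -> pd.DataFrame:
        return self.frame[self.frame["scope"] == scope].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)
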
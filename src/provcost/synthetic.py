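"""Synthetic input bundles with known ground truth.

The generator emulates the statistical structure the costing framework
assumes: a latent development index (HDI-like) per province; per-capita GDP
rank-correlated with it through a Gaussian copula; province unit costs that
follow an exponential law in the latent index, ``A * exp(B * hdi) + C``,
with multiplicative log-normal noise; Dirichlet hospital-seeking behaviour
with urban mass shifted toward county/provincial hospitals and a
structurally zero inpatient township share; and log-normal micro-cost line
items at the county-level base hospital.

Defaults are set to a realistic mainland-China-like regime: 31 provinces,
HDI spanning 0.55-0.90, per-capita GDP roughly $4k-21k, and unit-cost
dispersion of about 3.4x between the least and most developed provinces,
comparable to the 3-5x spread the detailed method produces for real
procedure costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .detailed import run_reference_pipeline
from .io import Bundle
from .types import (
    CATEGORIES,
    SETTINGS,
    CostComponent,
    CostTable,
    LevelMultiplierSet,
    PriceAdjustment,
    Procedure,
    SeekingBehavior,
    Province,
    ValidationError,
)

DEGRADE_MODES = ("shuffle_behaviour", "flatten_curve", "corrupt_proportions")

#: Default Dirichlet concentrations over (township, county, provincial) for
#: outpatient care and (county, provincial) for inpatient care.  Urban
#: residents favour higher-level hospitals; rural residents favour township
#: and county facilities.
DEFAULT_BEHAVIOUR_CONCENTRATION: dict[tuple[str, str], tuple[float, ...]] = {
    ("urban", "outpatient"): (2.0, 5.0, 5.0),
    ("rural", "outpatient"): (6.0, 4.0, 2.0),
    ("urban", "inpatient"): (4.0, 4.0),
    ("rural", "inpatient"): (6.0, 2.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic world."""

    n_provinces: int = 31
    seed: int = 0
    #: (A, B, C) of the unit-cost law per setting, in source currency per
    #: visit (outpatient) or bed-day (inpatient), B per unit of HDI.
    curve_constants: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"outpatient": (2.0, 4.0, 5.0),
                                 "inpatient": (8.0, 4.0, 20.0)})
    #: sd of the multiplicative log-normal noise on unit costs.
    noise_sd: float = 0.05
    hdi_range: tuple[float, float] = (0.55, 0.90)
    gdp_hdi_correlation: float = 0.85
    #: per-capita GDP marginal: log-normal, median ``gdp_median`` with
    #: log-scale sd ``gdp_log_sd`` (default span roughly $4k-21k).
    gdp_median: float = 8500.0
    gdp_log_sd: float = 0.45
    behaviour_concentration: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOUR_CONCENTRATION))
    n_procedures: dict[str, int] = field(
        default_factory=lambda: {"outpatient": 3, "inpatient": 2})
    urban_fraction_range: tuple[float, float] = (0.2, 0.95)
    #: extra macro-index columns: name -> copula correlation with the latent
    #: index (for predictor-ranking experiments).
    extra_index_correlations: dict[str, float] = field(default_factory=dict)
    cpi_factors: tuple[float, ...] = (1.06, 1.05, 1.05, 1.04, 1.05,
                                      1.04, 1.05, 1.06, 1.04, 1.05)
    fx_rate: float = 6.8632

    def validate(self) -> None:
        if self.n_provinces < 2:
            raise ValidationError("need at least 2 provinces", rule="n-provinces")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0", rule="noise-nonnegative")
        lo, hi = self.hdi_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("hdi_range must be an interval within (0, 1)",
                                  rule="hdi-range")
        if not -1.0 <= self.gdp_hdi_correlation <= 1.0:
            raise ValidationError("gdp_hdi_correlation must be in [-1, 1]",
                                  rule="correlation-range")
        lo, hi = self.urban_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("urban_fraction_range must lie within [0, 1]",
                                  rule="urban-range")
        for key, alphas in self.behaviour_concentration.items():
            if any(a <= 0 for a in alphas):
                raise ValidationError(
                    f"behaviour concentration for {key} must be positive",
                    rule="concentration-positive")
        for setting, n in self.n_procedures.items():
            if setting not in SETTINGS or n < 1:
                raise ValidationError("n_procedures must map each setting to >= 1",
                                      rule="n-procedures")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    curve_constants: dict[str, tuple[float, float, float]]
    latent_index: np.ndarray           # HDI per province, generation order
    reference: CostTable               # detailed-method output for the bundle

    def unit_cost_curve(self, setting: str, x: np.ndarray) -> np.ndarray:
        a, b, c = self.curve_constants[setting]
        return a * np.exp(b * np.asarray(x, dtype=float)) + c


def _copula_uniforms(rng: np.random.Generator, n: int, rho: float,
                     base_z: np.ndarray) -> np.ndarray:
    """Uniforms rank-correlated with ``base_z`` at Gaussian-copula level rho."""
    z = rho * base_z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(n)
    return stats.norm.cdf(z)


def generate_bundle(config: GeneratorConfig) -> tuple[Bundle, GroundTruth]:
    """Draw one complete input bundle plus its ground truth; deterministic
    for a given config (including seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_provinces

    # latent development index and correlated macro-indices
    z_hdi = rng.standard_normal(n)
    lo, hi = config.hdi_range
    hdi = lo + (hi - lo) * stats.norm.cdf(z_hdi)
    u_gdp = _copula_uniforms(rng, n, config.gdp_hdi_correlation, z_hdi)
    gdp = stats.lognorm.ppf(u_gdp, s=config.gdp_log_sd, scale=config.gdp_median)
    extra = {}
    for name, rho in config.extra_index_correlations.items():
        u = _copula_uniforms(rng, n, rho, z_hdi)
        extra[name] = stats.lognorm.ppf(u, s=0.4, scale=5000.0)

    # unit costs on the exponential law, with multiplicative noise
    unit = {}
    for setting in SETTINGS:
        a, b, c = config.curve_constants[setting]
        noise = np.exp(config.noise_sd * rng.standard_normal(n)) \
            if config.noise_sd > 0 else np.ones(n)
        unit[setting] = (a * np.exp(b * hdi) + c) * noise

    urb_lo, urb_hi = config.urban_fraction_range
    urban = rng.uniform(urb_lo, urb_hi, size=n) if urb_hi > urb_lo \
        else np.full(n, urb_lo)
    population = rng.lognormal(mean=np.log(4.0e7), sigma=0.6, size=n)
    region_cycle = ("eastern", "middle", "western")

    provinces = [
        Province(
            name=f"P{i + 1:02d}", region=region_cycle[i % 3],
            urban_fraction=float(urban[i]), population=float(population[i]),
            outpatient_visit_cost=float(unit["outpatient"][i]),
            inpatient_bedday_cost=float(unit["inpatient"][i]),
            per_capita_gdp=float(gdp[i]), hdi=float(hdi[i]),
            extra_indices={k: float(v[i]) for k, v in extra.items()},
        )
        for i in range(n)
    ]

    # one shared hospital-seeking behaviour matrix
    proportions = {}
    for (residence, setting), alphas in config.behaviour_concentration.items():
        draw = rng.dirichlet(alphas)
        if setting == "inpatient":
            vec = np.concatenate([[0.0], draw])  # township share is structural 0
        else:
            vec = draw
        proportions[(residence, setting)] = vec
    behavior = SeekingBehavior(proportions)

    # county-level micro-cost line items; outpatient items are clinic-visit
    # scale, inpatient items are admission scale (source currency)
    scale_by_setting = {"outpatient": 8.0, "inpatient": 400.0}
    components, procedures = [], {}
    for setting in SETTINGS:
        for j in range(config.n_procedures[setting]):
            pid = f"{setting[:3]}_proc_{j + 1}"
            procedures[pid] = Procedure(pid, pid, setting,
                                        Procedure.default_levels(setting))
            for category in CATEGORIES:
                amount = float(rng.lognormal(
                    mean=np.log(scale_by_setting[setting]), sigma=0.5))
                components.append(CostComponent(pid, category, setting, amount))

    # hospital-level multipliers: township cheaper, provincial dearer
    entries = {}
    for category in CATEGORIES:
        for setting in SETTINGS:
            entries[(category, setting, "township")] = float(rng.uniform(0.4, 0.8))
            entries[(category, setting, "county")] = 1.0
            entries[(category, setting, "provincial")] = float(rng.uniform(1.3, 2.2))
    multipliers = LevelMultiplierSet(entries)

    bundle = Bundle(
        procedures=procedures, components=components, multipliers=multipliers,
        provinces=provinces, behavior=behavior,
        adjustment=PriceAdjustment(config.cpi_factors, config.fx_rate),
        base_province=provinces[0].name)
    truth = GroundTruth(curve_constants=dict(config.curve_constants),
                        latent_index=hdi,
                        reference=run_reference_pipeline(bundle))
    return bundle, truth


def _unvalidated_behavior(proportions: dict) -> SeekingBehavior:
    """Construct a SeekingBehavior without invariant checks, for building
    negative-control fixtures that the loader must reject."""
    obj = object.__new__(SeekingBehavior)
    object.__setattr__(obj, "proportions",
                       {k: np.asarray(v, dtype=float) for k, v in proportions.items()})
    return obj


def degrade_bundle(bundle: Bundle, mode: str, seed: int = 0) -> Bundle:
    """Perturb a valid bundle into a negative-control fixture.

    ``shuffle_behaviour`` permutes behaviour vectors across residence groups;
    ``flatten_curve`` removes the unit-cost/index relationship (every
    province gets the across-province mean unit costs, i.e. B = 0);
    ``corrupt_proportions`` breaks one behaviour row's sum-to-1 invariant and
    therefore yields a bundle that load-time validation must reject after a
    round trip through the file formats.
    """
    if mode not in DEGRADE_MODES:
        raise ValidationError(f"unknown degrade mode {mode!r}", rule="degrade-mode")
    rng = np.random.default_rng(seed)

    if mode == "shuffle_behaviour":
        residences = ("urban", "rural")
        proportions = {}
        for setting in SETTINGS:
            perm = rng.permutation(len(residences))
            for src, dst in enumerate(perm):
                proportions[(residences[dst], setting)] = \
                    bundle.behavior.vector(residences[src], setting)
        return replace(bundle, behavior=SeekingBehavior(proportions))

    if mode == "flatten_curve":
        mean_out = float(np.mean([p.outpatient_visit_cost for p in bundle.provinces]))
        mean_inp = float(np.mean([p.inpatient_bedday_cost for p in bundle.provinces]))
        provinces = [replace(p, outpatient_visit_cost=mean_out,
                             inpatient_bedday_cost=mean_inp, extra_indices=dict(p.extra_indices))
                     for p in bundle.provinces]
        return replace(bundle, provinces=provinces)

    # corrupt_proportions
    proportions = dict(bundle.behavior.proportions)
    key = sorted(proportions)[rng.integers(len(proportions))]
    vec = proportions[key].copy()
    vec[1] += 0.1  # breaks the sum rule
    proportions[key] = vec
    return replace(bundle, behavior=_unvalidated_behavior(proportions))
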
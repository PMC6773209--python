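"""The six-step reference method: unit operations, pipeline, and its
independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from provcost.detailed import (
    adjust_price,
    aggregate_costs,
    base_level_costs,
    derive_level_multipliers,
    extrapolate_to_province,
    province_weighted_cost,
    run_reference_pipeline,
    scale_to_level,
    summary_ratios,
    WeightedCostResult,
)
from provcost.io import Bundle
from provcost.synthetic import GeneratorConfig, generate_bundle
from provcost.types import (
    CostComponent,
    LevelCosts,
    LevelMultiplierSet,
    PriceAdjustment,
    Province,
    SeekingBehavior,
    ValidationError,
)

from conftest import make_tiny_bundle


class TestAdjustPrice:
    @pytest.mark.parametrize("amount,factors,fx,expected", [
        (100.0, (1.0,), 1.0, 100.0),              # identity
        (68.632, (1.0,), 6.8632, 10.0),           # currency conversion only
        (100.0, (1.03, 1.02), 2.0, 52.53),        # chained CPI then conversion
    ])
    def test_chained_cpi_then_conversion(self, amount, factors, fx, expected):
        adj = PriceAdjustment(factors, fx)
        assert adjust_price(amount, adj) == pytest.approx(expected, rel=1e-12)

    def test_factor_order_is_immaterial(self):
        a = PriceAdjustment((1.03, 1.02, 1.07), 3.1)
        b = PriceAdjustment((1.07, 1.02, 1.03), 3.1)
        assert adjust_price(55.0, a) == pytest.approx(adjust_price(55.0, b), rel=1e-12)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValidationError):
            adjust_price(-1.0, PriceAdjustment((1.0,), 1.0))


class TestDeriveLevelMultipliers:
    REFS = {("staff_exp", "township"): 50.0, ("staff_exp", "county"): 100.0,
            ("staff_exp", "provincial"): 180.0,
            ("flat", "township"): 7.0, ("flat", "county"): 7.0,
            ("flat", "provincial"): 7.0}

    def test_ratios_to_county_baseline(self):
        ms = derive_level_multipliers(self.REFS, {"staff": "staff_exp"})
        assert ms.get("staff", "outpatient", "township") == pytest.approx(0.5)
        assert ms.get("staff", "inpatient", "county") == 1.0
        assert ms.get("staff", "outpatient", "provincial") == pytest.approx(1.8)

    def test_constant_series_gives_unit_multipliers(self):
        ms = derive_level_multipliers(self.REFS, {"supplies": "flat"})
        for level in ("township", "county", "provincial"):
            assert ms.get("supplies", "outpatient", level) == pytest.approx(1.0)

    def test_missing_county_baseline_and_unknown_category(self):
        with pytest.raises(ValidationError, match="county"):
            derive_level_multipliers({("s", "township"): 1.0}, {"staff": "s"})
        with pytest.raises(ValidationError, match="category"):
            derive_level_multipliers(self.REFS, {"overhead": "staff_exp"})


class TestScaleToLevel:
    def test_weighted_category_sum(self):
        comps = [CostComponent("p", "staff", "outpatient", 10.0),
                 CostComponent("p", "supplies", "outpatient", 5.0)]
        ms = LevelMultiplierSet({("staff", "outpatient", "provincial"): 2.0,
                                 ("supplies", "outpatient", "provincial"): 1.5})
        total, breakdown = scale_to_level(comps, ms, "provincial")
        assert total == pytest.approx(27.5)
        assert breakdown == {"staff": 20.0, "supplies": 7.5}

    def test_identity_multipliers_reproduce_county_total(self):
        comps = [CostComponent("p", "staff", "inpatient", 10.0),
                 CostComponent("p", "drugs", "inpatient", 5.0)]
        total, _ = scale_to_level(comps, LevelMultiplierSet.identity(), "township")
        assert total == pytest.approx(15.0)

    def test_empty_component_set_costs_nothing(self):
        assert scale_to_level([], LevelMultiplierSet.identity(), "county")[0] == 0.0

    def test_missing_multiplier_is_an_error(self):
        comps = [CostComponent("p", "staff", "outpatient", 10.0)]
        with pytest.raises(ValidationError, match="multiplier"):
            scale_to_level(comps, LevelMultiplierSet({}), "provincial")


class TestExtrapolateToProvince:
    BASE = LevelCosts("p", {"county": 100.0, "provincial": 200.0})

    def test_equal_unit_costs_leave_costs_unchanged(self):
        out = extrapolate_to_province(self.BASE, 40.0, 40.0)
        assert out.costs == self.BASE.costs

    def test_unit_cost_ratio_scales_every_level(self):
        out = extrapolate_to_province(self.BASE, 40.0, 60.0)
        assert out.costs == pytest.approx({"county": 150.0, "provincial": 300.0})

    def test_zero_level_cost_stays_zero(self):
        out = extrapolate_to_province(LevelCosts("p", {"county": 0.0}), 40.0, 60.0)
        assert out.costs["county"] == 0.0

    def test_nonpositive_unit_cost_rejected(self):
        with pytest.raises(ValidationError):
            extrapolate_to_province(self.BASE, 0.0, 60.0)


def _province(urban_fraction=0.6):
    return Province("X", "eastern", urban_fraction, 1e6, 10.0, 100.0, 9000.0, 0.7)


def _behavior(urban=(0.5, 0.3, 0.2), rural=(0.8, 0.1, 0.1)):
    return SeekingBehavior({
        ("urban", "outpatient"): np.array(urban),
        ("rural", "outpatient"): np.array(rural),
        ("urban", "inpatient"): np.array([0.0, 0.5, 0.5]),
        ("rural", "inpatient"): np.array([0.0, 0.8, 0.2]),
    })


class TestProvinceWeightedCost:
    def test_level_behaviour_urban_rural_combination(self):
        levels = LevelCosts("p", {"township": 2.0, "county": 4.0, "provincial": 6.0})
        res = province_weighted_cost(levels, _province(0.6), _behavior(), "outpatient")
        assert res.urban == pytest.approx(3.4)
        assert res.rural == pytest.approx(2.6)
        assert res.overall == pytest.approx(3.08)
        # overall is exactly the urban-fraction blend of the strata
        assert res.overall == pytest.approx(0.6 * res.urban + 0.4 * res.rural,
                                            rel=1e-12)

    def test_degenerate_weights_pick_out_one_level(self):
        levels = LevelCosts("p", {"township": 7.0, "county": 1.0, "provincial": 1.0})
        res = province_weighted_cost(
            levels, _province(1.0), _behavior(urban=(1.0, 0.0, 0.0)), "outpatient")
        assert res.overall == pytest.approx(7.0)

    def test_share_on_uncosted_level_is_an_error(self):
        levels = LevelCosts("p", {"county": 4.0, "provincial": 6.0})
        with pytest.raises(ValidationError, match="no cost"):
            province_weighted_cost(levels, _province(), _behavior(), "outpatient")

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(costs=st.lists(st.floats(0.0, 1e4), min_size=3, max_size=3),
           x=st.floats(0.0, 1.0),
           w=st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6))
    def test_result_bounded_by_level_costs(self, costs, x, w):
        """The weighted cost is a convex combination of the level costs."""
        urban = np.array(w[:3]) / sum(w[:3])
        rural = np.array(w[3:]) / sum(w[3:])
        levels = LevelCosts("p", dict(zip(("township", "county", "provincial"), costs)))
        res = province_weighted_cost(
            levels, _province(x), _behavior(urban=urban, rural=rural), "outpatient")
        assert min(costs) - 1e-9 <= res.overall <= max(costs) + 1e-9
        assert min(costs) - 1e-9 <= res.urban <= max(costs) + 1e-9

    def test_constant_level_costs_collapse_to_that_constant(self):
        levels = LevelCosts("p", dict.fromkeys(("township", "county", "provincial"), 3.7))
        res = province_weighted_cost(levels, _province(0.23), _behavior(), "outpatient")
        assert res.overall == pytest.approx(3.7, rel=1e-12)


class TestAggregateCosts:
    def _results(self, overalls, urbans=None, rurals=None):
        urbans = urbans or overalls
        rurals = rurals or overalls
        return [WeightedCostResult(f"P{i}", "p", o, u, r)
                for i, (o, u, r) in enumerate(zip(overalls, urbans, rurals))]

    def _provinces(self, populations, urban_fraction=0.5):
        return [Province(f"P{i}", "eastern", urban_fraction, pop, 10, 100, 9000, 0.7)
                for i, pop in enumerate(populations)]

    def test_single_province_group_is_identity(self):
        table = aggregate_costs(self._results([12.0]), self._provinces([5e6]),
                                "national")
        assert table.value("national", "national", "p") == pytest.approx(12.0)

    def test_equal_populations_give_simple_mean(self):
        table = aggregate_costs(self._results([10.0, 20.0]),
                                self._provinces([2e6, 2e6]), "national")
        assert table.value("national", "national", "p") == pytest.approx(15.0)

    def test_population_weighted_mean(self):
        table = aggregate_costs(self._results([10.0, 20.0]),
                                self._provinces([1.0e6, 3.0e6]), "national")
        assert table.value("national", "national", "p") == pytest.approx(17.5)

    def test_invariant_under_uniform_population_rescaling(self):
        res = self._results([3.0, 8.0, 11.0], [4.0, 9.0, 12.0], [2.0, 7.0, 10.0])
        t1 = aggregate_costs(res, self._provinces([1e6, 4e6, 2e6]), "national")
        t2 = aggregate_costs(res, self._provinces([7e6, 28e6, 14e6]), "national")
        for stratum in ("overall", "urban", "rural"):
            assert t1.value("national", "national", "p", stratum) == \
                pytest.approx(t2.value("national", "national", "p", stratum),
                              rel=1e-12)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValidationError):
            aggregate_costs([], self._provinces([1e6]), "national")


class TestSummaryRatios:
    def test_identical_strata_give_unit_ratios(self):
        res = [WeightedCostResult("P0", "p", 5.0, 5.0, 5.0)]
        provs = [Province("P0", "eastern", 0.5, 1e6, 10, 100, 9000, 0.7)]
        table = aggregate_costs(res, provs, "national")
        ratios = summary_ratios(table)
        assert ratios["urban_rural"][("national", "p")] == pytest.approx(1.0)

    def test_published_style_urban_rural_and_regional_ratios(self):
        frame = pd.DataFrame([
            {"scope": "national", "scope_id": "national", "procedure_id": "ckc",
             "overall": 280.7, "urban": 314.7, "rural": 226.7},
            {"scope": "region", "scope_id": "eastern", "procedure_id": "ckc",
             "overall": 351.0, "urban": 383.3, "rural": 278.8},
            {"scope": "region", "scope_id": "western", "procedure_id": "ckc",
             "overall": 214.1, "urban": 244.3, "rural": 181.3},
        ])
        from provcost.types import CostTable
        ratios = summary_ratios(CostTable(frame), presentation_decimals=1)
        assert ratios["urban_rural"][("national", "ckc")] == 1.4
        assert ratios["eastern_western"]["ckc"] == 1.6


def _brute_force_reference(bundle: Bundle) -> dict:
    """Independent flat-enumeration recomputation of the whole pipeline
    (loops over residence x level terms; no reuse of pipeline code)."""
    inflator = 1.0
    for f in bundle.adjustment.cpi_factors:
        inflator *= f
    inflator /= bundle.adjustment.fx_rate
    base = bundle.province(bundle.base_province)
    out = {}
    for pid, proc in bundle.procedures.items():
        level_cost = {}
        for level in proc.allowed_levels:
            total = 0.0
            for c in bundle.components:
                if c.procedure_id != pid:
                    continue
                m = 1.0 if level == "county" else \
                    bundle.multipliers.entries[(c.category, c.setting, level)]
                total += c.amount * inflator * m
            level_cost[level] = total
        for prov in bundle.provinces:
            if proc.setting == "outpatient":
                ratio = prov.outpatient_visit_cost / base.outpatient_visit_cost
            else:
                ratio = prov.inpatient_bedday_cost / base.inpatient_bedday_cost
            strata = {}
            for residence in ("urban", "rural"):
                shares = bundle.behavior.vector(residence, proc.setting)
                acc = 0.0
                for share, level in zip(shares, ("township", "county", "provincial")):
                    if share > 0:
                        acc += share * level_cost[level] * ratio
                strata[residence] = acc
            x = prov.urban_fraction
            out[(prov.name, pid)] = {
                "urban": strata["urban"], "rural": strata["rural"],
                "overall": x * strata["urban"] + (1 - x) * strata["rural"]}
    return out


class TestReferencePipeline:
    def test_row_count_two_provinces_one_region_national(self):
        bundle = make_tiny_bundle()
        bundle.provinces[1].region = "eastern"  # single region
        table = run_reference_pipeline(bundle)
        # 2 procedures x (2 provinces + 1 region + national)
        assert len(table) == 2 * (2 + 1 + 1)

    def test_all_identity_scalings_reproduce_county_micro_total(self):
        """Identity multipliers, equal unit costs and uniform behaviour make
        every row equal the adjusted county micro-cost total."""
        bundle = make_tiny_bundle(
            multipliers=LevelMultiplierSet.identity(),
            provinces=[
                Province("Alpha", "eastern", 0.6, 1e7, 10.0, 100.0, 12000, 0.85),
                Province("Beta", "western", 0.4, 3e7, 10.0, 100.0, 5000, 0.60),
            ])
        table = run_reference_pipeline(bundle)
        assert table.value("national", "national", "screen") == pytest.approx(15.0, rel=1e-12)
        assert table.value("province", "Beta", "surgery") == pytest.approx(150.0, rel=1e-12)

    def test_homogeneous_of_degree_one_in_component_amounts(self, tiny_bundle):
        doubled = make_tiny_bundle(components=[
            CostComponent(c.procedure_id, c.category, c.setting, 2 * c.amount)
            for c in tiny_bundle.components])
        t1 = run_reference_pipeline(tiny_bundle).frame.set_index(
            ["scope", "scope_id", "procedure_id"])
        t2 = run_reference_pipeline(doubled).frame.set_index(
            ["scope", "scope_id", "procedure_id"])
        np.testing.assert_allclose(2 * t1["overall"], t2.loc[t1.index, "overall"],
                                   rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_on_small_bundles(self, seed):
        bundle, _ = generate_bundle(GeneratorConfig(
            n_provinces=3, seed=seed,
            n_procedures={"outpatient": 2, "inpatient": 1}))
        table = run_reference_pipeline(bundle)
        oracle = _brute_force_reference(bundle)
        for (prov, pid), expected in oracle.items():
            for stratum in ("overall", "urban", "rural"):
                assert table.value("province", prov, pid, stratum) == \
                    pytest.approx(expected[stratum], rel=1e-9)

    def test_deterministic(self, tiny_bundle):
        t1 = run_reference_pipeline(tiny_bundle)
        t2 = run_reference_pipeline(make_tiny_bundle())
        pd.testing.assert_frame_equal(t1.frame, t2.frame)
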
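import numpy as np
import pytest

from provcost.io import Bundle
from provcost.synthetic import GeneratorConfig, generate_bundle
from provcost.types import (
    CostComponent,
    LevelMultiplierSet,
    PriceAdjustment,
    Procedure,
    Province,
    SeekingBehavior,
)


def make_tiny_bundle(**overrides) -> Bundle:
    """A hand-written two-province, two-procedure bundle with simple numbers
    (identity price adjustment) used across unit tests."""
    procedures = {
        "screen": Procedure("screen", "screen", "outpatient",
                            ("township", "county", "provincial")),
        "surgery": Procedure("surgery", "surgery", "inpatient",
                             ("county", "provincial")),
    }
    components = [
        CostComponent("screen", "staff", "outpatient", 10.0),
        CostComponent("screen", "supplies", "outpatient", 5.0),
        CostComponent("surgery", "staff", "inpatient", 100.0),
        CostComponent("surgery", "drugs", "inpatient", 50.0),
    ]
    entries = {}
    for cat in ("staff", "supplies", "drugs", "equipment", "programmatic"):
        for setting in ("outpatient", "inpatient"):
            entries[(cat, setting, "township")] = 0.5
            entries[(cat, setting, "county")] = 1.0
            entries[(cat, setting, "provincial")] = 2.0
    provinces = [
        Province("Alpha", "eastern", 0.6, 1.0e7, 10.0, 100.0, 12000.0, 0.85),
        Province("Beta", "western", 0.4, 3.0e7, 5.0, 50.0, 5000.0, 0.60),
    ]
    behavior = SeekingBehavior({
        ("urban", "outpatient"): np.array([0.2, 0.3, 0.5]),
        ("rural", "outpatient"): np.array([0.6, 0.3, 0.1]),
        ("urban", "inpatient"): np.array([0.0, 0.4, 0.6]),
        ("rural", "inpatient"): np.array([0.0, 0.7, 0.3]),
    })
    kwargs = dict(
        procedures=procedures, components=components,
        multipliers=LevelMultiplierSet(entries), provinces=provinces,
        behavior=behavior, adjustment=PriceAdjustment((1.0,), 1.0),
        base_province="Alpha")
    kwargs.update(overrides)
    return Bundle(**kwargs)


@pytest.fixture
def tiny_bundle() -> Bundle:
    return make_tiny_bundle()


@pytest.fixture(scope="session")
def world31():
    """One 31-province synthetic world (default study conditions, seed 11)."""
    return generate_bundle(GeneratorConfig(n_provinces=31, seed=11))
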
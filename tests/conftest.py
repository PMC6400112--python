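"""Shared fixtures: reference parameter sets and the calibrated synthetic cohort."""

import pytest
from hypothesis import settings

from demscreen.decision_model import EconomicParams, TestCharacteristics
from demscreen.io import load_reference_tables
from demscreen.synthetic_data import ScenarioSpec, calibrate_to_anchors

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_test() -> TestCharacteristics:
    return TestCharacteristics(se=0.9, sp=0.9, p=0.1)


@pytest.fixture(scope="session")
def ref_econ() -> EconomicParams:
    return EconomicParams()


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def calibrated_spec() -> ScenarioSpec:
    """Synthetic cohort calibrated to the 2011/2031 prevalence anchors
    (340,000 -> 674,000 diagnosed cases)."""
    result = calibrate_to_anchors(
        ScenarioSpec(), [(2011, 340_000.0), (2031, 674_000.0)]
    )
    assert result.residual <= 0.05
    return result.spec
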
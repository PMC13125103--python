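import pytest

from diastolic_cdss import (
    ThresholdConfig,
    build_default_rulebase,
    case_a,
    case_b,
    derive_all,
)


@pytest.fixture(scope="session")
def study_a():
    return case_a()


@pytest.fixture(scope="session")
def study_b():
    return case_b()


@pytest.fixture(scope="session")
def derived_a(study_a):
    return derive_all(study_a)


@pytest.fixture(scope="session")
def derived_b(study_b):
    return derive_all(study_b)


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def rulebase(thresholds):
    return build_default_rulebase(thresholds)
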
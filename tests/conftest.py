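import pytest

from abca1func.config import CalibrationConfig
from abca1func.domains import DomainMap, VariantRecord
from abca1func.studydata import LOSS_OF_FUNCTION_VARIANTS


@pytest.fixture(scope="session")
def config() -> CalibrationConfig:
    return CalibrationConfig()


@pytest.fixture(scope="session")
def domain_map() -> DomainMap:
    return DomainMap.default()


@pytest.fixture(scope="session")
def lof_variants() -> list[VariantRecord]:
    """The 15 published loss-of-function variants as parsed records."""
    return [VariantRecord.from_name(name) for name in LOSS_OF_FUNCTION_VARIANTS]
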
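import pytest

from coroflow import (
    ActivityPresets,
    CatheterCatalog,
    FluidProperties,
)


@pytest.fixture(scope="session")
def fluid():
    """Default blood-analog working fluid (3.7 cP)."""
    return FluidProperties()


@pytest.fixture(scope="session")
def catalog():
    """Default 4/5/6 Fr catalog."""
    return CatheterCatalog.default()


@pytest.fixture(scope="session")
def presets():
    """Shipped per-vessel, per-activity distal resistance presets."""
    return ActivityPresets.default()
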
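import pytest

from ddt_assay.construct_model import LAYOUT_NAMES, build_reference_construct


@pytest.fixture(scope="session")
def constructs():
    """All four reference layouts, built once per session."""
    return {name: build_reference_construct(name) for name in LAYOUT_NAMES}


@pytest.fixture(scope="session")
def pll1_2c(constructs):
    return constructs["pLL1_2c"]
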
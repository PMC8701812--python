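import pytest
from hypothesis import HealthCheck, settings

import relaxprint as rp
from relaxprint.pipeline import analyze_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    # grid fixtures are immutable, so sharing them across generated examples is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic study panel (28 pure brands + FO-SO mixtures), seed 0."""
    return rp.generate_panel(rp.PanelConfig(seed=0))


@pytest.fixture(scope="session")
def analysis(default_panel):
    """Full pipeline analysis of the default panel."""
    return analyze_panel(default_panel)


@pytest.fixture()
def default_grid():
    return rp.AcquisitionProtocol().grid
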
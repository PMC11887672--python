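import pytest
from hypothesis import HealthCheck, settings

from lncscreen import ScreenConfig, SimulationConfig, run_screen, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic bundle (seed 1): 16 GOIs, 112 in-window lncRNAs."""
    out = tmp_path_factory.mktemp("bundle_seed1")
    return simulate_dataset(SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def default_screen(default_bundle):
    """One full screen run on the default bundle: (records, funnel, bundle)."""
    config = ScreenConfig.from_bundle_dir(default_bundle.out_dir)
    records, funnel = run_screen(config)
    return records, funnel, default_bundle
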
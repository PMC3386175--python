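import pytest

from dhsevo.pipeline import run_chromatin_pipeline
from dhsevo.syndata import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_ds():
    """Default synthetic dataset shared across tests (read-only)."""
    return simulate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_ds):
    return run_chromatin_pipeline(
        default_ds.peaksets, default_ds.cuts, default_ds.fib_meta, default_ds.maps
    )
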
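import numpy as np
import pytest

from retroscape import synthetic_data as sd


@pytest.fixture(scope="session")
def bundle():
    """One small simulated landscape shared across tests."""
    return sd.simulate_landscape(sd.SimConfig(seed=123))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    bundle.write_outputs(str(outdir))
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
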
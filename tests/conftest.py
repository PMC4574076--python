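import logging

import numpy as np
import pytest

from chipdecon.simulate import SimConfig, simulate_study

logging.getLogger("chipdecon").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """One mid-sized simulated study shared across tests (seed fixed)."""
    cfg = SimConfig(seed=1, chrom_lengths={"chrS1": 1_290_000}, n_peaks=200, n_tss=500)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    """The same study written out as plain-text files."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = bundle.write(outdir)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
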
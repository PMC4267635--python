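import numpy as np
import pytest
from hypothesis import settings

from cclamp.simulate import SyntheticConfig, make_fixture, simulate

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")

SMALL_CONFIG = dict(
    seed=7,
    n_chromosomes=2,
    chrom_length=400_000,
    n_genes=40,
    n_peaks_wt=120,
    n_peaks_mut=120,
    peak_length_range=(150, 250),
)


@pytest.fixture(scope="session")
def small_fixture():
    """A fast in-memory fixture exercising every stage."""
    return simulate(SyntheticConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """The same fixture written to disk in the standard formats."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = make_fixture(SyntheticConfig(**SMALL_CONFIG), outdir)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
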
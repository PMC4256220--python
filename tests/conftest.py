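import dataclasses

import pytest

from tssvar.binning import BinGrid
from tssvar.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return BinGrid()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_tss=80)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def null_config(small_config):
    """Same size as the default study but with every planted effect disabled."""
    return dataclasses.replace(
        small_config, seed=13, positional_modifiers=(), inner_coupling=0.0,
        outer_coupling=0.0, nucleosome_coupling=0.0, bbs_coupling=0.0,
        gerp_coupling=0.0,
    )


@pytest.fixture(scope="session")
def bundle_paths(tmp_path_factory, small_dataset):
    outdir = tmp_path_factory.mktemp("bundle")
    return small_dataset.write(outdir)
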
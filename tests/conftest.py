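import dataclasses

import numpy as np
import pytest

from ltrcurator import sim


@pytest.fixture(scope="session")
def library():
    """Two lineages per superfamily, fixed seed."""
    return sim.make_lineage_library(2, seed=7)


@pytest.fixture(scope="session")
def sim_config():
    return sim.SimConfig(n_per_class=(30, 25, 15, 20, 10), seed=42)


@pytest.fixture(scope="session")
def dataset(library, sim_config):
    """100-record five-class dataset shared across tests."""
    return sim.generate_dataset(sim_config, library)


@pytest.fixture(scope="session")
def short_library(library):
    """Miniature lineages (elements of a few hundred bp) for tests that
    one-hot encode whole sequences; motifs are reused from the session
    library so non-overlap still holds."""
    out = []
    for spec in library[:2] + library[2:4]:
        out.append(dataclasses.replace(
            spec, ltr_len_range=(25, 40), total_len_range=(320, 420)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
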
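import numpy as np
import pytest

from tcrspot.repertoire import CloneKey, RepertoireCounts
from tcrspot.simulate import (
    SimulationConfig,
    simulate_repertoire,
    simulate_tissue,
    toy_segment_references,
)


@pytest.fixture(scope="session")
def refs():
    return toy_segment_references()


@pytest.fixture(scope="session")
def small_config():
    """A small but complete slide: 12x12 spots, 10 clones, no errors."""
    return SimulationConfig(
        seed=7, n_rows=12, n_cols=12, tumor_radius_um=400.0,
        n_clones=10, total_umis=300,
    )


@pytest.fixture(scope="session")
def small_grid(small_config):
    return simulate_tissue(small_config)


@pytest.fixture(scope="session")
def small_repertoire(small_config):
    return simulate_repertoire(small_config)


def random_repertoire(rng, n_clones=None, max_count=20, label=""):
    """Random small clone-count table for oracle comparisons."""
    if n_clones is None:
        n_clones = int(rng.integers(1, 8))
    aas = "ACDEFGHIKLMNPQRSTVWY"
    entries = {}
    for i in rng.choice(20, size=min(n_clones, 20), replace=False):
        key = CloneKey("TRBV%d" % (i + 1), "TRBJ1", "CASS" + aas[i] + "F")
        entries[key] = int(rng.integers(1, max_count))
    return RepertoireCounts(entries, label=label)
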
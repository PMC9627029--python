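import numpy as np
import pytest

from gutsampler import FlockModel, generate_flock
from gutsampler.core_io import AsvTable, Pouch, SampleMetadata, Site


@pytest.fixture(scope="session")
def default_flock():
    """One default synthetic flock (9 birds x 10 AT locations, 2 negatives)."""
    return generate_flock(FlockModel(seed=11))


@pytest.fixture(scope="session")
def flock_true_parts(default_flock):
    """(raw table restricted to true samples, their metadata, taxonomy, tree,
    ground truth) for the default flock."""
    table, meta, taxonomy, tree, truth = default_flock
    true_meta = [m for m in meta if not m.is_negative]
    raw = table.select_samples([m.sample_id for m in true_meta])
    return raw, true_meta, taxonomy, tree, truth


@pytest.fixture
def tiny_table():
    counts = np.array([[5, 0, 2],
                       [3, 7, 2],
                       [0, 3, 6]], dtype=float)
    return AsvTable(counts, ["ASV_a", "ASV_b", "ASV_c"], ["S1", "S2", "S3"])


def make_meta(sample_id, bird, site, pouch=None, dna=10.0):
    return SampleMetadata(sample_id=sample_id, bird_id=bird, site=Site(site),
                          pouch=Pouch(pouch) if pouch else None, dna_conc=dna)
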
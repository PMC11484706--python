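import numpy as np
import pytest

from epiconform.crosslink import PairKey
from epiconform.io import CrosslinkSpeciesRecord, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_sequence():
    return SequenceRecord(id="toy", residues="MKTAYIAKQRQISFVK",
                          description="toy protein")


def make_species(protein="P1", species="crosslink", i=10, j=None,
                 condition="PU", replicate=1, ph=100.0):
    if species == "crosslink" and j is None:
        j = i + 20
    return CrosslinkSpeciesRecord(
        protein_id=protein, species_type=species, residue_i=i, residue_j=j,
        condition=condition, replicate=replicate, peak_height=ph)


@pytest.fixture
def simple_pair():
    return PairKey("P1", 10, 30)


@pytest.fixture
def simple_species_records(simple_pair):
    """One cross-link plus its two dead-ends: %XL = 50 by construction."""
    return [
        make_species(i=10, j=30, ph=50.0),
        make_species(species="deadend", i=10, ph=25.0),
        make_species(species="deadend", i=30, ph=25.0),
    ]
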
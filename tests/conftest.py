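import numpy as np
import pytest

from nemabar import SimConfig, make_dataset
from nemabar.core_seq import SpecimenRecord, TruthFlags


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic survey, reused by read-only tests."""
    return make_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def clean_subset(default_dataset):
    ds = default_dataset
    ids = ds.clean_ids()
    return ds.sequences.subset(ids), [
        r for r in ds.records if r.sequence_id in set(ids)]


@pytest.fixture
def make_records():
    """Factory for specimen records of ad-hoc sequence sets.

    Takes a mapping sequence id -> 'Genus species' (genus = first word);
    an optional second argument maps sequence id -> higher taxon.
    """

    def _make(species_of: dict, higher_taxon_of: dict | None = None):
        recs = []
        for i, (sid, sp) in enumerate(species_of.items()):
            genus = sp.split()[0]
            ht = (higher_taxon_of or {}).get(sid, "Enoplida")
            recs.append(SpecimenRecord(
                voucher=f"v{i}", species=sp, genus=genus,
                higher_taxon=ht, location="N", sequence_id=sid,
                truth=TruthFlags()))
        return recs

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
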
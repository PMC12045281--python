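import numpy as np
import pytest

from phyloprof.io_taxa import SpeciesRecord, SpeciesTable


def make_record(
    species_id,
    range_label,
    *,
    wgd=False,
    busco=99.0,
    cpd="Standard",
    focal=False,
):
    return SpeciesRecord(
        species_id=species_id,
        proteome_id=f"UP_{species_id}",
        range_label=range_label,
        wgd_member=wgd,
        busco_c=busco,
        cpd_class=cpd,
        is_focal=focal,
    )


@pytest.fixture
def toy_table():
    """11-species panel: focal + 2 genus + 2 family + 2 class + 2 phylum +
    2 kingdom; the WGD clade is the genus only."""
    records = [
        make_record("sc", "genus", wgd=True, focal=True),
        make_record("g1", "genus", wgd=True),
        make_record("g2", "genus", wgd=True),
        make_record("f1", "family"),
        make_record("f2", "family"),
        make_record("c1", "class"),
        make_record("c2", "class"),
        make_record("p1", "phylum"),
        make_record("p2", "phylum"),
        make_record("k1", "kingdom"),
        make_record("k2", "kingdom"),
    ]
    return SpeciesTable(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
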
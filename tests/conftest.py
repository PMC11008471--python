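import numpy as np
import pytest

from abclust import (
    AntibodyRecord,
    FixtureSpec,
    make_embeddings,
    make_paratopes,
    make_repertoire,
    make_structures,
)


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def repertoire(default_spec):
    """The documented planted-recovery conditions: 10 lineages x 8 members."""
    records, truth = make_repertoire(default_spec)
    return records, truth


@pytest.fixture(scope="session")
def aux(default_spec, repertoire):
    records, _ = repertoire
    return {
        "structures": make_structures(records, default_spec),
        "embeddings": make_embeddings(records, default_spec),
        "paratopes": make_paratopes(records, default_spec),
    }


def make_record(record_id, cdrh3, cdrl3="QQYNSYPLT", v_call="IGHV3-23*01",
                j_call="IGHJ4*02", **kwargs):
    """Minimal paired record: fixed frameworks around the given CDR3s."""
    h_fw1, h_fw2 = "EVQLVE", "WGQG"
    l_fw1, l_fw2 = "DIQMTQ", "FGQG"
    heavy = h_fw1 + cdrh3 + h_fw2
    light = l_fw1 + cdrl3 + l_fw2
    bounds = {
        "cdrh3": (len(h_fw1), len(h_fw1) + len(cdrh3)),
        "cdrl3": (len(l_fw1), len(l_fw1) + len(cdrl3)),
    }
    rec = AntibodyRecord(
        record_id=record_id,
        heavy_seq=heavy,
        light_seq=light,
        v_call=v_call,
        j_call=j_call,
        region_bounds=bounds,
        **kwargs,
    )
    rec.validate()
    return rec


@pytest.fixture
def toy_pair():
    return make_record("a", "ARDYW"), make_record("b", "ARDFW")
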
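import pytest

from pentastore import default_table, encode_store
from pentastore.fixtures import make_store_reads, random_file, DEFAULT_BARCODES
from pentastore.readsim import ReadSimConfig


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def poem_sized_store():
    """A 5,929-byte random file encoded with defaults (the canonical size)."""
    data = random_file(5929, seed=1)
    oligos, manifest = encode_store(data)
    return data, oligos, manifest


@pytest.fixture(scope="session")
def noisefree_reads():
    cfg = ReadSimConfig(
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        meth_miss_rate=0.0,
        meth_false_rate=0.0,
        barcode_left=DEFAULT_BARCODES[0],
        barcode_right=DEFAULT_BARCODES[1],
    )
    return make_store_reads(n_bytes=132, cfg=cfg, seed=3)


@pytest.fixture(scope="session")
def noisy_reads():
    """Default nanopore-like noise (methylation-confusion dominated)."""
    return make_store_reads(n_bytes=132, seed=3)
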
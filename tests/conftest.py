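import pytest

from pfas_bcbcr.chem_registry import (
    load_roster,
    packaged_roster_path,
    roster_index,
)


@pytest.fixture(scope="session")
def roster():
    return load_roster(packaged_roster_path())


@pytest.fixture(scope="session")
def roster_idx(roster):
    return roster_index(roster)


@pytest.fixture(scope="session")
def pfoa(roster_idx):
    return roster_idx["DTXSID8031865"]


@pytest.fixture(scope="session")
def pfos(roster_idx):
    return roster_idx["DTXSID3031864"]
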
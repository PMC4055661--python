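import logging

import pytest

from florisk.records import build_rate_pools
from florisk.synthetic import make_worked_fixture

logging.getLogger("florisk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def worked():
    """The hand-written five-taxon fixture: (records, cells)."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_records(worked):
    return worked[0]


@pytest.fixture(scope="session")
def worked_cells(worked):
    return worked[1]


@pytest.fixture(scope="session")
def worked_pools(worked_records):
    return build_rate_pools(worked_records)
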
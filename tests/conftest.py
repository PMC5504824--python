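from __future__ import annotations

import pytest

from isips import build_network, deduplicate, filter_records, read_mitab
from isips.synthgen import fig2_fixture, toy_mitab_fixture


@pytest.fixture(scope="session")
def fig2(tmp_path_factory):
    """The worked-example network: (path, complex definition, network)."""
    out = tmp_path_factory.mktemp("fig2")
    path, complex_def = fig2_fixture(out)
    records = read_mitab(path)
    tables = deduplicate(filter_records(records, complex_def.subunits))
    net = build_network(tables.nonredundant_pairs(), complex_def)
    return path, complex_def, net


@pytest.fixture(scope="session")
def toy_mitab(tmp_path_factory):
    """The hand-audited 12-row MITAB table: (path, complex definition)."""
    out = tmp_path_factory.mktemp("toy")
    return toy_mitab_fixture(out)
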
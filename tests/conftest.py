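"""Shared simulation fixtures.

Full-network control-case runs are expensive, so each (species, loop) result
is computed once per session and shared across tests.  Runs are desk-scaled
to 3 s (500 ms settling + 2.5 s analyzed) rather than the full 7 s protocol.
"""

import numpy as np
import pytest

from tcloop import build_network, simulate
from tcloop.network_builder import CubePoint

TEST_DURATION_MS = 3000.0
SETTLE_MS = 500.0

_cache = {}


def control_case_run(species: str, loop: str):
    key = (species, loop)
    if key not in _cache:
        net = build_network(species, loop, cube=CubePoint.control_case())
        _cache[key] = simulate(net, None, duration=TEST_DURATION_MS, dt=0.025)
    return _cache[key]


@pytest.fixture(scope="session")
def rodent_closed_run():
    return control_case_run("rodent", "closed")


@pytest.fixture(scope="session")
def rodent_open_run():
    return control_case_run("rodent", "open")


@pytest.fixture(scope="session")
def primate_closed_run():
    return control_case_run("primate", "closed")


@pytest.fixture(scope="session")
def primate_open_run():
    return control_case_run("primate", "open")


@pytest.fixture(scope="session")
def primate_hybrid_run():
    return control_case_run("primate", "hybrid")
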
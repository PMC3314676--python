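import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from hiernet.graph_core import Network


def out_star(n_leaves: int) -> Network:
    """One center with an outgoing edge to each leaf."""
    return Network.from_edges([("c", f"l{i}") for i in range(n_leaves)])


def directed_cycle(n: int) -> Network:
    return Network.from_edges([(f"v{i}", f"v{(i + 1) % n}") for i in range(n)])


def directed_chain(n: int) -> Network:
    return Network.from_edges([(f"v{i}", f"v{i + 1}") for i in range(n - 1)])


@pytest.fixture
def chain5() -> Network:
    return directed_chain(5)


@pytest.fixture
def star10() -> Network:
    return out_star(10)
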
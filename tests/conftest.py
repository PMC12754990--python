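import numpy as np
import pytest

from arealrisk import AreaGraph, make_lattice


@pytest.fixture
def path3() -> AreaGraph:
    """Path graph a-b-c."""
    return AreaGraph(
        area_ids=["a", "b", "c"],
        neighbors={"a": {"b"}, "b": {"a", "c"}, "c": {"b"}},
    )


@pytest.fixture
def lattice44() -> AreaGraph:
    return make_lattice(4, 4, "queen")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
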
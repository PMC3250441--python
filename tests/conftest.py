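import numpy as np
import pytest

from bicontrol import BipartiteNetwork


@pytest.fixture
def overlap_toy() -> BipartiteNetwork:
    """Two controllers with 5 targets each sharing exactly 2 (the standard
    overlap illustration: overlap(x1 -> x2) = 2/5)."""
    links = [("x1", f"y{i}") for i in (1, 2, 3, 4, 5)]
    links += [("x2", f"y{i}") for i in (1, 2, 6, 7, 8)]
    return BipartiteNetwork(
        ["x1", "x2"], [f"y{i}" for i in range(1, 9)], links, name="overlap_toy"
    )


@pytest.fixture
def complete_3x4() -> BipartiteNetwork:
    links = [(f"c{i}", f"t{j}") for i in range(3) for j in range(4)]
    return BipartiteNetwork(
        [f"c{i}" for i in range(3)], [f"t{j}" for j in range(4)], links
    )


def random_network(M: int, N: int, D: float, seed: int) -> BipartiteNetwork:
    """Local ER generator for oracle tests (independent of bicontrol.synth)."""
    rng = np.random.default_rng(seed)
    links = [
        (f"c{i}", f"t{j}")
        for i in range(M)
        for j in range(N)
        if rng.random() < D
    ]
    return BipartiteNetwork(
        [f"c{i}" for i in range(M)], [f"t{j}" for j in range(N)], links
    )
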
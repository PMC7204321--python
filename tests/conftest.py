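import random

import pytest

from netpharm.tables_io import InteractionNetwork, load_table1, load_table2, load_table3


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


def random_network(rng: random.Random, n: int, p: float) -> InteractionNetwork:
    """Erdos-Renyi G(n, p) with unit confidences, nodes n00..n{n-1}."""
    net = InteractionNetwork()
    names = [f"n{i:02d}" for i in range(n)]
    for name in names:
        net.add_node(name)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j], 1.0)
    return net
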
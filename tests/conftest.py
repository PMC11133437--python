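import pytest

from topoqspr import MolecularGraph, drug_graph, paper_tables, random_molecular_graph


def cycle(n: int) -> MolecularGraph:
    return MolecularGraph.from_edges(
        [(f"v{i}", f"v{(i + 1) % n}") for i in range(n)], name=f"C{n}"
    )


def star(k: int) -> MolecularGraph:
    return MolecularGraph.from_edges(
        [("c", f"leaf{i}") for i in range(k)], name=f"K1,{k}"
    )


def path(n: int) -> MolecularGraph:
    return MolecularGraph.from_edges(
        [(f"v{i}", f"v{i + 1}") for i in range(n - 1)], name=f"P{n}"
    )


@pytest.fixture(scope="session")
def sulfadiazine():
    return drug_graph("Sulfadiazine")


@pytest.fixture(scope="session")
def tables():
    return paper_tables()


@pytest.fixture(scope="session")
def random_graphs():
    """100 seeded random molecular-like graphs (n <= 30, max degree <= 4)."""
    graphs = []
    for seed in range(100):
        n = 2 + seed % 29
        graphs.append(random_molecular_graph(seed, n, max_degree=2 + seed % 3))
    return graphs
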
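import io
import textwrap

import numpy as np
import pytest

from phenonet.ontology import OntologyDAG
from phenonet.network import FunctionalNetwork


DIAMOND_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: test-phenotypes

    [Term]
    id: MP:A
    name: root phenotype

    [Term]
    id: MP:B
    name: left branch
    is_a: MP:A

    [Term]
    id: MP:C
    name: right branch
    is_a: MP:A

    [Term]
    id: MP:D
    name: leaf
    is_a: MP:B
    is_a: MP:C

    [Term]
    id: MP:OBS
    name: retired term
    is_obsolete: true
    """
)


@pytest.fixture
def diamond_obo_stream():
    return io.StringIO(DIAMOND_OBO)


@pytest.fixture
def diamond_dag():
    return OntologyDAG(
        terms=frozenset({"MP:A", "MP:B", "MP:C", "MP:D"}),
        parents={
            "MP:A": frozenset(),
            "MP:B": frozenset({"MP:A"}),
            "MP:C": frozenset({"MP:A"}),
            "MP:D": frozenset({"MP:B", "MP:C"}),
        },
    )


@pytest.fixture
def tiny_network():
    """Five genes; g absent pairs default to 0."""
    return FunctionalNetwork.from_edges(
        [
            ("p1", "p2", 0.5),
            ("g", "p1", 0.2),
            ("g", "p2", 0.3),
            ("p2", "q", 0.9),
        ],
        genes=["p1", "p2", "g", "q", "isolated"],
    )


def random_network(rng: np.random.Generator, n_genes: int, density: float = 0.2):
    """Random symmetric network used by oracle tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < density:
                edges.append((genes[i], genes[j], float(rng.random())))
    return FunctionalNetwork.from_edges(edges, genes=genes), genes


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    """Random DAG: each non-root term picks 1-2 parents among earlier terms."""
    terms = [f"T{i}" for i in range(n_terms)]
    parents = {terms[0]: frozenset()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i + 1)))
        ps = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = frozenset(terms[int(p)] for p in ps)
    return OntologyDAG(terms=frozenset(terms), parents=parents)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
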
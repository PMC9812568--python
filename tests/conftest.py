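import networkx as nx
import numpy as np
import pytest

from kgner import KnowledgeGraph, Sentence, SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def tiny_kg() -> KnowledgeGraph:
    """Hand-built graph: a disease, its alias, and a protein cause."""
    g = nx.Graph()
    g.add_edge(0, 1, relations={"same_as"})
    g.add_edge(0, 2, relations={"caused_by"})
    return KnowledgeGraph(
        surface_forms=["Alzheimer's disease", "senile dementia", "Mfn2"],
        categories=["Disease", "Disease", "Target"],
        graph=g,
    )


@pytest.fixture
def sample_sentence() -> Sentence:
    return Sentence(
        tokens=["Alzheimer's", "disease", "is", "a", "neurodegenerative", "disorder"],
        labels=["B-Disease", "I-Disease", "O", "O", "O", "O"],
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle (fast to train on)."""
    return generate_bundle(
        SynthConfig(n_entities=8, n_train=60, n_dev=20, n_test=40, vocab_size=80, seed=5)
    )


def random_adjacency(rng: np.random.Generator, m: int, p: float = 0.4) -> np.ndarray:
    """Random symmetric 0/1 adjacency with unit diagonal."""
    A = (rng.random((m, m)) < p).astype(np.int8)
    A = np.triu(A, 1)
    A = A + A.T + np.eye(m, dtype=np.int8)
    return A
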
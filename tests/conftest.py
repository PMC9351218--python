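import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def path_abc():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def star5():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions: 2000 proteins, seed 1."""
    from essprot.synthetic_data import SyntheticSpec, generate_dataset

    return generate_dataset(SyntheticSpec(n_proteins=2000, seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset for cheap structural tests."""
    from essprot.synthetic_data import SyntheticSpec, generate_dataset

    return generate_dataset(SyntheticSpec(n_proteins=300, seed=7))


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    """Aligned feature bundle for the small dataset (localization top-256)."""
    from essprot import graph_embedding as ge
    from essprot import localization_features as lf
    from essprot import model_core as mc

    ds = small_dataset
    embedding = ge.embed_network(ds.graph, ge.WalkParams(seed=7), dim=64)
    ranking = lf.rank_localization_terms(ds.localization, ds.graph)
    mat = lf.build_localization_matrix(ds.localization, ranking, ds.proteins, K=256)
    return mc.build_feature_bundle(ds.proteins, ds.tensors, mat, embedding, ds.labels)
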
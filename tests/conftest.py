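import numpy as np
import pytest

from oncolink.graph import KnowledgeGraph, LinkDataset, NodeFeatureTable


@pytest.fixture
def toy_graph() -> KnowledgeGraph:
    """3 genes, 2 relations, 3 edges: the smallest interesting multigraph."""
    return KnowledgeGraph(
        nodes=("A", "B", "C"),
        edges=[("A", "act", "B"), ("B", "inh", "C"), ("A", "act", "C")],
        relations=("act", "inh"),
    )


@pytest.fixture
def toy_features(toy_graph) -> NodeFeatureTable:
    rng = np.random.default_rng(0)
    return NodeFeatureTable(
        genes=toy_graph.nodes,
        X=rng.normal(size=(3, 4)),
        block_dims=(2, 1, 1),
    )


@pytest.fixture
def toy_links() -> LinkDataset:
    return LinkDataset(
        [("A", "B", 1), ("B", "C", 1), ("A", "C", 0), ("C", "A", 0), ("C", "B", 1)]
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """The default planted-rule benchmark: graph, features, labeled links,
    and a train/validation/test split (3/1/1 folds)."""
    from oncolink.evaluation import crossval
    from oncolink.synthetic import SimConfig, gen_features, gen_graph, gen_links

    cfg = SimConfig(seed=1)
    graph = gen_graph(cfg)
    feats = gen_features(graph, cfg)
    links = gen_links(graph, cfg)
    cv = crossval(links, k=5, seed=1)
    train_idx, cross_idx, test_idx = cv.rotations[0]
    return {
        "cfg": cfg,
        "graph": graph,
        "features": feats,
        "links": links,
        "train": links.subset(train_idx),
        "val": links.subset(cross_idx),
        "test": links.subset(test_idx),
    }
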
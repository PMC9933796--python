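"""Shared fixtures: one moderately sized simulated collection and its derived
graph, node statistics and Walklets embedding, reused across test modules."""

import numpy as np
import pytest

import vaxstance.evaluation as ev
import vaxstance.node_embedding as ne
import vaxstance.reply_graph as rg
import vaxstance.synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    return sd.SimConfig(
        n_users=800,
        n_tweets=2000,
        n_replies=6000,
        text_dim=32,
        homophily=0.9,
        text_separation=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sd.SimDataset:
    return sd.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pruned_graph(small_dataset) -> rg.ReplyGraph:
    return rg.prune_min_degree(rg.build_reply_graph(small_dataset.replies))


@pytest.fixture(scope="session")
def small_node_stats(small_dataset, small_pruned_graph):
    return rg.compute_node_stats(small_pruned_graph, small_dataset.users)


@pytest.fixture(scope="session")
def small_embedding(small_pruned_graph) -> ne.EmbeddingMatrix:
    return ne.walklets_embed(
        small_pruned_graph.undirected,
        ne.WalkConfig(walks_per_node=6, walk_length=30, seed=0),
        ne.EmbedConfig(total_dim=64, scales=4, epochs=2, seed=0),
    )


@pytest.fixture(scope="session")
def skeptic_view(small_dataset, small_embedding, small_node_stats) -> ev.LabeledView:
    return ev.prepare_view(
        small_dataset,
        ev.SKEPTIC_TASK,
        embedding=small_embedding,
        node_stats=small_node_stats,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
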
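"""Biased random walks and skip-gram embedding of similarity networks."""

from __future__ import annotations

import numpy as np
import pytest

from chemsimnet import (
    WalkConfig,
    embed_space,
    embedding_similarity,
    generate_walks,
    train_embedding,
)
from chemsimnet.embedding import TrainConfig, load_model, save_model
from chemsimnet.errors import DataError
from chemsimnet.simnet import SimilarityNetwork


def path_network(w_ab: float, w_bc: float) -> SimilarityNetwork:
    return SimilarityNetwork(
        nodes=["a", "b", "c"],
        edges=[(0, 1, w_ab, 0.001), (1, 2, w_bc, 0.001)],
        alpha=0.05,
    )


def transition_freq_from_b(network, seed=0):
    walks = generate_walks(
        network, WalkConfig(num_walks_per_node=100, walk_length=350, seed=seed)
    )
    to_a = to_c = 0
    for walk in walks:
        for prev, nxt in zip(walk, walk[1:]):
            if prev == "b":
                if nxt == "a":
                    to_a += 1
                else:
                    to_c += 1
    return to_a, to_c


class TestWalks:
    def test_first_order_frequencies_match_edge_weights(self):
        # p=q=1: next-step proportions from b follow 1:2 edge weights
        to_a, to_c = transition_freq_from_b(path_network(1.0, 2.0), seed=4)
        total = to_a + to_c
        assert total > 1e4
        assert to_c / total == pytest.approx(2 / 3, abs=0.02)

    def test_doubling_a_weight_increases_traversal(self):
        base_a, base_c = transition_freq_from_b(path_network(1.0, 1.0), seed=4)
        up_a, up_c = transition_freq_from_b(path_network(1.0, 2.0), seed=4)
        assert up_c / (up_a + up_c) > base_c / (base_a + base_c)

    def test_components_do_not_mix(self):
        edges = []
        for base in (0, 3):
            for i in range(3):
                for j in range(i + 1, 3):
                    edges.append((base + i, base + j, 1.0, 0.001))
        net = SimilarityNetwork(
            nodes=[f"t{i}" for i in range(6)], edges=edges, alpha=0.05
        )
        first = {"t0", "t1", "t2"}
        for walk in generate_walks(net, WalkConfig(seed=1)):
            visited = set(walk)
            assert visited <= first or visited.isdisjoint(first)

    def test_walk_count_bookkeeping(self, two_cliques):
        config = WalkConfig(num_walks_per_node=7, walk_length=10, seed=2)
        walks = generate_walks(two_cliques, config)
        assert len(walks) == 7 * 12
        assert all(len(w) == 10 for w in walks)

    def test_isolated_nodes_never_visited(self):
        net = SimilarityNetwork(
            nodes=["a", "b", "lonely"], edges=[(0, 1, 1.0, 0.001)], alpha=0.05
        )
        for walk in generate_walks(net, WalkConfig(seed=3)):
            assert "lonely" not in walk

    def test_edgeless_network_rejected(self):
        net = SimilarityNetwork(nodes=["a", "b"], edges=[], alpha=0.05)
        with pytest.raises(DataError, match="nothing to embed"):
            generate_walks(net, WalkConfig())

    def test_seed_reproducibility(self, two_cliques):
        a = generate_walks(two_cliques, WalkConfig(seed=11))
        b = generate_walks(two_cliques, WalkConfig(seed=11))
        assert a == b


class TestTraining:
    def test_cliques_separate(self, two_cliques):
        walks = generate_walks(two_cliques, WalkConfig(seed=5))
        vectors = train_embedding(walks, dims=8, seed=6)
        ids = sorted(vectors)
        arr = np.vstack([vectors[i] for i in ids])
        unit = arr / np.linalg.norm(arr, axis=1, keepdims=True)
        sim = unit @ unit.T
        within = (sim[:6, :6].sum() - 6) / 30
        between = sim[:6, 6:].mean()
        assert within > between

    def test_vector_shapes_and_coverage(self, two_cliques):
        walks = generate_walks(two_cliques, WalkConfig(seed=5))
        vectors = train_embedding(walks, dims=8, seed=6)
        assert set(vectors) == set(two_cliques.nodes)
        assert all(v.shape == (8,) and np.isfinite(v).all() for v in vectors.values())

    def test_deterministic_given_seed(self, two_cliques):
        walks = generate_walks(two_cliques, WalkConfig(seed=5))
        a = train_embedding(walks, dims=8, seed=7)
        b = train_embedding(walks, dims=8, seed=7)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_dims_exceeding_vocabulary_warns(self, two_cliques):
        walks = generate_walks(two_cliques, WalkConfig(seed=5))
        with pytest.warns(UserWarning, match="vocabulary"):
            train_embedding(walks, dims=50, seed=1, config=TrainConfig(epochs=1))


class TestEmbedSpace:
    @pytest.mark.parametrize(
        "label, dims",
        [("quantum", 9), ("quantum_elements", 9), ("fingerprint_bits", 36),
         ("descriptors", 36)],
    )
    def test_dims_rule(self, two_cliques, label, dims):
        model = embed_space(two_cliques, label, seed=1)
        assert model.dims == dims

    def test_isolated_nodes_reported_not_embedded(self):
        net = SimilarityNetwork(
            nodes=["a", "b", "lonely"], edges=[(0, 1, 0.9, 0.001)], alpha=0.05
        )
        model = embed_space(net, "fingerprint_bits", seed=1)
        assert model.isolated_nodes == ["lonely"]
        assert "lonely" not in model.vectors
        with pytest.raises(KeyError, match="lonely"):
            model.vector("lonely")


class TestSimilarityAndSerialization:
    def test_similarity_properties(self, two_cliques):
        model = embed_space(two_cliques, "quantum", seed=2)
        a, b = two_cliques.nodes[0], two_cliques.nodes[1]
        assert embedding_similarity(model, a, a) == pytest.approx(1.0)
        assert embedding_similarity(model, a, b) == pytest.approx(
            embedding_similarity(model, b, a)
        )

    def test_orthogonal_hand_vectors(self):
        from conftest import make_model

        model = make_model({"x": [1.0, 0.0, 0.0], "y": [0.0, 1.0, 0.0]})
        assert embedding_similarity(model, "x", "y") == 0.0

    def test_roundtrip(self, tmp_path, two_cliques):
        model = embed_space(two_cliques, "quantum", seed=3)
        save_model(model, tmp_path / "quantum")
        loaded = load_model(tmp_path / "quantum")
        assert loaded.dims == model.dims
        assert set(loaded.vectors) == set(model.vectors)
        for key in model.vectors:
            assert np.allclose(loaded.vectors[key], model.vectors[key], atol=1e-12)
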
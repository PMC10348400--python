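"""Shared fixtures: planted datasets run through the pipeline once per session."""

from __future__ import annotations

import numpy as np
import pytest

from chemsimnet import (
    EmbeddingModel,
    TrainConfig,
    WalkConfig,
    build_network,
    compute_similarity,
    embed_space,
    generate_planted_blocks,
)
from chemsimnet.simnet import SimilarityNetwork
from chemsimnet.spaces import build_space


def make_model(vectors: dict[str, np.ndarray], space_label: str = "fingerprint_bits") -> EmbeddingModel:
    """Hand-built embedding model for query/cluster tests."""
    dims = len(next(iter(vectors.values())))
    return EmbeddingModel(
        space_label=space_label,
        dims=dims,
        vectors={k: np.asarray(v, dtype=float) for k, v in vectors.items()},
    )


@pytest.fixture(scope="session")
def planted60():
    """The 60-molecule / 3-community / 2% noise study dataset."""
    return generate_planted_blocks(
        n_molecules=60, n_communities=3, within_noise=0.02, seed=101
    )


@pytest.fixture(scope="session")
def spaces60(planted60):
    return {label: build_space(block) for label, block in planted60.blocks.items()}


@pytest.fixture(scope="session")
def bits_model60(spaces60):
    """fingerprint_bits space taken through simnet + embedding."""
    space = spaces60["fingerprint_bits"]
    result = compute_similarity(space.mol_ids, space.reduced, n_permutations=1000, seed=102)
    network = build_network(result, alpha=0.05)
    return embed_space(network, "fingerprint_bits", WalkConfig(seed=103), TrainConfig(), seed=103)


@pytest.fixture(scope="session")
def planted200():
    """200-molecule dataset with planted target sharing 0.6 within / 0.1 between."""
    return generate_planted_blocks(
        n_molecules=200, n_communities=4, within_noise=0.02,
        p_target_within=0.6, p_target_between=0.1, seed=201,
    )


@pytest.fixture(scope="session")
def bits_model200(planted200):
    """fingerprint_bits embedding of the 200-molecule dataset (alpha=0.01 network)."""
    space = build_space(planted200.blocks["fingerprint_bits"])
    result = compute_similarity(space.mol_ids, space.reduced, n_permutations=1000, seed=202)
    network = build_network(result, alpha=0.01)
    return embed_space(network, "fingerprint_bits", WalkConfig(seed=203), TrainConfig(), seed=203)


@pytest.fixture()
def two_cliques() -> SimilarityNetwork:
    """Two 6-node cliques joined by one weak bridge edge."""
    edges = []
    for base in (0, 6):
        for i in range(6):
            for j in range(i + 1, 6):
                edges.append((base + i, base + j, 1.0, 0.001))
    edges.append((0, 6, 0.1, 0.001))
    return SimilarityNetwork(
        nodes=[f"n{i:02d}" for i in range(12)], edges=edges, alpha=0.05
    )
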
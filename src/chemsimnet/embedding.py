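"""Node embeddings of similarity networks.

Each similarity network is embedded with the node2vec scheme: biased
second-order random walks explore the network, and a skip-gram model with
negative sampling (SGNS) is trained on the walk corpus so that molecules
occupying similar network neighborhoods obtain nearby vectors. Molecule
signatures use 36 dimensions for fingerprint and descriptor spaces and 9
dimensions for the (smaller) quantum-property spaces; similarity between
embedded molecules is the cosine of their vectors.

The walk bias follows the second-order scheme: stepping from ``v`` (having
arrived from ``t``), the unnormalized probability of moving to ``x`` is the
edge weight w(v,x) times 1/p if x = t (return), 1 if x is adjacent to t,
and 1/q otherwise. With p = q = 1 this reduces to a first-order weighted
random walk. Edge weights must be non-negative for walk probabilities, so
negative cosine weights are clipped to a small epsilon (1e-6); the clip is
recorded in the model metadata.

The SGNS trainer is a deterministic single-threaded mini-batched SGD in
numpy: unigram^0.75 negative sampling, linearly decaying learning rate,
input vectors taken as the embedding. Isolated nodes never appear in walks
and are not embedded; they are listed separately in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError, ValidationError
from .simnet import SimilarityNetwork

__all__ = [
    "WalkConfig",
    "TrainConfig",
    "EmbeddingModel",
    "generate_walks",
    "train_embedding",
    "embed_space",
    "embedding_similarity",
    "dims_for_space",
    "save_model",
    "load_model",
]

WEIGHT_EPSILON = 1e-6


@dataclass(frozen=True)
class WalkConfig:
    """Biased random-walk hyperparameters (node2vec p/q scheme)."""

    p: float = 1.0
    q: float = 1.0
    num_walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValidationError("p and q must be positive")
        if self.walk_length < 2:
            raise ValidationError("walk_length must be >= 2")
        if self.num_walks_per_node < 1:
            raise ValidationError("num_walks_per_node must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Skip-gram training hyperparameters."""

    window: int = 10
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    batch_size: int = 4096


@dataclass
class EmbeddingModel:
    """Per-molecule signature vectors for one chemical space."""

    space_label: str
    dims: int
    vectors: dict[str, np.ndarray]
    isolated_nodes: list[str] = field(default_factory=list)
    walk_config: WalkConfig = field(default_factory=WalkConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def embedded_nodes(self) -> set[str]:
        return set(self.vectors)

    def vector(self, mol_id: str) -> np.ndarray:
        if mol_id not in self.vectors:
            raise KeyError(f"no embedding in this space for {mol_id!r}")
        return self.vectors[mol_id]


def _adjacency(network: SimilarityNetwork):
    """Neighbor index lists and clipped non-negative weights per node."""
    neighbors: dict[int, list[int]] = {}
    weights: dict[int, list[float]] = {}
    for i, j, sim, _pval in network.edges:
        w = max(float(sim), WEIGHT_EPSILON)
        neighbors.setdefault(i, []).append(j)
        weights.setdefault(i, []).append(w)
        neighbors.setdefault(j, []).append(i)
        weights.setdefault(j, []).append(w)
    adj = {}
    for node, nbrs in neighbors.items():
        order = np.argsort(nbrs)
        adj[node] = (
            np.asarray(nbrs, dtype=np.int64)[order],
            np.asarray(weights[node], dtype=float)[order],
        )
    return adj


def generate_walks(
    network: SimilarityNetwork, config: WalkConfig | None = None
) -> list[list[str]]:
    """Second-order biased random walks over a similarity network.

    ``num_walks_per_node`` walks start from every non-isolated node; each
    walk has length ``walk_length`` (shorter only if the walker is trapped).
    Reproducible given the config seed.
    """
    config = config or WalkConfig()
    if not network.edges:
        raise DataError("nothing to embed: network has no edges")
    adj = _adjacency(network)
    start_nodes = sorted(adj)
    rng = np.random.default_rng(config.seed)
    inv_p, inv_q = 1.0 / config.p, 1.0 / config.q
    walks: list[list[str]] = []
    for _ in range(config.num_walks_per_node):
        for start in start_nodes:
            walk = [start]
            while len(walk) < config.walk_length:
                current = walk[-1]
                if current not in adj:
                    break  # trapped (cannot happen on undirected graphs)
                nbrs, wts = adj[current]
                if len(walk) == 1 or (inv_p == 1.0 and inv_q == 1.0):
                    probs = wts
                else:
                    prev = walk[-2]
                    prev_nbrs = adj[prev][0]
                    bias = np.where(
                        nbrs == prev,
                        inv_p,
                        np.where(np.isin(nbrs, prev_nbrs), 1.0, inv_q),
                    )
                    probs = wts * bias
                cumulative = np.cumsum(probs)
                draw = rng.random() * cumulative[-1]
                walk.append(int(nbrs[np.searchsorted(cumulative, draw, side="right")]))
            walks.append([network.nodes[v] for v in walk])
    return walks


def _skipgram_pairs(indexed_walks: list[np.ndarray], window: int) -> np.ndarray:
    pairs = []
    for walk in indexed_walks:
        length = len(walk)
        for offset in range(1, window + 1):
            if offset >= length:
                break
            left = walk[:-offset]
            right = walk[offset:]
            pairs.append(np.column_stack([left, right]))
            pairs.append(np.column_stack([right, left]))
    if not pairs:
        raise DataError("walks too short to form any training pair")
    return np.concatenate(pairs, axis=0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _scatter_rows(idx: np.ndarray, rows: np.ndarray, n: int, dims: int) -> np.ndarray:
    """Sum ``rows`` into an (n, dims) array at row indices ``idx``.

    bincount-based scatter-add; considerably faster than np.add.at for the
    repeated indices that dominate small-vocabulary batches.
    """
    flat = (idx[:, None] * dims + np.arange(dims)).ravel()
    return np.bincount(flat, weights=rows.ravel(), minlength=n * dims).reshape(n, dims)


def train_embedding(
    walks: Sequence[Sequence[str]],
    dims: int,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train skip-gram with negative sampling on a walk corpus.

    Deterministic under a fixed seed (single-threaded numpy SGD). Returns a
    mol_id -> vector map; every node appearing in the walks gets a vector.
    """
    config = config or TrainConfig()
    if dims < 2:
        raise ValidationError("dims must be >= 2")
    if not walks:
        raise DataError("empty walk corpus")
    vocab = sorted({node for walk in walks for node in walk})
    if dims > len(vocab):
        import warnings

        warnings.warn(f"dims={dims} exceeds vocabulary size {len(vocab)}; proceeding")
    index = {node: i for i, node in enumerate(vocab)}
    indexed = [np.asarray([index[n] for n in walk], dtype=np.int64) for walk in walks]
    pairs = _skipgram_pairs(indexed, config.window)

    counts = np.bincount(pairs[:, 0], minlength=len(vocab)).astype(float)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    vocab_size = len(vocab)
    w_in = (rng.random((vocab_size, dims)) - 0.5) / dims
    w_out = np.zeros((vocab_size, dims))

    n_pairs = len(pairs)
    # accumulated updates per node scale with batch/vocab; cap the batch so
    # the summed step stays in the stable regime on small vocabularies
    batch_size = int(min(config.batch_size, max(64, 16 * vocab_size)))
    batches_per_epoch = int(np.ceil(n_pairs / batch_size))
    total_batches = batches_per_epoch * config.epochs
    batch_counter = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_pairs)
        for b in range(batches_per_epoch):
            batch = pairs[order[b * batch_size : (b + 1) * batch_size]]
            centers, contexts = batch[:, 0], batch[:, 1]
            lr = max(
                config.min_learning_rate,
                config.learning_rate * (1.0 - batch_counter / total_batches),
            )
            batch_counter += 1

            negatives = np.searchsorted(
                noise_cdf, rng.random((len(batch), config.negative))
            )
            v_c = w_in[centers]
            # positive examples: label 1
            u_pos = w_out[contexts]
            g_pos = _sigmoid(np.einsum("ij,ij->i", v_c, u_pos)) - 1.0
            # negative examples: label 0
            u_neg = w_out[negatives]
            g_neg = _sigmoid(np.einsum("ij,ikj->ik", v_c, u_neg))

            clip = lambda g: np.clip(g, -5.0, 5.0)  # noqa: E731
            grad_center = g_pos[:, None] * u_pos + np.einsum("ik,ikj->ij", g_neg, u_neg)
            w_in += _scatter_rows(centers, -lr * clip(grad_center), vocab_size, dims)
            out_idx = np.concatenate([contexts, negatives.ravel()])
            out_grad = np.concatenate(
                [
                    -lr * clip(g_pos[:, None] * v_c),
                    (-lr * clip(g_neg[:, :, None] * v_c[:, None, :])).reshape(-1, dims),
                ]
            )
            w_out += _scatter_rows(out_idx, out_grad, vocab_size, dims)
    return {node: w_in[index[node]].copy() for node in vocab}


def dims_for_space(space_label: str) -> int:
    """36 dimensions for fingerprint/descriptor spaces, 9 for quantum."""
    return 9 if space_label in ("quantum", "quantum_elements") else 36


def embed_space(
    network: SimilarityNetwork,
    space_label: str,
    walk_config: WalkConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Walks + skip-gram with module defaults; dims chosen by space kind."""
    walk_config = walk_config or WalkConfig(seed=seed)
    train_config = train_config or TrainConfig()
    dims = dims_for_space(space_label)
    walks = generate_walks(network, walk_config)
    vectors = train_embedding(walks, dims, train_config, seed=seed)
    return EmbeddingModel(
        space_label=space_label,
        dims=dims,
        vectors=vectors,
        isolated_nodes=network.isolated_nodes,
        walk_config=walk_config,
        train_config=train_config,
    )


def embedding_similarity(model: EmbeddingModel, id_a: str, id_b: str) -> float:
    """Cosine similarity of two embedded molecules."""
    va, vb = model.vector(id_a), model.vector(id_b)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(np.clip(va @ vb / denom, -1.0, 1.0))


def save_model(model: EmbeddingModel, directory: str | Path) -> Path:
    """Write vectors as CSV (mol_id + dims columns) plus JSON metadata."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = sorted(model.vectors)
    frame = pd.DataFrame(
        np.vstack([model.vectors[m] for m in ids]) if ids else np.zeros((0, model.dims)),
        index=pd.Index(ids, name="mol_id"),
        columns=[f"d{j + 1}" for j in range(model.dims)],
    )
    frame.to_csv(directory / "vectors.csv")
    meta = {
        "space_label": model.space_label,
        "dims": model.dims,
        "isolated_nodes": model.isolated_nodes,
        "walk_config": model.walk_config.__dict__,
        "train_config": model.train_config.__dict__,
        "weight_epsilon": WEIGHT_EPSILON,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_model(directory: str | Path) -> EmbeddingModel:
    import pandas as pd

    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    frame = pd.read_csv(directory / "vectors.csv", index_col="mol_id")
    vectors = {str(m): frame.loc[m].to_numpy(dtype=float) for m in frame.index}
    return EmbeddingModel(
        space_label=meta["space_label"],
        dims=int(meta["dims"]),
        vectors=vectors,
        isolated_nodes=list(meta.get("isolated_nodes", [])),
        walk_config=WalkConfig(**meta["walk_config"]),
        train_config=TrainConfig(**meta["train_config"]),
    )
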
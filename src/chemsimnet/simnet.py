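"""Pairwise similarity, permutation significance and similarity networks.

Cosine similarity is computed on the reduced chemical-space matrices. Its
significance is assessed by a within-row shuffling permutation test: each
permutation independently shuffles every molecule's reduced feature values
(destroying cross-molecule feature alignment while preserving each row's
value multiset), recomputes the full cosine matrix, and counts how often
the null similarity reaches the observed one. The one-sided, add-one
corrected p-value is

    p(i,j) = (1 + #{null >= observed}) / (1 + n_permutations)

so the minimum attainable p is 1/(n_permutations+1). Pairs with p below
alpha (0.05 or 0.01) become edges of an undirected similarity network
weighted by cosine similarity.

The null loop streams permutations — it never materializes more than one
shuffled matrix at a time — and accumulates exact pair-level exceedance
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import DataError, ValidationError

__all__ = [
    "SimilarityResult",
    "SimilarityNetwork",
    "cosine_matrix",
    "tanimoto",
    "euclidean_complement",
    "permutation_pvalues",
    "compute_similarity",
    "build_network",
]


@dataclass
class SimilarityResult:
    """Observed similarities and their permutation p-values."""

    mol_ids: list[str]
    sim: np.ndarray
    pvals: np.ndarray
    n_permutations: int
    seed: int
    zero_norm_rows: list[int] = field(default_factory=list)


@dataclass
class SimilarityNetwork:
    """Molecules as nodes; significant pairs as weighted undirected edges."""

    nodes: list[str]
    edges: list[tuple[int, int, float, float]]  # (i, j, similarity, pval), i < j
    alpha: float

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph(alpha=self.alpha)
        graph.add_nodes_from(self.nodes)
        for i, j, sim, pval in self.edges:
            graph.add_edge(self.nodes[i], self.nodes[j], weight=sim, pval=pval)
        return graph

    @property
    def isolated_nodes(self) -> list[str]:
        connected = {i for e in self.edges for i in e[:2]}
        return [m for idx, m in enumerate(self.nodes) if idx not in connected]

    def write_edgelist(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("mol_id_a\tmol_id_b\tsimilarity\tpval\n")
            for i, j, sim, pval in self.edges:
                fh.write(f"{self.nodes[i]}\t{self.nodes[j]}\t{sim:.6g}\t{pval:.6g}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def cosine_matrix(reduced: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Pairwise cosine similarity matrix; zero-norm rows flagged and set to 0."""
    reduced = np.atleast_2d(np.asarray(reduced, dtype=float))
    if reduced.size == 0 or reduced.shape[0] < 2:
        raise DataError("cosine matrix needs at least 2 rows")
    norms = np.linalg.norm(reduced, axis=1)
    zero_rows = np.flatnonzero(norms == 0).tolist()
    safe = norms.copy()
    safe[safe == 0] = 1.0
    unit = reduced / safe[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    if zero_rows:
        sim[zero_rows, :] = 0.0
        sim[:, zero_rows] = 0.0
    return sim, zero_rows


def tanimoto(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """Tanimoto coefficient: bits set in both / bits set in either."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("bit vectors must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("tanimoto of two empty bit sets defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def euclidean_complement(a: np.ndarray, b: np.ndarray, scale: float) -> float:
    """Similarity as the complement of the normalized Euclidean distance.

    ``scale`` is the maximum pairwise distance over the dataset, so the
    maximally distant pair scores 0 and identical vectors score 1.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    return float(np.clip(1.0 - np.linalg.norm(a - b) / scale, 0.0, 1.0))


def permutation_pvalues(
    reduced: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Within-row shuffling permutation p-values for the cosine matrix.

    Every permutation draws a fresh independent shuffle of each row's
    values, recomputes the cosine matrix, and counts exceedances of the
    observed similarities. Reproducible given ``seed``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    reduced = np.asarray(reduced, dtype=float)
    observed, _ = cosine_matrix(reduced)
    rng = np.random.default_rng(seed)
    n = reduced.shape[0]
    exceed = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_permutations):
        shuffled = rng.permuted(reduced, axis=1)
        null_sim, _ = cosine_matrix(shuffled)
        exceed += null_sim >= observed
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    np.fill_diagonal(pvals, 1.0)
    return pvals


def compute_similarity(
    mol_ids: Sequence[str],
    reduced: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SimilarityResult:
    """Observed cosine matrix plus permutation p-values for one space."""
    sim, zero_rows = cosine_matrix(reduced)
    if zero_rows:
        warnings.warn(
            f"{len(zero_rows)} zero-norm rows excluded from cosine (stored as 0)"
        )
    pvals = permutation_pvalues(reduced, n_permutations=n_permutations, seed=seed)
    if zero_rows:
        pvals[zero_rows, :] = 1.0
        pvals[:, zero_rows] = 1.0
    return SimilarityResult(
        mol_ids=list(mol_ids),
        sim=sim,
        pvals=pvals,
        n_permutations=n_permutations,
        seed=seed,
        zero_norm_rows=zero_rows,
    )


def build_network(
    result: SimilarityResult | None = None,
    alpha: float = 0.05,
    *,
    mol_ids: Sequence[str] | None = None,
    sim: np.ndarray | None = None,
    pvals: np.ndarray | None = None,
) -> SimilarityNetwork:
    """Keep pairs with p < alpha as undirected weighted edges.

    Isolated nodes stay in the node list. Negative similarities are kept if
    significant (the embedding stage handles the weights).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0,1)")
    if result is not None:
        mol_ids, sim, pvals = result.mol_ids, result.sim, result.pvals
    if mol_ids is None or sim is None or pvals is None:
        raise ValidationError("need a SimilarityResult or mol_ids/sim/pvals")
    sim = np.asarray(sim, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    if sim.shape != pvals.shape or sim.shape[0] != len(mol_ids):
        raise ValidationError("shape mismatch between sim, pvals and mol_ids")
    edges = []
    n = len(mol_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if pvals[i, j] < alpha:
                edges.append((i, j, float(sim[i, j]), float(pvals[i, j])))
    return SimilarityNetwork(nodes=list(mol_ids), edges=edges, alpha=alpha)
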
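"""Clustering of embedding vectors and target-sharing validation.

Embedded molecules are grouped into communities with k-means or
agglomerative clustering on their signature vectors. The biological sanity
check cross-tabulates molecule pairs by embedding similarity (similar:
cosine > 0.96; not similar: cosine < 0.46; intermediate pairs excluded)
against whether the two molecules share at least one annotated gene-symbol
target, and tests the association with a Pearson chi-squared test (no
continuity correction). The odds ratio ad/bc (Haldane +0.5 when a cell is
zero) reports which group has the higher odds of sharing targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .chem_io import TargetAnnotation
from .embedding import EmbeddingModel, embedding_similarity
from .errors import DataError, ValidationError

__all__ = [
    "AssociationResult",
    "kmeans_clusters",
    "agglomerative_clusters",
    "silhouette_scan",
    "target_sharing_test",
    "chi2_2x2",
]

SIMILAR_THRESHOLD = 0.96
NOT_SIMILAR_THRESHOLD = 0.46


@dataclass
class AssociationResult:
    """2x2 association between pair similarity class and target sharing.

    Table rows: similar / not-similar pairs; columns: >=1 common target /
    no common target.
    """

    table: np.ndarray
    chi2: float
    pvalue: float
    odds_ratio: float
    similar_has_higher_odds: bool

    @property
    def n_similar_pairs(self) -> int:
        return int(self.table[0].sum())

    @property
    def n_not_similar_pairs(self) -> int:
        return int(self.table[1].sum())


def _embedding_matrix(model: EmbeddingModel) -> tuple[list[str], np.ndarray]:
    ids = sorted(model.vectors)
    if not ids:
        raise DataError("model has no embedded molecules")
    return ids, np.vstack([model.vectors[m] for m in ids])


def kmeans_clusters(model: EmbeddingModel, k: int, seed: int = 0) -> dict[str, int]:
    """Lloyd k-means with k-means++ seeding and 10 restarts; deterministic per seed."""
    ids, matrix = _embedding_matrix(model)
    if not 1 <= k <= len(ids):
        raise ValidationError(f"k must be in [1, {len(ids)}]")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(matrix)
    return dict(zip(ids, (int(l) for l in labels)))


def agglomerative_clusters(
    model: EmbeddingModel, k: int, method: str = "average"
) -> dict[str, int]:
    """Hierarchical clustering on Euclidean embedding distances, cut at k.

    ``method`` is the linkage: average, complete or ward.
    """
    if method not in ("average", "complete", "ward"):
        raise ValidationError(f"unsupported linkage: {method!r}")
    ids, matrix = _embedding_matrix(model)
    if not 1 <= k <= len(ids):
        raise ValidationError(f"k must be in [1, {len(ids)}]")
    tree = linkage(matrix, method=method, metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return dict(zip(ids, (int(l) for l in labels)))


def silhouette_scan(
    model: EmbeddingModel, k_range: Sequence[int] = range(2, 16), seed: int = 0
) -> dict[int, float]:
    """Mean silhouette score of k-means partitions over a k range.

    Convenience helper for choosing k; not part of the core procedure.
    """
    ids, matrix = _embedding_matrix(model)
    scores = {}
    for k in k_range:
        if k >= len(ids):
            break
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(matrix)
        scores[k] = float(silhouette_score(matrix, labels))
    return scores


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        rows, cols = table.sum(axis=1), table.sum(axis=0)
        raise DataError(
            f"chi-squared undefined: zero margin (rows {rows.tolist()}, cols {cols.tolist()})"
        )
    chi2, pvalue, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(pvalue)


def _odds_ratio(table: np.ndarray) -> float:
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float((a * d) / (b * c))


def target_sharing_test(
    model: EmbeddingModel,
    annotations: Sequence[TargetAnnotation],
    hi: float = SIMILAR_THRESHOLD,
    lo: float = NOT_SIMILAR_THRESHOLD,
) -> AssociationResult:
    """Association between pair similarity class and sharing >=1 gene target.

    Considers every unordered pair of annotated, embedded molecules;
    classifies by embedding cosine (> hi similar, < lo not similar,
    otherwise excluded) and cross-tabulates against shared gene symbols.
    """
    if hi <= lo:
        raise ValidationError("hi must exceed lo")
    genes: dict[str, set[str]] = {}
    for ann in annotations:
        genes.setdefault(ann.mol_id, set()).add(ann.gene_symbol)
    annotated = sorted(set(genes) & model.embedded_nodes)
    if len(annotated) < 2:
        raise DataError("need at least 2 annotated embedded molecules")
    table = np.zeros((2, 2), dtype=np.int64)
    for id_a, id_b in combinations(annotated, 2):
        sim = embedding_similarity(model, id_a, id_b)
        if sim > hi:
            row = 0
        elif sim < lo:
            row = 1
        else:
            continue
        col = 0 if genes[id_a] & genes[id_b] else 1
        table[row, col] += 1
    chi2, pvalue = chi2_2x2(table)
    odds_ratio = _odds_ratio(table)
    return AssociationResult(
        table=table,
        chi2=chi2,
        pvalue=pvalue,
        odds_ratio=odds_ratio,
        similar_has_higher_odds=odds_ratio > 1.0,
    )
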
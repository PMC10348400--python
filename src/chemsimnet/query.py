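"""Multi-space consensus similarity search.

A query molecule is looked up in every available embedding model; per space,
all embedded molecules whose embedding cosine reaches the threshold are
hits. Hits from all spaces are unioned and ranked by the number of
intersecting spaces (spaces where the hit cleared the threshold), then by
average similarity over those spaces, then by mol_id for a total order.

If no hit exists at the requested threshold (allowed range 0.75-0.99,
default 0.95), the threshold is automatically relaxed in steps of 0.01 —
continuing below the 0.75 floor if still empty — until at least one
molecule is returned; the effective threshold is recorded on every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .embedding import EmbeddingModel, embedding_similarity
from .errors import DataError, ValidationError

__all__ = ["QueryResult", "space_neighbors", "consensus_search"]

DEFAULT_THRESHOLD = 0.95
THRESHOLD_RANGE = (0.75, 0.99)


@dataclass
class QueryResult:
    """One similar molecule found for a query."""

    query_id: str
    hit_id: str
    per_space_sim: dict[str, float]
    effective_threshold: float
    skipped_spaces: list[str] = field(default_factory=list)

    @property
    def n_intersecting_spaces(self) -> int:
        return len(self.per_space_sim)

    @property
    def avg_similarity(self) -> float:
        return sum(self.per_space_sim.values()) / len(self.per_space_sim)


def space_neighbors(
    model: EmbeddingModel, query_id: str, threshold: float
) -> list[tuple[str, float]]:
    """Embedded molecules with similarity >= threshold, most similar first.

    Ties are broken by mol_id lexicographic order.
    """
    if not -1 <= threshold < 1:
        raise ValidationError("threshold must be in [-1, 1)")
    if query_id not in model.vectors:
        raise KeyError(f"no embedding in this space for {query_id!r}")
    hits = []
    for other in model.vectors:
        if other == query_id:
            continue
        sim = embedding_similarity(model, query_id, other)
        if sim >= threshold:
            hits.append((other, sim))
    hits.sort(key=lambda item: (-item[1], item[0]))
    return hits


def consensus_search(
    models: dict[str, EmbeddingModel],
    query_id: str,
    threshold: float = DEFAULT_THRESHOLD,
    floor: float = THRESHOLD_RANGE[0],
    step: float = 0.01,
) -> list[QueryResult]:
    """Union per-space hits with automatic threshold relaxation.

    The entry threshold must lie in [0.75, 0.99]. When the union is empty
    the threshold decreases by ``step`` (passing below ``floor`` if still
    empty) until at least one molecule is found or all similarities are
    exhausted; a query isolated in every space raises an error.
    """
    lo, hi = THRESHOLD_RANGE
    if not lo <= threshold <= hi:
        raise ValidationError(f"threshold must be within [{lo}, {hi}]")
    if step <= 0:
        raise ValidationError("step must be positive")
    available = {
        label: model for label, model in models.items() if query_id in model.vectors
    }
    skipped = sorted(set(models) - set(available))
    if not available:
        raise DataError(f"query {query_id!r} is not embedded in any space")

    current = threshold
    while True:
        per_hit: dict[str, dict[str, float]] = {}
        for label in sorted(available):
            for hit_id, sim in space_neighbors(available[label], query_id, current):
                per_hit.setdefault(hit_id, {})[label] = sim
        if per_hit:
            results = [
                QueryResult(
                    query_id=query_id,
                    hit_id=hit_id,
                    per_space_sim=sims,
                    effective_threshold=current,
                    skipped_spaces=skipped,
                )
                for hit_id, sims in per_hit.items()
            ]
            results.sort(
                key=lambda r: (-r.n_intersecting_spaces, -r.avg_similarity, r.hit_id)
            )
            return results
        next_threshold = current - step
        if next_threshold <= -1.0:
            raise DataError(
                f"query {query_id!r} has no neighbors in any space at any threshold"
            )
        current = next_threshold
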
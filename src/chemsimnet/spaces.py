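"""Dimension reduction of feature blocks into chemical spaces.

Discrete blocks (fingerprint bits / counts) are weighted with TF-IDF —
molecules play the role of documents and fingerprint features the role of
terms — and reduced by latent semantic indexing (truncated SVD of the
uncentered TF-IDF matrix), keeping the smallest number of components whose
squared singular values explain at least the requested variance fraction
(default 80%).

Continuous blocks (molecular descriptors, quantum properties) are
median-imputed, standardized and reduced by PCA, retaining 80% of the
variance for wide blocks and 90% for narrow ones (at most ``feature_cutoff``
columns, default 50).

Both reductions fix the component sign by forcing the largest-magnitude
loading of each component to be positive, so repeated fits are bitwise
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import DataError, ValidationError
from .features import FeatureBlock

__all__ = [
    "SpaceConfig",
    "ChemicalSpace",
    "tfidf_transform",
    "lsi_reduce",
    "preprocess_continuous",
    "pca_reduce",
    "build_space",
    "save_space",
    "load_space",
]


@dataclass(frozen=True)
class SpaceConfig:
    """Reduction settings.

    ``retention_discrete`` applies to TF-IDF + LSI; continuous blocks use
    ``retention_wide`` when they have more than ``feature_cutoff`` features
    and ``retention_narrow`` otherwise.
    """

    retention_discrete: float = 0.80
    retention_wide: float = 0.80
    retention_narrow: float = 0.90
    feature_cutoff: int = 50
    max_missing_fraction: float = 0.5

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ChemicalSpace:
    """A reduced matrix plus the fitted transform that produced it."""

    space_label: str
    mol_ids: list[str]
    reduced: np.ndarray
    n_components: int
    variance_retained: float
    transform_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reduced.shape != (len(self.mol_ids), self.n_components):
            raise ValidationError("reduced matrix shape mismatch")
        if self.n_components < 1:
            raise ValidationError("need at least one component")

    def row(self, mol_id: str) -> np.ndarray:
        return self.reduced[self.mol_ids.index(mol_id)]


def tfidf_transform(block: FeatureBlock) -> tuple[np.ndarray, np.ndarray]:
    """TF-IDF weighting of a discrete block.

    tf is the raw value; idf(j) = ln((1+n)/(1+df_j)) + 1 with df_j the
    number of molecules where feature j is nonzero (smoothed so all-zero
    columns stay finite). No output normalization is applied — cosine
    similarity downstream is scale invariant.
    """
    if block.kind not in ("binary", "count"):
        raise ValidationError("TF-IDF applies to binary/count blocks only")
    if block.n_molecules < 2:
        raise DataError("TF-IDF needs at least 2 molecules")
    values = block.values.astype(float)
    n = values.shape[0]
    df = (values > 0).sum(axis=0)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    return values * idf, idf


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(components[np.argmax(np.abs(components), axis=0), np.arange(components.shape[1])])
    flip[flip == 0] = 1.0
    return components * flip, scores * flip


def _select_k(variance_shares: np.ndarray, retention: float) -> int:
    cumulative = np.cumsum(variance_shares)
    return int(np.searchsorted(cumulative, retention - 1e-12) + 1)


def lsi_reduce(matrix: np.ndarray, retention: float = 0.80) -> tuple[np.ndarray, int, float, dict]:
    """Truncated SVD keeping the minimal k with cumulative squared-singular-value
    share >= ``retention``. Returns ``(scores, k, variance_retained, params)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise DataError("empty matrix")
    if not 0 < retention < 1:
        raise ValidationError("retention must be in (0,1)")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise DataError("no variance: zero matrix")
    shares = s**2 / total
    k = _select_k(shares, retention)
    components, scores = _fix_signs(vt[:k].T, u[:, :k] * s[:k])
    return (
        scores,
        k,
        float(shares[:k].sum()),
        {"components": components, "singular_values": s[:k]},
    )


def preprocess_continuous(
    block: FeatureBlock, max_missing_fraction: float = 0.5
) -> tuple[np.ndarray, dict]:
    """Median-impute missing cells, drop mostly-missing columns, z-score.

    Columns with more than ``max_missing_fraction`` missing are dropped with
    a warning; an input left with no columns is an error.
    """
    if block.kind != "continuous":
        raise ValidationError("preprocess_continuous expects a continuous block")
    values = block.values.astype(float).copy()
    missing = (
        block.missing_mask.copy()
        if block.missing_mask is not None
        else np.isnan(values)
    )
    missing |= np.isnan(values)
    frac = missing.mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    dropped = [block.feature_names[j] for j in np.flatnonzero(frac > max_missing_fraction)]
    if dropped:
        warnings.warn(f"dropping columns with >{max_missing_fraction:.0%} missing: {dropped}")
    if keep.size == 0:
        raise DataError("all columns dropped: too many missing values")
    values, missing = values[:, keep], missing[:, keep]
    medians = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        observed = values[~missing[:, j], j]
        medians[j] = np.median(observed)
        values[missing[:, j], j] = medians[j]
    means = values.mean(axis=0)
    scales = values.std(axis=0)
    scales[scales == 0] = 1.0
    standardized = (values - means) / scales
    params = {
        "kept_columns": [block.feature_names[j] for j in keep],
        "medians": medians,
        "means": means,
        "scales": scales,
    }
    return standardized, params


def pca_reduce(matrix: np.ndarray, retention: float) -> tuple[np.ndarray, int, float, dict]:
    """PCA keeping the minimal k with cumulative explained-variance ratio
    >= ``retention``. Input is expected standardized (mean 0, sd 1).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise DataError("PCA needs at least 2 rows")
    if not 0 < retention < 1:
        raise ValidationError("retention must be in (0,1)")
    centered = matrix - matrix.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise DataError("no variance after centering")
    shares = s**2 / total
    k = _select_k(shares, retention)
    components, scores = _fix_signs(vt[:k].T, u[:, :k] * s[:k])
    return (
        scores,
        k,
        float(shares[:k].sum()),
        {"components": components, "explained_variance_ratio": shares[:k]},
    )


def build_space(block: FeatureBlock, config: SpaceConfig | None = None) -> ChemicalSpace:
    """Dispatch a feature block through the matching reduction pipeline."""
    config = config or SpaceConfig()
    if block.kind in ("binary", "count"):
        weighted, idf = tfidf_transform(block)
        scores, k, retained, params = lsi_reduce(weighted, config.retention_discrete)
        params = {"pipeline": "tfidf+lsi", "idf": idf, **params,
                  "retention_target": config.retention_discrete}
    elif block.kind == "continuous":
        standardized, prep = preprocess_continuous(block, config.max_missing_fraction)
        retention = (
            config.retention_narrow
            if standardized.shape[1] <= config.feature_cutoff
            else config.retention_wide
        )
        scores, k, retained, params = pca_reduce(standardized, retention)
        params = {"pipeline": "impute+scale+pca", **prep, **params,
                  "retention_target": retention}
    else:
        raise ValidationError(f"unknown block kind: {block.kind!r}")
    params["config_hash"] = config.config_hash()
    return ChemicalSpace(
        space_label=block.space_label,
        mol_ids=list(block.mol_ids),
        reduced=scores,
        n_components=k,
        variance_retained=retained,
        transform_params=params,
    )


def save_space(space: ChemicalSpace, directory: str | Path) -> Path:
    """Serialize a chemical space to a directory (CSV matrices + JSON metadata)."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        space.reduced,
        index=pd.Index(space.mol_ids, name="mol_id"),
        columns=[f"c{j + 1}" for j in range(space.n_components)],
    ).to_csv(directory / "reduced.csv")
    params = space.transform_params
    if "components" in params:
        pd.DataFrame(params["components"]).to_csv(directory / "loadings.csv", index=False)
    meta = {
        "space_label": space.space_label,
        "n_components": space.n_components,
        "variance_retained": space.variance_retained,
        "pipeline": params.get("pipeline"),
        "retention_target": params.get("retention_target"),
        "config_hash": params.get("config_hash"),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_space(directory: str | Path) -> ChemicalSpace:
    import pandas as pd

    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    frame = pd.read_csv(directory / "reduced.csv", index_col="mol_id")
    return ChemicalSpace(
        space_label=meta["space_label"],
        mol_ids=[str(m) for m in frame.index],
        reduced=frame.to_numpy(dtype=float),
        n_components=int(meta["n_components"]),
        variance_retained=float(meta["variance_retained"]),
        transform_params={
            "pipeline": meta.get("pipeline"),
            "retention_target": meta.get("retention_target"),
            "config_hash": meta.get("config_hash"),
        },
    )
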
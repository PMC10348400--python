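"""Clustering of embedding vectors and the target-sharing association test."""

from __future__ import annotations

import numpy as np
import pytest
from conftest import make_model
from scipy.cluster.hierarchy import linkage

from chemsimnet import agglomerative_clusters, kmeans_clusters, target_sharing_test
from chemsimnet.chem_io import TargetAnnotation
from chemsimnet.cluster_validate import chi2_2x2, silhouette_scan
from chemsimnet.errors import DataError, ValidationError


def blob_model(n_per=8, centers=((0, 0, 5), (5, 5, 0), (-5, 5, 5)), spread=0.2, seed=0):
    rng = np.random.default_rng(seed)
    vectors = {}
    for c, center in enumerate(centers):
        for i in range(n_per):
            vectors[f"c{c}_{i:02d}"] = np.asarray(center, dtype=float) + rng.normal(
                0, spread, size=len(center)
            )
    return make_model(vectors)


class TestChi2:
    def test_association_table_closed_form(self):
        chi2, p = chi2_2x2(np.array([[20, 5], [5, 20]]))
        assert chi2 == pytest.approx(18.0, abs=1e-9)
        assert p < 0.001

    def test_independence_table(self):
        chi2, p = chi2_2x2(np.array([[10, 10], [10, 10]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_formula_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            t = rng.integers(1, 60, size=(2, 2)).astype(float)
            (a, b), (c, d) = t
            n = t.sum()
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            chi2, _ = chi2_2x2(t)
            assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_zero_margin_reports_offender(self):
        with pytest.raises(DataError, match="zero margin"):
            chi2_2x2(np.array([[0, 0], [5, 7]]))


class TestKMeans:
    def test_single_cluster(self):
        model = blob_model()
        labels = kmeans_clusters(model, k=1, seed=0)
        assert set(labels.values()) == {0}

    def test_recovers_planted_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        model = blob_model(seed=3)
        labels = kmeans_clusters(model, k=3, seed=1)
        truth = [m.split("_")[0] for m in sorted(labels)]
        pred = [labels[m] for m in sorted(labels)]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_deterministic(self):
        model = blob_model(seed=5)
        assert kmeans_clusters(model, 3, seed=2) == kmeans_clusters(model, 3, seed=2)

    def test_k_bounds(self):
        model = blob_model(n_per=2)
        with pytest.raises(ValidationError):
            kmeans_clusters(model, k=100, seed=0)


class TestAgglomerative:
    def test_every_molecule_its_own_cluster_at_k_equals_n(self):
        model = blob_model(n_per=3)
        labels = agglomerative_clusters(model, k=len(model.vectors))
        assert len(set(labels.values())) == len(model.vectors)

    @pytest.mark.parametrize("method", ["average", "complete", "ward"])
    def test_two_tight_distant_groups_exact(self, method):
        model = blob_model(n_per=6, centers=((0, 0, 0), (50, 50, 50)), spread=0.1)
        labels = agglomerative_clusters(model, k=2, method=method)
        groups = {m.split("_")[0] for m in labels}
        for g in groups:
            members = {v for m, v in labels.items() if m.startswith(g)}
            assert len(members) == 1

    @pytest.mark.parametrize("method", ["average", "complete", "ward"])
    def test_merge_heights_non_decreasing(self, method):
        model = blob_model(seed=7)
        matrix = np.vstack([model.vectors[m] for m in sorted(model.vectors)])
        heights = linkage(matrix, method=method)[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_invalid_linkage(self):
        with pytest.raises(ValidationError):
            agglomerative_clusters(blob_model(), 2, method="single-league")


class TestSilhouetteScan:
    def test_prefers_true_k(self):
        model = blob_model(seed=11)
        scores = silhouette_scan(model, k_range=range(2, 7), seed=0)
        assert max(scores, key=scores.get) == 3


class TestTargetSharing:
    def _model_and_annotations(self):
        # group A colinear (pair cosine 1 > hi), group B orthogonal to A
        vectors = {}
        for i in range(5):
            vectors[f"A{i}"] = np.array([1.0, 0.0, 0.0]) * (1 + 0.1 * i)
            vectors[f"B{i}"] = np.array([0.0, 1.0, 0.0]) * (1 + 0.1 * i)
        model = make_model(vectors)
        annotations = [
            TargetAnnotation(mol_id=f"A{i}", gene_symbol="SHARED_A") for i in range(5)
        ] + [
            TargetAnnotation(mol_id=f"B{i}", gene_symbol=f"PRIV_B{i}") for i in range(5)
        ]
        return model, annotations

    def test_direction_and_counts(self):
        model, annotations = self._model_and_annotations()
        result = target_sharing_test(model, annotations, hi=0.96, lo=0.46)
        # similar pairs: 10 within-A (share) + 10 within-B (no share); cross pairs not similar
        assert result.table[0].tolist() == [10, 10]
        assert result.table[1].tolist() == [0, 25]
        assert result.odds_ratio > 1
        assert result.similar_has_higher_odds

    def test_pairs_counted_once(self):
        model, annotations = self._model_and_annotations()
        result = target_sharing_test(model, annotations)
        n = 10
        assert result.table.sum() <= n * (n - 1) / 2

    def test_intermediate_pairs_excluded(self):
        theta = np.deg2rad(45)  # cosine ~0.707 strictly between lo and hi
        model = make_model(
            {
                "X0": np.array([1.0, 0.0]),
                "X1": np.array([np.cos(theta), np.sin(theta)]),
                "Y0": np.array([0.0, 1.0]),
                "Y1": np.array([0.0, 1.2]),
            }
        )
        annotations = [
            TargetAnnotation(mol_id=m, gene_symbol="GX" if m.startswith("X") else "GY")
            for m in model.vectors
        ]
        result = target_sharing_test(model, annotations, hi=0.96, lo=0.46)
        # pairs X0-X1, X1-Y0, X1-Y1 are intermediate: only 3 classified pairs remain
        assert result.table.sum() == 3

    def test_parameter_validation(self):
        model, annotations = self._model_and_annotations()
        with pytest.raises(ValidationError):
            target_sharing_test(model, annotations, hi=0.4, lo=0.5)
        with pytest.raises(DataError):
            target_sharing_test(model, annotations[:1])
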
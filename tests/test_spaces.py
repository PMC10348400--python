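"""TF-IDF + LSI and impute/scale + PCA reduction contracts."""

from __future__ import annotations

import numpy as np
import pytest

from chemsimnet import (
    FeatureBlock,
    SpaceConfig,
    build_space,
    lsi_reduce,
    pca_reduce,
    preprocess_continuous,
    tfidf_transform,
)
from chemsimnet.errors import DataError, ValidationError
from chemsimnet.simnet import cosine_matrix
from chemsimnet.spaces import load_space, save_space


def discrete_block(values, kind="binary", label="fingerprint_bits"):
    values = np.asarray(values)
    return FeatureBlock(
        label,
        [f"m{i}" for i in range(values.shape[0])],
        [f"f{j}" for j in range(values.shape[1])],
        values.astype(np.int64),
        kind,
    )


def continuous_block(values, missing=None, label="descriptors"):
    values = np.asarray(values, dtype=float)
    return FeatureBlock(
        label,
        [f"m{i}" for i in range(values.shape[0])],
        [f"f{j}" for j in range(values.shape[1])],
        values,
        "continuous",
        None if missing is None else np.asarray(missing, dtype=bool),
    )


class TestTfidf:
    def test_ubiquitous_feature_has_unit_idf(self):
        block = discrete_block([[1, 1], [1, 0], [1, 3]], kind="count")
        weighted, idf = tfidf_transform(block)
        assert idf[0] == pytest.approx(1.0)  # df = n -> ln(1)+1
        assert np.allclose(weighted[:, 0], block.values[:, 0])

    def test_rare_feature_idf_value(self):
        # 4 molecules, feature present in 1: idf = ln(5/2) + 1
        block = discrete_block([[1, 1], [1, 0], [1, 0], [1, 0]])
        _, idf = tfidf_transform(block)
        assert idf[1] == pytest.approx(np.log(5 / 2) + 1, abs=1e-12)
        assert idf[1] == pytest.approx(1.9163, abs=5e-5)

    def test_all_zero_column_stays_zero(self):
        block = discrete_block([[1, 0], [1, 0], [0, 0]])
        weighted, idf = tfidf_transform(block)
        assert np.isfinite(idf).all()
        assert np.all(weighted[:, 1] == 0)

    def test_matches_sklearn(self):
        from sklearn.feature_extraction.text import TfidfTransformer

        rng = np.random.default_rng(5)
        values = rng.integers(0, 4, size=(12, 9))
        block = discrete_block(values, kind="count")
        weighted, _ = tfidf_transform(block)
        reference = (
            TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=False)
            .fit_transform(values)
            .toarray()
        )
        assert np.allclose(weighted, reference, atol=1e-10)

    def test_rejects_continuous(self):
        with pytest.raises(ValidationError):
            tfidf_transform(continuous_block([[1.0, 2.0], [3.0, 4.0]]))


class TestLsi:
    def test_rank_one(self):
        matrix = np.outer([1, 2, 3], [1, 1, 0, 2])
        scores, k, retained, _ = lsi_reduce(matrix, 0.80)
        assert k == 1
        assert retained == pytest.approx(1.0)

    def test_constructed_spectrum(self):
        # orthogonal design with squared-singular-value shares (0.7, 0.2, 0.1)
        rng = np.random.default_rng(7)
        u, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        v, _ = np.linalg.qr(rng.normal(size=(4, 3)))
        s = np.sqrt([0.7, 0.2, 0.1])
        matrix = u @ np.diag(s) @ v.T
        _, k, retained, _ = lsi_reduce(matrix, 0.80)
        assert k == 2
        assert retained == pytest.approx(0.9, abs=1e-9)

    def test_zero_matrix_rejected(self):
        with pytest.raises(DataError, match="no variance"):
            lsi_reduce(np.zeros((3, 4)), 0.8)

    def test_selected_k_is_minimal(self):
        rng = np.random.default_rng(11)
        matrix = rng.normal(size=(20, 12))
        scores, k, retained, _ = lsi_reduce(matrix, 0.80)
        shares = np.linalg.svd(matrix, compute_uv=False) ** 2
        shares = shares / shares.sum()
        assert retained >= 0.80
        if k > 1:
            assert shares[: k - 1].sum() < 0.80


class TestPreprocessContinuous:
    def test_median_impute_then_zscore(self):
        block = continuous_block(
            [[1.0], [2.0], [np.nan], [3.0]],
            missing=[[False], [False], [True], [False]],
        )
        standardized, params = preprocess_continuous(block)
        filled = np.array([1.0, 2.0, 2.0, 3.0])  # median of (1,2,3) = 2
        expected = (filled - filled.mean()) / filled.std()
        assert np.allclose(standardized[:, 0], expected)
        assert params["medians"][0] == pytest.approx(2.0)

    def test_zscoring_is_idempotent(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(30, 4))
        once, _ = preprocess_continuous(continuous_block(values))
        twice, _ = preprocess_continuous(continuous_block(once))
        assert np.allclose(once, twice, atol=1e-12)

    def test_mostly_missing_column_dropped(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan], [4.0, 5.0]])
        block = continuous_block(values, missing=np.isnan(values))
        with pytest.warns(UserWarning, match="missing"):
            standardized, params = preprocess_continuous(block)
        assert params["kept_columns"] == ["f0"]
        assert standardized.shape[1] == 1


class TestPca:
    def test_perfectly_correlated_columns(self):
        x = np.linspace(0, 1, 25)
        matrix = np.column_stack([x, 2 * x])
        matrix = (matrix - matrix.mean(0)) / matrix.std(0)
        for retention in (0.5, 0.8, 0.95):
            _, k, _, _ = pca_reduce(matrix, retention)
            assert k == 1

    def test_isotropic_gaussian_needs_four_of_five(self):
        rng = np.random.default_rng(17)
        matrix = rng.normal(size=(10000, 5))
        matrix = (matrix - matrix.mean(0)) / matrix.std(0)
        _, k, _, _ = pca_reduce(matrix, 0.80)
        assert k == 4  # each component carries ~20%

    def test_k_monotone_in_retention(self):
        rng = np.random.default_rng(19)
        matrix = rng.normal(size=(50, 10))
        _, k80, _, _ = pca_reduce(matrix, 0.80)
        _, k90, _, _ = pca_reduce(matrix, 0.90)
        assert k90 >= k80

    def test_needs_two_rows(self):
        with pytest.raises(DataError):
            pca_reduce(np.ones((1, 3)), 0.8)


class TestBuildSpace:
    def test_discrete_retention_contract(self, planted60):
        space = build_space(planted60.blocks["fingerprint_bits"])
        assert space.variance_retained >= 0.80
        assert space.n_components >= 1

    def test_narrow_continuous_block_uses_90(self, planted60):
        space = build_space(planted60.blocks["quantum"])  # 20 features <= cutoff 50
        assert space.transform_params["retention_target"] == 0.90
        assert space.variance_retained >= 0.90

    def test_wide_continuous_block_uses_80(self, planted60):
        space = build_space(planted60.blocks["descriptors"])  # 80 features > cutoff
        assert space.transform_params["retention_target"] == 0.80

    def test_cutoff_is_configurable(self, planted60):
        config = SpaceConfig(feature_cutoff=10)
        space = build_space(planted60.blocks["quantum"], config)
        assert space.transform_params["retention_target"] == 0.80

    def test_deterministic(self, planted60):
        a = build_space(planted60.blocks["fingerprint_counts"])
        b = build_space(planted60.blocks["fingerprint_counts"])
        assert np.array_equal(a.reduced, b.reduced)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(23)
        values = rng.integers(0, 2, size=(15, 40))
        block = discrete_block(values)
        perm = rng.permutation(15)
        permuted = discrete_block(values[perm])
        a = build_space(block)
        b = build_space(permuted)
        assert np.allclose(a.reduced[perm], b.reduced, atol=1e-9)

    def test_near_full_retention_preserves_cosine(self):
        rng = np.random.default_rng(29)
        values = rng.integers(0, 3, size=(8, 6))
        block = discrete_block(values, kind="count")
        weighted, _ = tfidf_transform(block)
        scores, _, _, _ = lsi_reduce(weighted, 0.999)
        full, _ = cosine_matrix(weighted)
        reduced, _ = cosine_matrix(scores)
        assert np.max(np.abs(full - reduced)) < 1e-6

    def test_roundtrip_serialization(self, tmp_path, planted60):
        space = build_space(planted60.blocks["quantum"])
        save_space(space, tmp_path / "quantum")
        loaded = load_space(tmp_path / "quantum")
        assert loaded.space_label == space.space_label
        assert loaded.n_components == space.n_components
        assert np.allclose(loaded.reduced, space.reduced, atol=1e-12)
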
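"""Similarity builders against direct evaluation and DP oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from predr import (
    AlignmentParams,
    FingerprintMatrix,
    SequenceStore,
    SimilarityMatrix,
    TargetMap,
    compute_feature_weights,
    diagonal_normalize,
    disease_profile_drug_similarity,
    normalized_sw_score,
    weighted_cosine_matrix,
)
from predr.containers import AssociationTable, ValidationError
from predr.similarity import WeightVector, sw_raw_score

from oracles import smith_waterman_dp

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _fp(values, prefix="f"):
    values = np.asarray(values)
    return FingerprintMatrix(
        tuple(f"d{i}" for i in range(values.shape[0])),
        tuple(f"{prefix}{j}" for j in range(values.shape[1])),
        values,
    )


class TestFeatureWeights:
    def test_equal_frequencies_give_uniform_weights(self):
        F = _fp([[1, 1, 1], [0, 0, 0], [1, 1, 1]])
        w = compute_feature_weights(F)
        assert w.sigma_h == 0
        np.testing.assert_array_equal(w.weights, 1.0)

    def test_direct_evaluation_and_monotonicity(self):
        # frequencies h = (1, 2, 3): sigma^2 = 2/3 (population variance)
        F = _fp([[1, 1, 1], [0, 1, 1], [0, 0, 1]])
        w = compute_feature_weights(F, d=10.0)
        h = np.array([1.0, 2.0, 3.0])
        expected = np.exp(-(h**2) / (10.0 * (2.0 / 3.0)))
        np.testing.assert_allclose(w.weights, expected, atol=1e-15)
        assert w.weights[0] > w.weights[1] > w.weights[2]

    def test_default_d_is_ten(self):
        F = _fp([[1, 0], [0, 1]])
        assert compute_feature_weights(F).d == 10.0

    def test_nonpositive_d_rejected(self):
        F = _fp([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            compute_feature_weights(F, d=0)


class TestWeightedCosine:
    def test_self_similarity_one_and_disjoint_zero(self):
        F = _fp([[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]])
        S = weighted_cosine_matrix(F, WeightVector.uniform(F.feature_ids))
        assert S.values[0, 0] == 1.0
        assert S.values[0, 1] == 0.0
        assert S.values[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_plain_cosine_value(self):
        # x=(1,1,0), x'=(1,0,1), uniform weights -> 1/(sqrt2*sqrt2) = 0.5
        F = _fp([[1, 1, 0], [1, 0, 1]])
        S = weighted_cosine_matrix(F, WeightVector.uniform(F.feature_ids))
        assert S.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_uniform_weights_equal_plain_cosine(self, rng):
        for _ in range(5):
            X = rng.integers(0, 2, size=(12, 20))
            X[X.sum(axis=1) == 0, 0] = 1
            F = _fp(X)
            S = weighted_cosine_matrix(F, WeightVector.uniform(F.feature_ids))
            Xf = X.astype(float)
            plain = Xf @ Xf.T / np.outer(
                np.linalg.norm(Xf, axis=1), np.linalg.norm(Xf, axis=1)
            )
            np.testing.assert_allclose(S.values, plain, atol=1e-12)

    def test_zero_row_convention(self):
        F = _fp([[0, 0], [1, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            S = weighted_cosine_matrix(F, WeightVector.uniform(F.feature_ids))
        assert S.values[0, 0] == 1.0
        assert S.values[0, 1] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_range_and_psd_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(8, 15))
        X[X.sum(axis=1) == 0, 0] = 1
        F = _fp(X)
        S = weighted_cosine_matrix(F, compute_feature_weights(F))
        assert (S.values >= 0).all() and (S.values <= 1 + 1e-12).all()
        assert np.linalg.eigvalsh(S.values).min() >= -1e-8


class TestSmithWaterman:
    def test_identical_sequences_normalize_to_one(self):
        assert normalized_sw_score("MKVLITAGAR", "MKVLITAGAR") == pytest.approx(1.0)

    def test_symmetry_on_random_30mers(self, rng):
        for _ in range(5):
            a = "".join(rng.choice(list(AA20), 30))
            b = "".join(rng.choice(list(AA20), 30))
            assert normalized_sw_score(a, b) == pytest.approx(
                normalized_sw_score(b, a), abs=1e-12
            )

    def test_classic_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        p = AlignmentParams()
        assert sw_raw_score(a, b, p) == smith_waterman_dp(a, b)

    def test_raw_scores_match_dp_on_random_pairs(self, rng):
        p = AlignmentParams()
        for _ in range(50):
            la, lb = rng.integers(5, 61, size=2)
            a = "".join(rng.choice(list(AA20), la))
            b = "".join(rng.choice(list(AA20), lb))
            assert sw_raw_score(a, b, p) == smith_waterman_dp(a, b)

    def test_affine_gaps_match_dp(self, rng):
        p = AlignmentParams("BLOSUM50", gap_open=10.0, gap_extend=1.0)
        for _ in range(20):
            a = "".join(rng.choice(list(AA20), 40))
            b = "".join(rng.choice(list(AA20), 40))
            assert sw_raw_score(a, b, p) == smith_waterman_dp(
                a, b, gap_open=10.0, gap_extend=1.0
            )

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValidationError):
            normalized_sw_score("MKV*", "MKV")

    def test_gap_params_validated(self):
        with pytest.raises(ValidationError):
            AlignmentParams(gap_open=2.0, gap_extend=5.0)


class TestTargetSetSimilarity:
    def test_identical_singleton_targets_give_one(self):
        from predr import target_set_similarity_matrix

        store = SequenceStore({"p1": "MKVLITAGARWQ"})
        tmap = TargetMap({"d1": frozenset({"p1"}), "d2": frozenset({"p1"})}, store)
        S = target_set_similarity_matrix(tmap, store)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_empty_target_set_flagged(self):
        from predr import target_set_similarity_matrix

        store = SequenceStore({"p1": "MKVLITAGARWQ"})
        tmap = TargetMap({"d1": frozenset({"p1"}), "d2": frozenset()}, store)
        with pytest.warns(UserWarning, match="no targets"):
            S = target_set_similarity_matrix(tmap, store)
        assert S.values[1, 1] == 1.0
        assert S.values[0, 1] == 0.0

    def test_aggregators_over_cross_pairs(self, monkeypatch):
        """T(d)={p1,p2}, T(d')={p3}, scores {0.2, 0.7}: max 0.7, mean 0.45."""
        from predr import similarity as simmod

        store = SequenceStore({"p1": "MKV", "p2": "AAA", "p3": "WWW"})
        tmap = TargetMap(
            {"d1": frozenset({"p1", "p2"}), "d2": frozenset({"p3"})}, store
        )
        fake = SimilarityMatrix(
            ("p1", "p2", "p3"),
            np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.7], [0.2, 0.7, 1.0]]),
        )
        monkeypatch.setattr(
            simmod, "pairwise_sw_matrix", lambda store, p, ids: fake.reorder(ids)
        )
        S_max = simmod.target_set_similarity_matrix(
            tmap, store, aggregator="max", normalize=False)
        S_mean = simmod.target_set_similarity_matrix(
            tmap, store, aggregator="mean", normalize=False)
        assert S_max.value("d1", "d2") == pytest.approx(0.7)
        assert S_mean.value("d1", "d2") == pytest.approx(0.45)


class TestDiagonalNormalize:
    def test_direct_value(self):
        K = SimilarityMatrix(("a", "b"), np.array([[4.0, 2.0], [2.0, 9.0]]))
        out = diagonal_normalize(K)
        np.testing.assert_allclose(
            out.values, [[1.0, 1.0 / 3.0], [1.0 / 3.0, 1.0]], atol=1e-14
        )

    def test_unit_diagonal_input_unchanged(self):
        K = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.3], [0.3, 1.0]]))
        np.testing.assert_allclose(diagonal_normalize(K).values, K.values)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_on_random_spd(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 6))
        K = SimilarityMatrix(tuple("abcdef"), A @ A.T + 6 * np.eye(6))
        once = diagonal_normalize(K)
        twice = diagonal_normalize(once)
        np.testing.assert_allclose(once.values.diagonal(), 1.0, atol=1e-12)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_nonpositive_diagonal_names_id(self):
        K = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValidationError, match="b"):
            diagonal_normalize(K)


class TestDiseaseProfileSimilarity:
    def _pheno(self):
        return SimilarityMatrix(
            ("q1", "q2", "q3"),
            np.array([[1.0, 0.3, 0.8], [0.3, 1.0, 0.55], [0.8, 0.55, 1.0]]),
        )

    def test_shared_disease_gives_one_under_max(self):
        a = AssociationTable.from_edges([("d1", "q1"), ("d2", "q1")])
        S = disease_profile_drug_similarity(a, self._pheno())
        assert S.value("d1", "d2") == pytest.approx(1.0)

    def test_enumeration_of_aggregates(self):
        a = AssociationTable.from_edges(
            [("d1", "q1"), ("d2", "q2"), ("d2", "q3")]
        )
        S_max = disease_profile_drug_similarity(a, self._pheno(), "max")
        S_mean = disease_profile_drug_similarity(a, self._pheno(), "mean")
        assert S_max.value("d1", "d2") == pytest.approx(0.8)
        assert S_mean.value("d1", "d2") == pytest.approx(0.55)

    def test_drug_without_disease_excluded_with_warning(self):
        a = AssociationTable(
            frozenset({("d1", "q1")}), ("d1", "d2"), ("q1", "q2", "q3")
        )
        with pytest.warns(UserWarning, match="d2"):
            S = disease_profile_drug_similarity(a, self._pheno())
        assert S.ids == ("d1",)

    def test_symmetric_on_random_fixture(self, small_benchmark):
        S = disease_profile_drug_similarity(
            small_benchmark.associations, small_benchmark.pheno
        )
        np.testing.assert_allclose(S.values, S.values.T, atol=1e-15)
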
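"""Metrics against brute-force oracles; CV leakage and partition audits."""

import warnings

import numpy as np
import pytest

from predr import (
    AssociationTable,
    SequenceStore,
    TargetMap,
    aupr,
    kfold_cv,
    leave_one_drug_out,
    roc_auc,
    threshold_metrics,
)
from predr.containers import ValidationError
from predr.evaluation import filter_trivial_positives

from oracles import auc_by_pair_counting, aupr_step_curve, threshold_scan_brute


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([3, 2, 1, 0], [1, 1, -1, -1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([1.0] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_six_point_fixture_matches_pair_counting(self):
        scores = [0.9, 0.8, 0.8, 0.4, 0.4, 0.1]
        labels = [1, -1, 1, 1, -1, -1]
        assert roc_auc(scores, labels) == pytest.approx(
            auc_by_pair_counting(scores, labels)
        )

    def test_random_fixtures_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            labels = rng.choice([-1, 1], size=n)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_by_pair_counting(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2], [1, 1])

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.choice([-1, 1], size=30)
        labels[0], labels[1] = 1, -1
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(2 * scores) + 5, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([4, 3, 2, 1], [1, 1, -1, -1]) == 1.0

    def test_five_point_fixture_matches_hand_stepped_curve(self):
        scores = [0.9, 0.7, 0.6, 0.4, 0.2]
        labels = [1, -1, 1, -1, 1]
        # steps: P=1 at R=1/3; P=2/3 at R=2/3; P=3/5 at R=1
        expected = (1 / 3) * 1.0 + (1 / 3) * (2 / 3) + (1 / 3) * (3 / 5)
        assert aupr(scores, labels) == pytest.approx(expected, abs=1e-12)
        assert aupr(scores, labels) == pytest.approx(
            aupr_step_curve(scores, labels), abs=1e-12
        )

    def test_random_scores_approach_positive_fraction(self, rng):
        n, pi = 4000, 0.25
        labels = np.where(rng.random(n) < pi, 1, -1)
        scores = rng.normal(size=n)
        assert aupr(scores, labels) == pytest.approx(labels.mean() / 2 + 0.5, abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            aupr([1, 2], [-1, -1])


class TestThresholdMetrics:
    def test_direct_arithmetic_fixture(self):
        # a score layout realizing TP=8 FP=2 TN=8 FN=2 at its best-F cut
        scores = [1.0] * 8 + [1.0] * 2 + [0.0] * 8 + [0.0] * 2
        labels = [1] * 8 + [-1] * 2 + [-1] * 8 + [1] * 2
        m = threshold_metrics(scores, labels)
        np.testing.assert_allclose(
            (m.acc, m.sn, m.sp, m.pre, m.f), 0.8, atol=1e-12
        )

    def test_separable_scores_reach_unity(self):
        m = threshold_metrics([5, 4, 1, 0], [1, 1, -1, -1])
        assert (m.acc, m.sn, m.sp, m.pre, m.f) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 60))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.choice([-1, 1], size=n)
            labels[:2] = [1, -1]
            ours = threshold_metrics(scores, labels)
            brute = threshold_scan_brute(scores, labels)
            np.testing.assert_allclose(tuple(ours), brute, atol=1e-12)


class TestKfoldCv:
    def test_folds_partition_labeled_pairs(self, small_benchmark, small_pair_kernel):
        rep = kfold_cv(
            small_benchmark.associations, small_pair_kernel,
            k=4, seed=3, c_grid=[1.0],
        )
        n_labeled = 2 * small_benchmark.associations.n_edges
        assert len(rep.fold_assignment) == n_labeled
        assert sum(r["n_test"] for r in rep.fold_rows) == n_labeled
        assert set(rep.fold_assignment.values()) == set(range(4))

    def test_fold_assignment_deterministic(self, small_benchmark, small_pair_kernel):
        r1 = kfold_cv(small_benchmark.associations, small_pair_kernel,
                      k=3, seed=5, c_grid=[1.0])
        r2 = kfold_cv(small_benchmark.associations, small_pair_kernel,
                      k=3, seed=5, c_grid=[1.0])
        assert r1.fold_assignment == r2.fold_assignment
        assert r1.pooled == r2.pooled

    def test_mean_is_mean_of_folds(self, small_benchmark, small_pair_kernel):
        rep = kfold_cv(small_benchmark.associations, small_pair_kernel,
                       k=3, seed=5, c_grid=[1.0])
        aucs = [r["auc"] for r in rep.fold_rows]
        assert rep.mean["auc"] == pytest.approx(np.mean(aucs))

    def test_separable_fixture_reaches_auc_one(self):
        """Noise-free planted benchmark: 2-fold CV ranks perfectly."""
        from predr import BenchmarkParams, generate_benchmark, psd_repair, PairKernel
        from predr.pipeline import build_drug_kernels

        b = generate_benchmark(BenchmarkParams(
            n_drugs=12, n_diseases=10, n_classes=2,
            bit_noise=0.0, mutation_rate=0.0, pheno_noise=0.0,
            assoc_prob_within=1.0, assoc_prob_between=0.0,
            n_chem_features=40, n_se_features=30, seq_length=40, seed=2,
        ))
        kernels = build_drug_kernels(b)
        pk = PairKernel(kernels["comb"], psd_repair(b.pheno))
        rep = kfold_cv(b.associations, pk, k=2, seed=0, c_grid=[1.0])
        assert rep.mean["auc"] == 1.0


class TestLeaveOneDrugOut:
    def test_no_leakage_and_mean_aggregation(self, small_benchmark, small_pair_kernel):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = leave_one_drug_out(
                small_benchmark.associations, small_pair_kernel, seed=1, C=1.0
            )
        assert rep.mean_auc == pytest.approx(
            np.mean(list(rep.per_drug_auc.values()))
        )
        assert set(rep.per_drug_auc) | set(rep.skipped) == {
            d for d, _ in small_benchmark.associations.edges
        }

    def test_held_out_pairs_never_trained_on(self, small_benchmark, small_pair_kernel):
        """Leakage audit: reconstruct each drug's training set the same way
        and verify it is disjoint from the drug's own pairs."""
        from predr.evaluation import _derive_seeds
        from predr.svm import sample_negatives

        a = small_benchmark.associations
        drugs = sorted({d for d, _ in a.edges})
        seeds = _derive_seeds(1, 2 + len(drugs))
        for i, drug in enumerate(drugs):
            test_pairs = {(drug, q) for q in a.disease_ids}
            reduced = a.without_drug(drug)
            train_pos = set(reduced.edges)
            train_neg = set(sample_negatives(
                reduced, len(train_pos), int(seeds[2 + i]), exclude=test_pairs
            ))
            assert not (train_pos | train_neg) & test_pairs


class TestTrivialFilter:
    def _fixture(self):
        seq_a = "MKVLITAGARWQDESTPLYH" * 3
        seq_b = "WWCCHHNNQQEEDDKKRRSS" * 3
        store = SequenceStore({"pA": seq_a, "pA2": seq_a, "pB": seq_b})
        tmap = TargetMap(
            {
                "d1": frozenset({"pA"}),
                "d2": frozenset({"pA2"}),   # identical sequence to d1's target
                "d3": frozenset({"pB"}),    # unrelated target
            },
            store,
        )
        a = AssociationTable.from_edges(
            [("d1", "q1"), ("d2", "q1"), ("d3", "q1"), ("d2", "q2")],
            ["d1", "d2", "d3"], ["q1", "q2"],
        )
        return a, tmap, store

    def test_shared_identical_target_removes_larger_drug_edge(self):
        a, tmap, store = self._fixture()
        filtered, removed = filter_trivial_positives(a, tmap, store, cutoff=0.8)
        assert ("d2", "q1") not in filtered.edges      # trivial via d1
        assert ("d1", "q1") in filtered.edges          # smaller id retained
        assert ("d3", "q1") in filtered.edges          # dissimilar target kept
        assert ("d2", "q2") in filtered.edges          # no conflicting positive
        assert len(removed) == 1 and removed[0]["conflicting_drug"] == "d1"

    def test_no_similar_targets_is_noop(self):
        a, tmap, store = self._fixture()
        tmap2 = TargetMap(
            {"d1": frozenset({"pA"}), "d2": frozenset({"pB"}),
             "d3": frozenset({"pB"})}, store)
        # d2/d3 share pB but never share a disease after dropping d3's edge
        a2 = AssociationTable.from_edges(
            [("d1", "q1"), ("d2", "q1"), ("d3", "q2")],
            ["d1", "d2", "d3"], ["q1", "q2"])
        filtered, removed = filter_trivial_positives(a2, tmap2, store, cutoff=0.8)
        assert filtered.edges == a2.edges and removed == []

    def test_cutoff_validation(self):
        a, tmap, store = self._fixture()
        with pytest.raises(ValueError):
            filter_trivial_positives(a, tmap, store, cutoff=0.0)
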
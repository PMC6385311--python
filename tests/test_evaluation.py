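import itertools
import math

import numpy as np
import pandas as pd
import pytest

from brwhnha import (
    AssociationMatrix,
    RunConfig,
    ScoreMatrix,
    ValidationError,
    auc_from_ranking,
    make_folds,
    paired_t_test,
    precision_recall_at_k,
    run_cv,
    select_evaluable_diseases,
)
from oracles import auc_bruteforce


def test_select_evaluable_boundary_inclusive():
    # disease degrees 60, 59, 61 over 61 miRNAs
    a = np.zeros((61, 3), dtype=np.int8)
    a[:60, 0] = 1
    a[:59, 1] = 1
    a[:61, 2] = 1
    assoc = AssociationMatrix(a, [f"m{i}" for i in range(61)], ["d1", "d2", "d3"])
    assert select_evaluable_diseases(assoc, 60) == ["d1", "d3"]
    assert select_evaluable_diseases(assoc, 62) == []


class TestFolds:
    def test_even_split(self):
        plan = make_folds([f"m{i}" for i in range(10)], 5, seed=1)
        assert sorted(len(f) for f in plan.folds) == [2, 2, 2, 2, 2]

    def test_near_equal_split(self):
        plan = make_folds([f"m{i}" for i in range(11)], 5, seed=1)
        assert sorted(len(f) for f in plan.folds) == [2, 2, 2, 2, 3]

    def test_union_is_input_and_disjoint(self):
        ids = [f"m{i}" for i in range(13)]
        plan = make_folds(ids, 5, seed=3)
        flat = [m for fold in plan.folds for m in fold]
        assert sorted(flat) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"m{i}" for i in range(12)]
        assert make_folds(ids, 5, seed=9).folds == make_folds(ids, 5, seed=9).folds

    def test_too_few_members_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(["m1", "m2"], 5, seed=0)


class TestAuc:
    def test_perfect_and_worst(self):
        assert auc_from_ranking([1, 2], 6) == 1.0
        assert auc_from_ranking([5, 6], 6) == 0.0

    def test_hand_value(self):
        # positives at ranks 1 and 4 of 4: rank-1 beats both negatives,
        # rank-4 beats none -> 2 of 4 pairs
        assert auc_from_ranking([1, 4], 4) == pytest.approx(0.5)

    def test_exhaustive_bruteforce_agreement(self):
        """All rankings with <= 8 candidates and <= 3 positives."""
        for n in range(2, 9):
            for n_pos in range(1, min(3, n - 1) + 1):
                for ranks in itertools.combinations(range(1, n + 1), n_pos):
                    assert auc_from_ranking(list(ranks), n) == pytest.approx(
                        auc_bruteforce(list(ranks), n), abs=1e-12
                    )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            auc_from_ranking([], 4)
        with pytest.raises(ValidationError):
            auc_from_ranking([1, 2], 2)  # no negatives
        with pytest.raises(ValidationError):
            auc_from_ranking([1, 1], 4)  # duplicate ranks


class TestPrecisionRecall:
    def test_counting(self):
        ranking = [f"m{i}" for i in range(20)]
        positives = {"m0", "m5", "m15"}  # 2 in the top 10
        pr = precision_recall_at_k(ranking, positives, [10, 20])
        assert pr[10] == (pytest.approx(0.2), pytest.approx(2 / 3))
        assert pr[20] == (pytest.approx(0.15), pytest.approx(1.0))

    def test_no_hits(self):
        pr = precision_recall_at_k(["a", "b"], {"z"}, [2])
        assert pr[2] == (0.0, 0.0)

    def test_recall_nondecreasing_in_k(self):
        rng = np.random.default_rng(2)
        ranking = [f"m{i}" for i in rng.permutation(50)]
        positives = set(ranking[::7])
        pr = precision_recall_at_k(ranking, positives, list(range(5, 51, 5)))
        recalls = [pr[k][1] for k in sorted(pr)]
        assert all(a <= b for a, b in zip(recalls, recalls[1:]))

    def test_unsorted_ks_rejected(self):
        with pytest.raises(ValidationError):
            precision_recall_at_k(["a"], {"a"}, [10, 5])


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t_test([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.degenerate_variance

    def test_constant_nonzero_difference(self):
        res = paired_t_test([0.8, 0.7], [0.7, 0.6])
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.pvalue == 0.0 and res.degenerate_variance

    def test_closed_form_t(self):
        # differences (0.02, 0.03, 0.01, 0.02): mean 0.02,
        # sd = sqrt(2e-4/3), t = mean / (sd / 2)
        b = [0.80, 0.81, 0.82, 0.83]
        a = [x + d for x, d in zip(b, (0.02, 0.03, 0.01, 0.02))]
        sd = math.sqrt(2e-4 / 3)
        expected_t = 0.02 / (sd / 2)
        res = paired_t_test(a, b)
        assert res.statistic == pytest.approx(expected_t, abs=1e-10)
        assert 0 < res.pvalue < 0.05
        assert not res.degenerate_variance

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t_test([0.1, 0.2], [0.1])


def _toy_network(n_m=30, n_d=4, degree=8, seed=0):
    """Small dense-enough network where every disease is evaluable."""
    rng = np.random.default_rng(seed)
    a = np.zeros((n_m, n_d), dtype=np.int8)
    for j in range(n_d):
        rows = rng.choice(n_m, size=degree, replace=False)
        a[rows, j] = 1
    assoc = AssociationMatrix(
        a, [f"m{i:02d}" for i in range(n_m)], [f"d{j}" for j in range(n_d)]
    )
    from brwhnha import SimilarityMatrix

    def sim(n, prefix):
        s = rng.random((n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        return s

    dss = SimilarityMatrix(sim(n_d, "d"), assoc.disease_ids, "semantic")
    mfs = SimilarityMatrix(sim(n_m, "m"), assoc.mirna_ids, "functional")
    return assoc, dss, mfs


class TestRunCV:
    def test_oracle_scorer_gets_auc_one(self):
        """A scorer that knows the held-out edges must score perfect AUC —
        sanity check that the harness wires positives and candidates up
        correctly."""
        assoc, dss, mfs = _toy_network()

        def oracle(masked, d, m, c):
            # score = 1 for every edge of the *full* matrix, so held-out
            # test edges outrank all never-associated candidates
            return ScoreMatrix(
                assoc.values.astype(float), assoc.mirna_ids, assoc.disease_ids,
                stage="walk_output",
            )

        report = run_cv(assoc, dss, mfs, RunConfig(seed=1), n_folds=5, repeats=2,
                        min_degree=5, ks=[10], scorer=oracle)
        assert (report.records["auc"] == 1.0).all()

    def test_random_scorer_near_half(self):
        assoc, dss, mfs = _toy_network(n_m=60, degree=20)
        rng = np.random.default_rng(99)

        def random_scorer(masked, d, m, c):
            return ScoreMatrix(
                rng.random(masked.values.shape), masked.mirna_ids,
                masked.disease_ids, stage="walk_output",
            )

        report = run_cv(assoc, dss, mfs, RunConfig(seed=2), n_folds=5, repeats=20,
                        min_degree=5, ks=[10], scorer=random_scorer)
        assert abs(report.records["auc"].mean() - 0.5) < 0.05

    def test_bit_reproducible_given_seed(self):
        assoc, dss, mfs = _toy_network()
        kwargs = dict(n_folds=5, repeats=2, min_degree=5, ks=[5, 10])
        r1 = run_cv(assoc, dss, mfs, RunConfig(seed=7), **kwargs)
        r2 = run_cv(assoc, dss, mfs, RunConfig(seed=7), **kwargs)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_freeze_disease_kernel_switch_runs(self):
        assoc, dss, mfs = _toy_network()
        report = run_cv(assoc, dss, mfs, RunConfig(seed=3), n_folds=5, repeats=1,
                        min_degree=5, ks=[10], freeze_disease_kernel=True)
        assert len(report.records) > 0
        assert ((report.records["auc"] >= 0) & (report.records["auc"] <= 1)).all()

    def test_aggregates(self):
        assoc, dss, mfs = _toy_network()
        report = run_cv(assoc, dss, mfs, RunConfig(seed=4), n_folds=5, repeats=2,
                        min_degree=5, ks=[10])
        per_disease = report.per_disease()
        assert set(per_disease["disease_id"]) == set(assoc.disease_ids)
        assert 0.0 <= report.mean_auc <= 1.0
        assert report.best_repeat_auc >= report.mean_auc - 1e-12
        pr = report.mean_precision_recall()
        assert list(pr["k"]) == [10]
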
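"""Negative sampling, folds, metrics, experiment plumbing, ranking."""

import numpy as np
import pytest

import mirdisc as md
from mirdisc.embedding import FeatureTable
from mirdisc.evaluation import assemble_dataset, pr_curve_grid, roc_curve_grid
from mirdisc.graphs import ConfigurationError

from conftest import brute_force_roc_auc, hand_average_precision


class TestSampleNegatives:
    def test_ratio_times_positives(self):
        pool = {f"m{i}" for i in range(50)}
        neg = md.sample_negatives(pool, n_pos=10, ratio=2, seed=0)
        assert len(neg) == 20 and neg <= pool

    def test_ratio_all_returns_whole_pool(self):
        pool = {f"m{i}" for i in range(50)}
        assert md.sample_negatives(pool, 10, "all", seed=0) == pool

    def test_same_seed_identical_sample(self):
        pool = {f"m{i}" for i in range(40)}
        s1 = md.sample_negatives(pool, 5, 3, seed=7)
        s2 = md.sample_negatives(pool, 5, 3, seed=7)
        assert s1 == s2

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ConfigurationError):
            md.sample_negatives({"a", "b"}, 10, 2, seed=0)


class TestKFold:
    def test_even_fold_sizes(self):
        y = [0] * 80 + [1] * 20
        folds = md.kfold_split([str(i) for i in range(100)], y, k=5, seed=0)
        assert all(len(te) == 20 for _, te in folds)

    def test_folds_partition_exactly(self):
        y = [0] * 30 + [1] * 15
        folds = md.kfold_split([str(i) for i in range(45)], y, k=5, seed=1)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(45))
        for i, (_, te_i) in enumerate(folds):
            for j, (_, te_j) in enumerate(folds):
                if i < j:
                    assert len(np.intersect1d(te_i, te_j)) == 0

    def test_stratification_exact_with_divisible_counts(self):
        y = np.array([1] * 10 + [0] * 40)
        folds = md.kfold_split([str(i) for i in range(50)], y, k=5, seed=2)
        for _, te in folds:
            assert y[te].sum() == 2

    def test_too_few_positives_rejected(self):
        with pytest.raises(ConfigurationError):
            md.kfold_split(["a"] * 10, [1] + [0] * 9, k=5, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert md.roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.1]) == 1.0

    def test_hand_counted_pairs(self):
        # pos {0.8, 0.3}, neg {0.5, 0.1}: 3 of 4 pairs won
        assert md.roc_auc([1, 0, 1, 0], [0.8, 0.5, 0.3, 0.1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert md.roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            md.roc_auc([1, 1], [0.1, 0.2])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(4, 50)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            assert md.roc_auc(y, scores) == pytest.approx(
                brute_force_roc_auc(y, scores), abs=1e-12
            )


class TestPrAuc:
    def test_perfect_ranking(self):
        assert md.pr_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_worked_four_point_example(self):
        # descending: 0.8 (pos, P=1, dR=1/2) then 0.3 (pos, P=2/3, dR=1/2)
        y, s = [1, 0, 1, 0], [0.8, 0.5, 0.3, 0.1]
        expected = 1.0 * 0.5 + (2 / 3) * 0.5
        assert md.pr_auc(y, s) == pytest.approx(expected, abs=1e-12)
        assert hand_average_precision(y, s) == pytest.approx(expected, abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(5)
        n, prevalence = 300, 0.2
        y = np.zeros(n, dtype=int)
        y[: int(n * prevalence)] = 1
        vals = [md.pr_auc(y, rng.random(n)) for _ in range(200)]
        assert abs(np.mean(vals) - prevalence) < 0.03

    def test_inverted_ranker_on_balanced_data_below_chance_band(self):
        y = [1] * 10 + [0] * 10
        scores = np.linspace(0, 1, 20)  # ascending: ranks positives last
        assert md.pr_auc(y, scores) < 0.55

    def test_no_positives_undefined(self):
        with pytest.raises(ValueError):
            md.pr_auc([0, 0], [0.1, 0.2])


class TestF1:
    def test_direct_formula(self):
        # TP=2, FP=1, FN=1 -> P = R = 2/3
        assert md.f1([1, 1, 1, 0], [1, 1, 0, 1]) == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        assert md.f1([1, 0, 1], [1, 0, 1]) == 1.0

    def test_no_predicted_positives_is_zero(self):
        assert md.f1([1, 1, 0], [0, 0, 0]) == 0.0


def _toy_features(n=60, d=8, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"m{i}" for i in range(n)]
    pos = set(ids[: n // 3])
    feats = rng.normal(size=(n, 2 * d))
    shift = np.array([2.5] * d + [0.0] * d)
    for i, m in enumerate(ids):
        if m in pos:
            feats[i] += shift
    table = FeatureTable(ids, feats, np.ones((n, 2), dtype=bool))
    labels = md.LabelSet(positives=pos, universe=set(ids))
    return table, labels


class TestExperiments:
    ENC = dict(epochs=4, patience=4, batch_size=16)

    def test_similarity_only_zeroes_interaction_block(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(
            negative_ratio="all", feature_source="similarity_only", seed=0
        )
        X, y, ids = assemble_dataset(table, labels, cfg)
        assert np.all(X[:, table.block_width :] == 0.0)
        assert len(ids) == 60 and y.sum() == 20

    def test_ratio_limits_negative_count(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(negative_ratio=1, seed=0)
        X, y, _ = assemble_dataset(table, labels, cfg)
        assert len(y) == 40 and y.sum() == 20

    def test_same_seed_reproduces_report(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(negative_ratio="all", seed=3, encoder_params=self.ENC)
        r1 = md.run_experiment(table, labels, cfg)
        r2 = md.run_experiment(table, labels, cfg)
        assert r1.fold_roc_auc == r2.fold_roc_auc
        assert r1.fold_pr_auc == r2.fold_pr_auc
        assert r1.fold_f1 == r2.fold_f1

    def test_report_aggregates_are_fold_means(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(negative_ratio="all", seed=1, encoder_params=self.ENC)
        rep = md.run_experiment(table, labels, cfg)
        assert rep.mean_roc_auc == pytest.approx(np.mean(rep.fold_roc_auc))
        assert len(rep.fold_roc_auc) == 5
        for v in rep.fold_roc_auc + rep.fold_pr_auc + rep.fold_f1:
            assert 0.0 <= v <= 1.0

    def test_curve_grids_are_well_formed(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(negative_ratio="all", seed=1, encoder_params=self.ENC)
        rep = md.run_experiment(table, labels, cfg)
        roc = roc_curve_grid(rep.fold_labels, rep.fold_scores)
        pr = pr_curve_grid(rep.fold_labels, rep.fold_scores)
        assert len(roc) == 101 and len(pr) == 101
        assert roc["tpr_mean"].iloc[-1] == pytest.approx(1.0)


class TestRanking:
    def test_ranked_candidates_contract(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(negative_ratio="all", seed=0)
        X, y, _ = assemble_dataset(table, labels, cfg)
        model = md.CnnGnbClassifier(epochs=4, batch_size=16, random_state=0).fit(X, y)
        ranked = md.rank_candidates(model, table, labels, top_k=10)
        assert len(ranked) == 10
        probs = [p for _, p in ranked]
        assert probs == sorted(probs, reverse=True)
        assert all(m not in labels.positives for m, _ in ranked)

    def test_full_ranking_excludes_every_positive(self):
        table, labels = _toy_features()
        cfg = md.ExperimentConfig(negative_ratio="all", seed=0)
        X, y, _ = assemble_dataset(table, labels, cfg)
        model = md.CnnGnbClassifier(epochs=4, batch_size=16, random_state=0).fit(X, y)
        ranked = md.rank_candidates(model, table, labels)
        assert len(ranked) == len(labels.unlabeled)
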
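"""Negative sampling, training, cross-validation, ranking, grid search."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from smilegnn.fusion_predictor import DrugPairDataset
from smilegnn.training_eval import (SmileGNNClassifier, TrainConfig,
                                    evaluate_cv, grid_search,
                                    rank_novel_pairs, sample_negatives, train)


def brute_force_auc(y, scores):
    """O(n^2) concordant-pair oracle (ties count half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestNegativeSampling:
    def test_forced_single_remaining_pair(self):
        # C(4,2)=6 pairs, 5 positive: the sampler is forced onto (c, d)
        pos = DrugPairDataset(pairs=[("a", "b", 1), ("a", "c", 1), ("a", "d", 1),
                                     ("b", "c", 1), ("b", "d", 1)])
        neg = sample_negatives(pos, ratio=1.0, rng_seed=0)
        assert neg.pairs == [("c", "d", 0)]

    def test_exhausted_pool_is_an_error(self):
        pos = DrugPairDataset(pairs=[("a", "b", 1)])
        with pytest.raises(ValueError, match="no non-positive"):
            sample_negatives(pos, ratio=1.0, rng_seed=0)

    def test_disjoint_from_positives_any_seed(self):
        rng = np.random.default_rng(0)
        drugs = [f"DB{i}" for i in range(30)]
        pos_set = set()
        while len(pos_set) < 60:
            a, b = rng.choice(30, 2, replace=False)
            pos_set.add((f"DB{min(a,b)}", f"DB{max(a,b)}"))
        pos = DrugPairDataset(pairs=[(a, b, 1) for a, b in pos_set])
        for seed in range(5):
            neg = sample_negatives(pos, 1.0, rng_seed=seed, drugs=drugs)
            assert len(neg) == 60
            assert not (neg.positives() & pos_set or
                        {(a, b) for a, b, _ in neg.pairs} & pos_set)

    def test_different_seeds_differ_but_same_size(self):
        rng = np.random.default_rng(1)
        pos_set = set()
        while len(pos_set) < 200:
            a, b = rng.choice(100, 2, replace=False)
            pos_set.add((f"DB{min(a,b):03d}", f"DB{max(a,b):03d}"))
        pos = DrugPairDataset(pairs=[(a, b, 1) for a, b in pos_set])
        n1 = sample_negatives(pos, 1.0, rng_seed=1)
        n2 = sample_negatives(pos, 1.0, rng_seed=2)
        assert len(n1) == len(n2) == 200
        assert {p[:2] for p in n1.pairs} != {p[:2] for p in n2.pairs}


class TestAucOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_rank_statistic_equals_concordance_count(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1  # guarantee both classes
        s = rng.uniform(size=200).round(2)  # rounding forces some ties
        assert roc_auc_score(y, s) == pytest.approx(brute_force_auc(y, s),
                                                    abs=1e-9)


class TestTraining:
    def test_loss_decreases_on_planted_signal(self, tiny_model):
        assert tiny_model.loss_history_[-1] < tiny_model.loss_history_[0]

    def test_same_seed_reproduces_parameters_bitwise(self, tiny_sim):
        ds, kg, struct = tiny_sim
        X = np.array([(a, b) for a, b, _ in ds.pairs.pairs], dtype=object)
        y = ds.pairs.labels()
        runs = []
        for _ in range(2):
            clf = SmileGNNClassifier(kg=kg, struct_features=struct, embed_dim=8,
                                     sample_size=3, epochs=3, seed=5)
            clf.fit(X, y)
            runs.append(clf)
        np.testing.assert_array_equal(
            runs[0].gnn_params_.entity_embeddings.data,
            runs[1].gnn_params_.entity_embeddings.data)
        np.testing.assert_array_equal(runs[0].fusion_params_.W.data,
                                      runs[1].fusion_params_.W.data)
        assert runs[0].loss_history_ == runs[1].loss_history_

    def test_train_wrapper_learns_signal(self, tiny_sim, tiny_config):
        ds, kg, struct = tiny_sim
        model = train(kg, struct, ds.pairs, tiny_config)
        assert model.loss_history_[-1] < model.loss_history_[0]

    def test_sklearn_get_set_params_round_trip(self, tiny_sim):
        _, kg, struct = tiny_sim
        clf = SmileGNNClassifier(kg=kg, struct_features=struct, embed_dim=8)
        params = clf.get_params()
        assert params["embed_dim"] == 8
        clf.set_params(epochs=2)
        assert clf.epochs == 2

    def test_pair_shape_validated(self, tiny_sim):
        _, kg, _ = tiny_sim
        clf = SmileGNNClassifier(kg=kg)
        with pytest.raises(ValueError, match=r"\(n, 2\)"):
            clf.fit(np.zeros((3, 3)), np.zeros(3))


class TestCrossValidation:
    def test_stratified_folds_preserve_label_ratio(self, tiny_sim):
        from sklearn.model_selection import StratifiedKFold
        ds, _, _ = tiny_sim
        y = ds.pairs.labels()
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros_like(y), y):
            assert abs(y[te].sum() - len(te) / 2 * (y.mean() * 2)) <= 1

    def test_cv_metrics_in_unit_interval_and_mean_of_folds(self, tiny_sim,
                                                           tiny_config):
        ds, kg, struct = tiny_sim
        m = evaluate_cv(kg, struct, ds.pairs, tiny_config)
        for v in (m.accuracy, m.auc, m.f1):
            assert 0.0 <= v <= 1.0
        assert m.auc == pytest.approx(np.mean(m.fold_auc))
        assert len(m.fold_auc) == tiny_config.n_folds

    def test_end_to_end_determinism(self, tiny_sim, tiny_config):
        ds, kg, struct = tiny_sim
        m1 = evaluate_cv(kg, struct, ds.pairs, tiny_config)
        m2 = evaluate_cv(kg, struct, ds.pairs, tiny_config)
        assert m1.fold_auc == m2.fold_auc
        assert m1.fold_accuracy == m2.fold_accuracy


class TestRanking:
    def test_all_candidates_known_yields_empty(self, tiny_model, tiny_sim):
        ds, _, _ = tiny_sim
        known = [(a, b) for a, b, lab in ds.pairs.pairs if lab == 1]
        out = rank_novel_pairs(tiny_model, known, ds.pairs, threshold=0.0)
        assert out.pairs == []

    def test_threshold_filter_and_ordering(self, tiny_model, tiny_sim):
        ds, kg, _ = tiny_sim
        drugs = sorted(kg.entities[i] for i in kg.drug_ids)
        candidates = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1:]]
        out = rank_novel_pairs(tiny_model, candidates, ds.pairs, threshold=0.9)
        known = ds.pairs.positives()
        scores = [p.score for p in out.pairs]
        assert all(s > 0.9 for s in scores)
        assert scores == sorted(scores, reverse=True)
        assert all((p.drug1_id, p.drug2_id) not in known and
                   (p.drug2_id, p.drug1_id) not in known for p in out.pairs)

    def test_top_k_matches_exhaustive_oracle(self, tiny_model, tiny_sim):
        ds, kg, _ = tiny_sim
        drugs = sorted(kg.entities[i] for i in kg.drug_ids)
        candidates = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1:]]
        out = rank_novel_pairs(tiny_model, candidates, ds.pairs,
                               threshold=0.0, top_k=10)
        # oracle: score everything, drop known, sort, take 10
        known = ds.pairs.positives()
        novel = [c for c in candidates if (min(c), max(c)) not in known]
        scored = tiny_model.score_pairs(novel)
        scored.sort(key=lambda s: (-s.score, s.drug1_id, s.drug2_id))
        assert [(p.drug1_id, p.drug2_id) for p in out.pairs] == \
               [(p.drug1_id, p.drug2_id) for p in scored[:10]]


class TestGridSearch:
    def test_singleton_grid_returns_that_config(self, tiny_sim, tiny_config):
        ds, kg, struct = tiny_sim
        best, results = grid_search([tiny_config], kg, struct, ds.pairs)
        assert best == tiny_config and len(results) == 1

    def test_sabotaged_learning_rate_loses(self, tiny_sim, tiny_config):
        ds, kg, struct = tiny_sim
        crippled = TrainConfig(**{**tiny_config.to_dict(),
                                  "learning_rate": 1e-12, "epochs": 2})
        best, results = grid_search([crippled, tiny_config], kg, struct, ds.pairs)
        assert best == tiny_config
        # winner equals manual argmax over the logged AUCs
        manual = max(results, key=lambda cm: (cm[1].auc, cm[1].f1,
                                              -cm[0].embed_dim))[0]
        assert best == manual
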
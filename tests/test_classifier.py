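"""Siblings-policy training sets, per-term forests, hierarchy enforcement."""

import numpy as np
import pytest

from funcland import (
    ScoreMatrix,
    enforce_hierarchy,
    fit_term_model,
    score_genes,
    siblings_training_set,
)
from funcland.classifier import ClassifierError, seed_for_term

from conftest import random_dag, store_from


class TestSiblingsPolicy:
    def test_hand_enumerated_example(self, two_level_tree):
        # R -> {A, C}, A -> {B, D}; target B
        store = store_from(
            {
                "g1": {"B", "A", "R"},
                "g2": {"D", "A", "R"},  # sibling D
                "g3": {"C", "R"},  # uncle C
            }
        )
        ts = siblings_training_set(two_level_tree, store, "B")
        assert ts.positives == {"g1"}
        assert ts.negatives == {"g2", "g3"}
        assert not ts.fallback_used

    def test_gene_with_target_and_sibling_is_positive(self, two_level_tree):
        store = store_from(
            {"g1": {"B", "D", "A", "R"}, "g2": {"D", "A", "R"}}
        )
        ts = siblings_training_set(two_level_tree, store, "B")
        assert "g1" in ts.positives
        assert "g1" not in ts.negatives

    def test_fallback_when_no_siblings_or_uncles(self, chain_graph):
        # chain R -> A -> B: A has neither siblings nor uncles
        store = store_from(
            {"g1": {"A", "R"}, "g2": {"R"}, "g3": {"R"}}
        )
        ts = siblings_training_set(chain_graph, store, "A")
        assert ts.fallback_used
        assert ts.positives == {"g1"}
        assert ts.negatives and ts.negatives <= {"g2", "g3"}

    def test_requires_propagated_store(self, two_level_tree):
        store = store_from({"g1": {"B"}}, propagated=False)
        with pytest.raises(ClassifierError):
            siblings_training_set(two_level_tree, store, "B")


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += y * 3  # widen the margin
    return X, y


class TestFit:
    def test_separable_data_fits_perfectly(self):
        X, y = _separable()
        tm = fit_term_model(
            X, y, {"n_estimators": [20], "max_depth": [5], "criterion": ["gini"]},
            seed=0, target="t"
        )
        assert (tm.estimator.predict(X) == y).all()

    def test_same_seed_reproduces_model(self):
        X, y = _separable()
        grid = {"n_estimators": [10, 20], "max_depth": [3, None]}
        a = fit_term_model(X, y, grid, seed=5, target="t")
        b = fit_term_model(X, y, grid, seed=5, target="t")
        assert a.params == b.params
        assert np.array_equal(
            a.estimator.predict_proba(X), b.estimator.predict_proba(X)
        )

    def test_single_point_grid_is_chosen(self):
        X, y = _separable()
        grid = {"n_estimators": [15], "max_depth": [4], "criterion": ["entropy"]}
        tm = fit_term_model(X, y, grid, seed=1, target="t")
        assert tm.params == {
            "n_estimators": 15, "max_depth": 4, "criterion": "entropy"
        }
        assert np.isfinite(tm.cv_score)

    def test_no_cv_path_with_single_point_grid(self):
        X, y = _separable()
        tm = fit_term_model(
            X, y, {"n_estimators": [10]}, folds=0, seed=1, target="t"
        )
        assert np.isnan(tm.cv_score)

    def test_single_class_labels_raise_naming_term(self):
        X, _ = _separable()
        with pytest.raises(ClassifierError, match="myterm"):
            fit_term_model(X, np.ones(len(X)), {"n_estimators": [5]},
                           target="myterm")

    def test_seed_for_term_stable_and_bounded(self):
        s1 = seed_for_term(42, "T.1.0")
        assert s1 == seed_for_term(42, "T.1.0")
        assert s1 != seed_for_term(42, "T.1.1")
        assert 0 <= s1 < 2**31


class TestScore:
    def _models(self, targets):
        X, y = _separable()
        return [
            fit_term_model(X, y, {"n_estimators": [10]}, folds=0,
                           seed=i, target=t)
            for i, t in enumerate(targets)
        ]

    def test_scores_bounded_and_shaped(self):
        models = self._models(["A", "B"])
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(7)]
        mats = {m.target: rng.normal(size=(7, 4)) for m in models}
        sm = score_genes(models, lambda t: mats[t], genes)
        assert sm.scores.shape == (7, 2)
        assert sm.scores.min() >= 0 and sm.scores.max() <= 1

    def test_single_gene_matrix(self):
        models = self._models(["A"])
        sm = score_genes(models, lambda t: np.zeros((1, 4)), ["g"])
        assert sm.scores.shape == (1, 1)

    def test_constant_features_give_constant_column(self):
        models = self._models(["A"])
        sm = score_genes(models, lambda t: np.zeros((5, 4)), list("abcde"))
        assert len(set(sm.scores[:, 0])) == 1

    def test_feature_width_mismatch_raises(self):
        models = self._models(["A"])
        with pytest.raises(ClassifierError):
            score_genes(models, lambda t: np.zeros((2, 9)), ["g1", "g2"])


class TestHierarchy:
    def test_chain_child_capped_by_parent(self, chain_graph):
        sm = ScoreMatrix(["g"], ["A", "B"], np.array([[0.2, 0.9]]))
        out = enforce_hierarchy(sm, chain_graph)
        assert out.scores[0].tolist() == [0.2, 0.2]

    def test_diamond_min_over_parents(self, diamond_graph):
        sm = ScoreMatrix(["g"], ["A", "B", "C"], np.array([[0.5, 0.4, 0.3]]))
        out = enforce_hierarchy(sm, diamond_graph)
        assert out.scores[0, out.terms.index("B")] == pytest.approx(0.3)

    def test_consistent_matrix_unchanged_and_idempotent(self, chain_graph):
        sm = ScoreMatrix(["g"], ["A", "B"], np.array([[0.8, 0.3]]))
        once = enforce_hierarchy(sm, chain_graph)
        assert np.array_equal(once.scores, sm.scores)
        twice = enforce_hierarchy(once, chain_graph)
        assert np.array_equal(once.scores, twice.scores)

    def test_unmodeled_parent_imposes_no_constraint(self, chain_graph):
        # only B scored; its parent A has no model -> implicit score 1
        sm = ScoreMatrix(["g"], ["B"], np.array([[0.9]]))
        out = enforce_hierarchy(sm, chain_graph)
        assert out.scores[0, 0] == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_end_consistent_and_never_increase(self, seed):
        import random as pyrandom

        rng = pyrandom.Random(seed)
        graph = random_dag(rng, rng.randint(5, 15))
        terms = sorted(t for t in graph.terms if not graph.is_root(t))
        np_rng = np.random.default_rng(seed)
        scores = np_rng.random((6, len(terms)))
        sm = ScoreMatrix([f"g{i}" for i in range(6)], terms, scores)
        out = enforce_hierarchy(sm, graph)
        assert np.all(out.scores <= sm.scores + 1e-15)
        idx = {t: j for j, t in enumerate(terms)}
        for t in terms:
            for p in graph.parents(t):
                if p in idx:
                    assert np.all(
                        out.scores[:, idx[t]] <= out.scores[:, idx[p]] + 1e-12
                    )
        # thresholded prediction sets are ancestor-closed
        for theta in (0.2, 0.5, 0.8):
            for i in range(6):
                pred = {t for t in terms if out.scores[i, idx[t]] >= theta}
                for t in pred:
                    for p in graph.parents(t):
                        if p in idx:
                            assert p in pred
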
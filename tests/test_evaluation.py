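"""Hierarchical metrics, null model, threshold selection, final predictions."""

import random

import numpy as np
import pytest

from funcland import (
    OntologyGraph,
    ScoreMatrix,
    finalize_predictions,
    hf_curve,
    hierarchical_prf,
    predictions_by_depth,
    random_scores,
    ratio_curve,
)
from funcland.evaluation import EvaluationError

from conftest import brute_hierarchical_prf, random_dag, store_from


class TestHierarchicalPRF:
    def test_worked_two_gene_chain_example(self, chain_graph):
        truth = store_from({"g1": {"R", "A"}, "g2": {"R", "A", "B"}})
        scores = ScoreMatrix(
            ["g1", "g2"], ["A", "B"], np.array([[0.9, 0.9], [0.9, 0.1]])
        )
        hprec, hrec, hf1 = hierarchical_prf(truth, scores, 0.5, chain_graph)
        assert hprec == pytest.approx(4 / 5)
        assert hrec == pytest.approx(4 / 5)
        assert hf1 == pytest.approx(0.8)

    def test_perfect_predictor_scores_one(self, chain_graph):
        truth = store_from({"g1": {"R", "A"}, "g2": {"R", "A", "B"}})
        scores = ScoreMatrix(
            ["g1", "g2"], ["A", "B"], np.array([[0.9, 0.1], [0.9, 0.9]])
        )
        assert hierarchical_prf(truth, scores, 0.5, chain_graph) == (1, 1, 1)

    def test_gene_missing_from_truth_raises(self, chain_graph):
        truth = store_from({"g1": {"R", "A"}})
        scores = ScoreMatrix(["g1", "gX"], ["A"], np.array([[0.9], [0.9]]))
        with pytest.raises(EvaluationError):
            hierarchical_prf(truth, scores, 0.5, chain_graph)

    def test_flat_one_level_ontology_reduces_to_micro_prf(self):
        # root with 4 leaves: hierarchical metrics coincide with classical
        # micro precision/recall over the per-gene label sets (root incl.)
        g = OntologyGraph.from_edges([(f"L{i}", "R") for i in range(4)])
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(8)]
        terms = [f"L{i}" for i in range(4)]
        scores = ScoreMatrix(genes, terms, rng.random((8, 4)))
        truth_sets = {
            gn: {t for t in terms if rng.random() < 0.4} | {"R"} for gn in genes
        }
        truth = store_from(truth_sets)
        theta = 0.5
        pred_sets = {
            gn: {t for j, t in enumerate(terms) if scores.scores[i, j] >= theta}
            for i, gn in enumerate(genes)
        }
        tp = sum(
            len((pred_sets[gn] | {"R"}) & truth_sets[gn]) for gn in genes
        )
        fp = sum(
            len((pred_sets[gn] | {"R"}) - truth_sets[gn]) for gn in genes
        )
        fn = sum(
            len(truth_sets[gn] - (pred_sets[gn] | {"R"})) for gn in genes
        )
        hprec, hrec, _ = hierarchical_prf(truth, scores, theta, g)
        assert hprec == pytest.approx(tp / (tp + fp))
        assert hrec == pytest.approx(tp / (tp + fn))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_set_arithmetic_oracle(self, seed):
        rng = random.Random(seed)
        graph = random_dag(rng, rng.randint(4, 15))
        root = graph.roots["BP"]
        terms = sorted(t for t in graph.terms if t != root)
        genes = [f"g{i}" for i in range(rng.randint(2, 20))]
        np_rng = np.random.default_rng(seed)
        scores = ScoreMatrix(genes, terms, np_rng.random((len(genes), len(terms))))
        truth_sets = {
            g: {t for t in terms if np_rng.random() < 0.3} for g in genes
        }
        truth = store_from({g: ts | ({root} if ts else set())
                            for g, ts in truth_sets.items()})
        for theta in (0.0, 0.3, 0.7, 1.0):
            pred = {
                g: {t for j, t in enumerate(terms)
                    if scores.scores[i, j] >= theta}
                for i, g in enumerate(genes)
            }
            want = brute_hierarchical_prf(truth.assoc, pred, root)
            got = hierarchical_prf(truth, scores, theta, graph)
            assert got == pytest.approx(want, abs=1e-12)


class TestCurves:
    def _setup(self, chain_graph):
        truth = store_from({"g1": {"R", "A"}, "g2": {"R", "A", "B"}})
        scores = ScoreMatrix(
            ["g1", "g2"], ["A", "B"], np.array([[0.6, 0.2], [0.8, 0.7]])
        )
        return truth, scores

    def test_constant_scores_give_two_regimes(self, chain_graph):
        truth, _ = self._setup(chain_graph)
        scores = ScoreMatrix(["g1", "g2"], ["A", "B"], np.full((2, 2), 0.5))
        curve = hf_curve(truth, scores, chain_graph)
        assert len(set(np.round(curve.hf1, 12))) == 2

    def test_hf_max_dominates_curve(self, chain_graph):
        truth, scores = self._setup(chain_graph)
        curve = hf_curve(truth, scores, chain_graph)
        assert np.all(curve.hf_max >= curve.hf1)

    def test_hrec_non_increasing(self, chain_graph):
        truth, scores = self._setup(chain_graph)
        curve = hf_curve(truth, scores, chain_graph)
        assert np.all(np.diff(curve.hrec) <= 1e-15)

    def test_curve_matches_pointwise_recomputation(self, chain_graph):
        truth, scores = self._setup(chain_graph)
        grid = (0.0, 0.25, 0.5, 0.75, 1.0)
        curve = hf_curve(truth, scores, chain_graph, grid)
        for i, theta in enumerate(grid):
            _, _, hf1 = hierarchical_prf(truth, scores, theta, chain_graph)
            assert curve.hf1[i] == pytest.approx(hf1, abs=1e-12)

    def test_empty_grid_rejected(self, chain_graph):
        truth, scores = self._setup(chain_graph)
        with pytest.raises(EvaluationError):
            hf_curve(truth, scores, chain_graph, ())


class TestRandomModel:
    def test_quarter_frequency_scores_every_gene_quarter(self):
        store = store_from(
            {f"g{i}": ({"A"} if i < 25 else set()) for i in range(100)}
        )
        sm = random_scores(store, ["e1", "e2", "e3"], ["A"])
        assert np.all(sm.scores == 0.25)

    def test_absent_term_scores_zero(self):
        store = store_from({"g1": {"A"}, "g2": set()})
        sm = random_scores(store, ["e1"], ["Z"])
        assert np.all(sm.scores == 0.0)

    def test_columns_constant_across_genes(self):
        store = store_from(
            {f"g{i}": {"A"} if i % 3 == 0 else {"B"} for i in range(30)}
        )
        sm = random_scores(store, [f"e{i}" for i in range(5)], ["A", "B"])
        assert np.all(sm.scores == sm.scores[0])


class TestRatio:
    def _curve(self, chain_graph, scale=1.0):
        from funcland.evaluation import EvalCurve

        thetas = np.array([0.0, 0.5, 1.0])
        hf1 = np.array([0.4, 0.6, 0.0]) * scale
        return EvalCurve(thetas, hf1, hf1, hf1)

    def test_identical_curves_ratio_one(self, chain_graph):
        a = self._curve(chain_graph)
        ratios, theta_star, best = ratio_curve(a, a)
        defined = ~np.isnan(ratios)
        assert np.allclose(ratios[defined], 1.0)
        assert best == 1.0
        assert theta_star == 0.0  # smallest argmax on ties

    def test_doubled_curve_ratio_two(self, chain_graph):
        num = self._curve(chain_graph, 2.0)
        den = self._curve(chain_graph, 1.0)
        ratios, theta_star, best = ratio_curve(num, den)
        assert best == pytest.approx(2.0)
        assert theta_star == 0.0

    def test_zero_null_points_excluded_not_infinite(self, chain_graph):
        num = self._curve(chain_graph)
        den = self._curve(chain_graph)
        ratios, _, best = ratio_curve(num, den)
        assert np.isnan(ratios[-1])  # theta=1 has null hF1 = 0
        assert np.isfinite(best)


class TestFinalize:
    def test_most_specific_kept_per_branch(self, chain_graph):
        sm = ScoreMatrix(["g"], ["A", "B"], np.array([[0.9, 0.8]]))
        preds = finalize_predictions(sm, 0.5, chain_graph)
        assert [(r.gene, r.term) for r in preds.records] == [("g", "B")]
        assert preds.records[0].depth == 2

    def test_two_branches_both_kept(self, tree_graph):
        sm = ScoreMatrix(["g"], ["B", "D"], np.array([[0.9, 0.8]]))
        preds = finalize_predictions(sm, 0.5, tree_graph)
        assert {r.term for r in preds.records} == {"B", "D"}

    def test_threshold_above_all_scores_empty(self, chain_graph):
        sm = ScoreMatrix(["g"], ["A", "B"], np.array([[0.9, 0.8]]))
        preds = finalize_predictions(sm, 0.95, chain_graph)
        assert preds.records == []

    def test_known_training_annotations_filtered(self, chain_graph):
        sm = ScoreMatrix(["g"], ["A", "B"], np.array([[0.9, 0.2]]))
        known = store_from({"g": {"A", "R"}})
        preds = finalize_predictions(sm, 0.5, chain_graph, known)
        assert preds.records == []

    @pytest.mark.parametrize("seed", range(6))
    def test_output_is_an_antichain(self, seed):
        from funcland import relatives

        rng = random.Random(seed)
        graph = random_dag(rng, 12)
        root = graph.roots["BP"]
        terms = sorted(t for t in graph.terms if t != root)
        np_rng = np.random.default_rng(seed)
        sm = ScoreMatrix(
            [f"g{i}" for i in range(5)], terms,
            np_rng.random((5, len(terms)))
        )
        preds = finalize_predictions(sm, 0.4, graph)
        per_gene: dict[str, set[str]] = {}
        for r in preds.records:
            per_gene.setdefault(r.gene, set()).add(r.term)
        for g, ts in per_gene.items():
            for t in ts:
                assert not (relatives(graph, t, "ancestors") & ts)


class TestDepthHistogram:
    def test_counts_and_zero_fill(self, chain_graph):
        sm = ScoreMatrix(
            ["g1", "g2"], ["A", "B"], np.array([[0.9, 0.1], [0.9, 0.9]])
        )
        preds = finalize_predictions(sm, 0.5, chain_graph)
        hist = predictions_by_depth(preds, chain_graph)
        assert hist == {0: 0, 1: 1, 2: 1}

    def test_total_equals_record_count(self, tree_graph):
        sm = ScoreMatrix(["g"], ["B", "D"], np.array([[0.9, 0.8]]))
        preds = finalize_predictions(sm, 0.5, tree_graph)
        hist = predictions_by_depth(preds, tree_graph)
        assert sum(hist.values()) == len(preds.records)

    def test_empty_predictions_all_zero(self, chain_graph):
        sm = ScoreMatrix(["g"], ["A"], np.array([[0.1]]))
        preds = finalize_predictions(sm, 0.9, chain_graph)
        hist = predictions_by_depth(preds, chain_graph)
        assert set(hist.values()) == {0}
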
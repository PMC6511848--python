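"""Functional-similarity metrics, matching and multi-species prediction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from munk.embedding import CrossSpeciesScores
from munk.function_eval import (
    SimplexWeights,
    aupr,
    goc,
    hungarian_match,
    kfs_labels,
    max_f1,
    max_f1_over_terms,
    multispecies_predict,
    resnik_protein,
    simplex_grid,
)
from munk.graph_io import OntologyAnnotation
from munk.kernels import KernelMatrix


def scores_of(v, src=None, tgt=None):
    v = np.asarray(v, dtype=float)
    src = src or tuple(f"s{i}" for i in range(v.shape[0]))
    tgt = tgt or tuple(f"t{j}" for j in range(v.shape[1]))
    return CrossSpeciesScores(tuple(src), tuple(tgt), v)


# ---------------------------------------------------------------- Resnik


def toy_ontology():
    dag = nx.MultiDiGraph()
    dag.add_edge("rare", "mid", relation="is_a")
    dag.add_edge("mid", "root", relation="is_a")
    return dag


class TestResnik:
    def test_root_only_shared_scores_zero(self):
        dag = toy_ontology()
        corpus = {f"g{i}": {"root"} for i in range(8)}
        corpus["g0"] |= {"mid", "rare"}
        ann = OntologyAnnotation(dag, {"s": corpus})
        assert resnik_protein(ann, corpus, "g1", "g2") == 0.0

    def test_shared_rare_term(self):
        dag = toy_ontology()
        corpus = {f"g{i}": {"root"} for i in range(8)}
        corpus["g0"] = {"root", "mid"}
        corpus["g1"] = {"root", "mid"}
        ann = OntologyAnnotation(dag, {"s": corpus})
        # "mid" annotates 2 of 8 genes: IC = -ln(0.25)
        assert resnik_protein(ann, corpus, "g0", "g1") == pytest.approx(-math.log(0.25))

    def test_identical_single_term_genes(self):
        dag = toy_ontology()
        corpus = {"g0": {"rare"}, "g1": {"rare"}, "g2": {"root"}, "g3": {"root"}}
        ann = OntologyAnnotation(dag, {"s": corpus})
        assert resnik_protein(ann, corpus, "g0", "g1") == pytest.approx(-math.log(0.5))

    def test_unannotated_gene_undefined(self):
        dag = toy_ontology()
        corpus = {"g0": {"root"}}
        ann = OntologyAnnotation(dag, {"s": corpus})
        assert resnik_protein(ann, corpus, "g0", "missing") is None

    def test_symmetric_and_nonnegative(self):
        dag = toy_ontology()
        corpus = {"g0": {"rare", "mid"}, "g1": {"mid", "root"}, "g2": {"root"}}
        ann = OntologyAnnotation(dag, {"s": corpus})
        for a, b in itertools.combinations(corpus, 2):
            s_ab = resnik_protein(ann, corpus, a, b)
            assert s_ab == resnik_protein(ann, corpus, b, a)
            assert s_ab >= 0


# ---------------------------------------------------------------- Hungarian


def brute_force_best_matching(v):
    m, n = v.shape
    assert m <= n
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(n), m):
        s = sum(v[i, j] for i, j in enumerate(perm))
        if s > best_score:
            best, best_score = perm, s
    return best_score


class TestHungarian:
    def test_two_by_two(self):
        match = hungarian_match(scores_of([[2, 1], [1, 2]]))
        assert match.as_dict == {"s0": "t0", "s1": "t1"}

    def test_diagonal_dominant(self):
        v = np.eye(4) * 10 + np.random.default_rng(0).uniform(size=(4, 4))
        match = hungarian_match(scores_of(v))
        assert match.as_dict == {f"s{i}": f"t{i}" for i in range(4)}

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        n = int(rng.integers(m, 6))
        v = rng.normal(size=(m, n))
        match = hungarian_match(scores_of(v))
        total = sum(
            v[int(s[1:]), int(t[1:])] for s, t in match.pairs
        )
        assert total == pytest.approx(brute_force_best_matching(v))

    def test_wide_and_tall_orientations_agree(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(3, 5))
        wide = hungarian_match(scores_of(v))
        tall = hungarian_match(
            CrossSpeciesScores(
                tuple(f"s{i}" for i in range(5)), tuple(f"t{j}" for j in range(3)), v.T
            )
        )
        assert len(wide) == len(tall) == 3


# ---------------------------------------------------------------- GOC / kFS


class TestGOC:
    def test_identical_sets(self):
        match = hungarian_match(scores_of(np.eye(2) + 1e-3))
        ann = {"s0": {"a"}, "s1": {"b"}}
        tgt = {"t0": {"a"}, "t1": {"b"}}
        assert goc(match, ann, tgt) == 1.0

    def test_disjoint_sets(self):
        match = hungarian_match(scores_of(np.eye(2) + 1e-3))
        assert goc(match, {"s0": {"a"}, "s1": {"b"}}, {"t0": {"x"}, "t1": {"y"}}) == 0.0

    def test_jaccard_third(self):
        match = hungarian_match(scores_of(np.array([[1.0]])))
        assert goc(match, {"s0": {"a", "b"}}, {"t0": {"b", "c"}}) == pytest.approx(1 / 3)

    def test_both_empty_excluded_one_empty_zero(self):
        match = hungarian_match(scores_of(np.eye(2) + 1e-3))
        # s0/t0 both empty -> excluded; s1 empty vs t1 nonempty -> 0
        assert goc(match, {"s1": set()}, {"t1": {"x"}}) == 0.0


class TestKFS:
    def test_rare_shared_term(self):
        ann1 = {"a1": {"T"}, "a2": {"T"}}
        ann2 = {"b1": {"T"}, "b2": {"T"}}
        labels = kfs_labels(ann1, ann2, k=100)
        assert labels[("a1", "b1")] == 1

    def test_threshold_edge(self):
        k = 3
        ann1 = {f"a{i}": {"T"} for i in range(k + 1)}  # T annotates k+1 genes
        ann2 = {"b1": {"T"}}
        labels = kfs_labels(ann1, ann2, k=k)
        assert all(v == 0 for v in labels.values())

    def test_exhaustive_toy_corpus(self):
        ann1 = {"a1": {"X"}, "a2": {"X", "Y"}, "a3": {"Y"}}
        ann2 = {"b1": {"X"}, "b2": {"Y"}, "b3": {"Z"}}
        labels = kfs_labels(ann1, ann2, k=2)
        expected = {
            ("a1", "b1"): 1, ("a1", "b2"): 0, ("a1", "b3"): 0,
            ("a2", "b1"): 1, ("a2", "b2"): 1, ("a2", "b3"): 0,
            ("a3", "b1"): 0, ("a3", "b2"): 1, ("a3", "b3"): 0,
        }
        assert labels == expected


# ---------------------------------------------------------------- AUPR / F1


def sweep_aupr_oracle(scores, labels):
    """Average precision by explicit threshold sweep over distinct scores."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    total_pos = labels.sum()
    thresholds = np.unique(scores)[::-1]
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        sel = scores >= t
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / total_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def sweep_max_f1_oracle(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    best = 0.0
    for t in np.unique(scores):
        sel = scores >= t
        tp = labels[sel].sum()
        if tp == 0:
            continue
        p, r = tp / sel.sum(), tp / labels.sum()
        best = max(best, 2 * p * r / (p + r))
    return best


class TestRankingMetrics:
    def test_perfect_ranking(self):
        assert aupr([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        assert aupr([4, 3, 2, 1], [0, 0, 0, 1]) == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            aupr([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(15))
    def test_aupr_matches_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = rng.choice(np.round(rng.uniform(size=8), 3), size=n)  # ties likely
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert aupr(scores, labels) == pytest.approx(sweep_aupr_oracle(scores, labels))

    def test_max_f1_hand_case(self):
        # 1 true gene ranked 2nd of 3
        assert max_f1([3, 2, 1], [0, 1, 0]) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(15))
    def test_max_f1_matches_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = rng.choice(np.round(rng.uniform(size=6), 3), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert max_f1(scores, labels) == pytest.approx(sweep_max_f1_oracle(scores, labels))

    def test_max_f1_over_terms_perfect_and_mean(self):
        preds = {
            "t1": [("g1", 3.0), ("g2", 2.0), ("g3", 1.0)],
            "t2": [("g1", 3.0), ("g2", 2.0), ("g3", 1.0)],
        }
        truth = {"t1": {"g1"}, "t2": {"g2"}}
        # t1 perfect (1.0), t2 max F1 = 2/3
        assert max_f1_over_terms(preds, truth) == pytest.approx((1.0 + 2 / 3) / 2)


# ---------------------------------------------------------------- prediction


class TestMultispeciesPredict:
    def make_kernel(self):
        nodes = ("g1", "g2", "g3", "g4")
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 4))
        return KernelMatrix(nodes, m @ m.T, 1.0)

    def test_corner_reduces_to_single_species(self):
        k = self.make_kernel()
        cross = CrossSpeciesScores(k.node_index, ("h1", "h2"),
                                   np.random.default_rng(1).normal(size=(4, 2)))
        ann_self = {"g1": {"T"}, "g2": {"T"}, "g3": set(), "g4": set()}
        ann_other = {"h1": {"T"}, "h2": {"T"}}
        corner = multispecies_predict(
            k, [cross], SimplexWeights((1.0, 0.0)), [ann_self, ann_other], "T"
        )
        pos = {v: i for i, v in enumerate(k.node_index)}
        for gene, score in corner:
            expected = k.values[pos[gene], pos["g1"]] + k.values[pos[gene], pos["g2"]]
            assert score == pytest.approx(expected)
        # candidates exclude the seed genes
        assert {"g1", "g2"}.isdisjoint({g for g, _ in corner})

    def test_occurrence_band_skips(self):
        k = self.make_kernel()
        cross = CrossSpeciesScores(k.node_index, ("h1",), np.zeros((4, 1)))
        ann_self = {"g1": {"T"}}  # occurs once < 2
        assert multispecies_predict(
            k, [cross], SimplexWeights((0.5, 0.5)), [ann_self, {}], "T"
        ) is None

    def test_simplex_grid_quarter_step_has_15_points(self):
        grid = simplex_grid(3, 0.25)
        assert len(grid) == 15
        for w in grid:
            assert sum(w.alpha) == pytest.approx(1.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SimplexWeights((0.5, 0.6))
        with pytest.raises(ValueError):
            SimplexWeights((-0.1, 1.1))
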
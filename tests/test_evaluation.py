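"""Ranking metrics, method-overlap statistics and the network-proximity baseline."""

import itertools

import networkx as nx
import numpy as np
import pytest

from herbnet.evaluation import (
    GoldStandard,
    UndefinedMetricError,
    aupr,
    auroc,
    averaged_metrics,
    f1_scan,
    precision_recall,
    rank_correlation,
    read_gold_standard,
    target_closeness,
    top_fraction_tanimoto,
)


def auroc_oracle(scores, positives):
    """Brute-force concordant-pair counting with half-credit ties."""
    pos = [scores[i] for i in scores if i in positives]
    neg = [scores[i] for i in scores if i not in positives]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def aupr_oracle(scores, positives):
    """Step integral of the PR curve over the deterministic ranking."""
    order = sorted(scores, key=lambda i: (-scores[i], i))
    n_pos = len(positives & set(scores))
    tp = 0
    area = 0.0
    prev_recall = 0.0
    for k, item in enumerate(order, start=1):
        if item in positives:
            tp += 1
        recall = tp / n_pos
        area += (recall - prev_recall) * (tp / k)
        prev_recall = recall
    return area


class TestPrecisionRecall:
    def test_plain_counts(self):
        uni = set(range(10))
        p, r = precision_recall({1, 2, 3, 4}, {1, 2, 3, 9}, uni)
        assert p == 0.75 and r == 0.75

    def test_perfect_prediction(self):
        uni = set(range(5))
        assert precision_recall({1, 2}, {1, 2}, uni) == (1.0, 1.0)

    def test_empty_prediction_degenerates_to_zero(self):
        p, r = precision_recall(set(), {1}, {1, 2})
        assert p == 0.0 and r == 0.0

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            precision_recall({99}, {1}, {1, 2})


class TestAuroc:
    def test_perfect_and_reversed(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        assert auroc(scores, {"a", "b"}) == 1.0
        assert auroc(scores, {"c", "d"}) == 0.0

    def test_interleaved_hand_case(self):
        scores = {"p1": 0.9, "p2": 0.4, "n1": 0.8, "n2": 0.1}
        assert auroc(scores, {"p1", "p2"}) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc({"a": 1.0, "b": 0.5}, {"a", "b"})

    @pytest.mark.parametrize("n_items", [4, 8, 12])
    def test_matches_pair_counting_oracle_with_ties(self, n_items):
        rng = np.random.default_rng(n_items)
        items = [f"i{k}" for k in range(n_items)]
        for _ in range(30):
            scores = {i: float(rng.integers(0, 4)) / 4 for i in items}  # forces ties
            n_pos = int(rng.integers(1, n_items))
            positives = set(rng.choice(items, size=n_pos, replace=False))
            if len(positives) == n_items:
                continue
            assert auroc(scores, positives) == pytest.approx(auroc_oracle(scores, positives))


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr({"a": 0.9, "b": 0.1}, {"a"}) == 1.0

    def test_single_positive_ranked_last(self):
        assert aupr({"a": 0.9, "b": 0.1}, {"b"}) == 0.5

    def test_no_positive_rejected(self):
        with pytest.raises(UndefinedMetricError):
            aupr({"a": 1.0}, set())

    @pytest.mark.parametrize("n_items", [5, 9, 12])
    def test_matches_step_integral_oracle(self, n_items):
        rng = np.random.default_rng(n_items + 50)
        items = [f"i{k}" for k in range(n_items)]
        for _ in range(30):
            scores = {i: round(float(rng.random()), 2) for i in items}
            n_pos = int(rng.integers(1, n_items + 1))
            positives = set(rng.choice(items, size=n_pos, replace=False))
            assert aupr(scores, positives) == pytest.approx(aupr_oracle(scores, positives))

    def test_random_ranking_converges_to_prevalence(self):
        rng = np.random.default_rng(0)
        items = [f"i{k}" for k in range(200)]
        positives = set(items[:50])  # prevalence 0.25
        vals = []
        for _ in range(30):
            scores = {i: float(rng.random()) for i in items}
            vals.append(aupr(scores, positives))
        assert np.mean(vals) == pytest.approx(0.25, abs=0.05)


class TestAveragedMetrics:
    def _fixture(self):
        import pandas as pd

        predictions = {
            "cmpd1": pd.Series({"ph1": 0.9, "ph2": 0.1, "ph3": 0.5}),
            "cmpd2": pd.Series({"ph1": 0.2, "ph2": 0.8, "ph3": 0.5}),
            "cmpd3": pd.Series({"ph1": 0.5, "ph2": 0.5, "ph3": 0.5}),
        }
        gold = GoldStandard(
            frozenset(
                {
                    ("cmpd1", "ph1", "therapeutic"),
                    ("cmpd2", "ph1", "therapeutic"),
                    ("cmpd3", "ph2", "candidate"),
                }
            )
        )
        return predictions, gold

    def test_mean_over_compounds(self):
        predictions, gold = self._fixture()
        rep = averaged_metrics(predictions, gold, axis="compound")
        # cmpd1 ranks ph1 top (AUROC 1), cmpd2 bottom (0), cmpd3 all tied (0.5)
        assert rep["auroc_mean"] == pytest.approx(0.5)
        assert rep["n_units"] == 3

    def test_phenotype_axis_ranks_compounds(self):
        predictions, gold = self._fixture()
        rep = averaged_metrics(predictions, gold, axis="phenotype")
        assert rep["n_units"] == 2  # ph3 has no positives
        assert rep["n_skipped"] == 1
        # ph1 ranks cmpd1 (0.9) and cmpd2 (0.2) against cmpd3 (0.5) -> AUROC 0.5
        # ph2 ranks cmpd3 (0.5) against 0.1 and 0.8 -> AUROC 0.5
        assert rep["auroc_mean"] == pytest.approx(0.5)

    def test_label_filter_restricts_positives(self):
        predictions, gold = self._fixture()
        rep = averaged_metrics(predictions, gold, axis="compound", label="therapeutic")
        assert rep["n_units"] == 2

    def test_no_evaluable_units_raises(self):
        predictions, _ = self._fixture()
        empty = GoldStandard(frozenset())
        with pytest.raises(UndefinedMetricError):
            averaged_metrics(predictions, empty, axis="compound")


class TestF1Scan:
    def test_separable_scores_reach_f1_one(self):
        pairs = {("c", f"p{i}"): 0.9 for i in range(3)}
        pairs.update({("c", f"n{i}"): 0.1 for i in range(3)})
        positives = {("c", f"p{i}") for i in range(3)}
        best, curve = f1_scan(pairs, positives)
        assert curve[best] == pytest.approx(1.0)
        assert 0.1 < best <= 0.9

    def test_tie_goes_to_smaller_threshold(self):
        pairs = {("c", "p"): 0.9}
        best, curve = f1_scan(pairs, {("c", "p")})
        assert best == 0.0  # F1=1 for every threshold <= 0.9


class TestOverlapStats:
    def test_rank_correlation_extremes(self):
        a = {"x": 3.0, "y": 2.0, "z": 1.0}
        assert rank_correlation(a, a) == pytest.approx(1.0)
        b = {"x": 1.0, "y": 2.0, "z": 3.0}
        assert rank_correlation(a, b) == pytest.approx(-1.0)

    def test_spearman_hand_case(self):
        a = {"i1": 4.0, "i2": 3.0, "i3": 2.0, "i4": 1.0}  # ranks 1,2,3,4
        b = {"i1": 3.0, "i2": 4.0, "i3": 1.0, "i4": 2.0}  # ranks 2,1,4,3
        assert rank_correlation(a, b) == pytest.approx(0.6)

    def test_too_few_shared_items(self):
        with pytest.raises(UndefinedMetricError):
            rank_correlation({"x": 1.0}, {"x": 2.0})

    def test_tanimoto_identical_and_disjoint(self):
        n = 20
        a = {f"i{k}": float(k) for k in range(n)}
        assert top_fraction_tanimoto(a, a, 0.10) == 1.0
        b = {f"i{k}": float(-k) for k in range(n)}
        assert top_fraction_tanimoto(a, b, 0.10) == 0.0

    def test_tanimoto_partial_overlap(self):
        scores_a = {"a": 9, "b": 8, "c": 7, "d": 1, "e": 1, "x": 0, "y": 0, "z": 0, "w": 0, "v": 0}
        scores_b = {"b": 9, "c": 8, "d": 7, "a": 1, "e": 1, "x": 0, "y": 0, "z": 0, "w": 0, "v": 0}
        assert top_fraction_tanimoto(scores_a, scores_b, 0.3) == pytest.approx(0.5)


class TestTargetCloseness:
    def test_coincident_sets_have_zero_distance(self):
        g = nx.path_graph(5)
        d, _ = target_closeness({0, 1}, {0, 1}, g, n_perm=10, seed=0)
        assert d == 0.0

    def test_path_graph_distance(self):
        g = nx.path_graph(3)  # 0 - 1 - 2
        d, _ = target_closeness({0}, {2}, g, n_perm=10, seed=0)
        assert d == 2.0

    def test_permutation_p_small_for_best_configuration(self):
        g = nx.path_graph(10)
        d, p = target_closeness({4}, {4}, g, n_perm=200, seed=1)
        assert d == 0.0
        assert p <= 0.2  # only draws hitting distance 0 count

    def test_unmappable_sets_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            target_closeness({99}, {0}, g, n_perm=5, seed=0)


def test_gold_standard_tsv_reader(tmp_path):
    path = tmp_path / "gold.tsv"
    path.write_text("cmpd1\tph1\ttherapeutic\ncmpd1\tph2\tcandidate\n")
    gold = read_gold_standard(path)
    assert gold.positives() == {("cmpd1", "ph1"), ("cmpd1", "ph2")}
    assert gold.positives("therapeutic") == {("cmpd1", "ph1")}
    bad = tmp_path / "bad.tsv"
    bad.write_text("c\tp\tweird\n")
    with pytest.raises(ValueError):
        read_gold_standard(bad)
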
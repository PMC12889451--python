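import math

import numpy as np
import pytest

from drugsig import (
    IndicationMapping,
    SimilarityRanking,
    all_rankings,
    average_indication_accuracy,
    hypergeometric_control,
    hypergeometric_expected_ia,
    indication_accuracy,
    leave_one_out_consensus,
    ndcg_at_k,
    new_indication_accuracy,
    new_ndcg_at_k,
    random_matrix_control,
    run_benchmark,
)
from drugsig.synthdata import SynthConfig, generate_study
from conftest import random_grid_matrix


def mk_rankings(lists: dict[str, list[str]]) -> dict[str, SimilarityRanking]:
    """Hand-built rankings; distances are just increasing with position."""
    return {
        q: SimilarityRanking(q, [(cid, 0.1 * (i + 1)) for i, cid in enumerate(ids)])
        for q, ids in lists.items()
    }


class TestIndicationAccuracy:
    def test_mutual_nearest_neighbors(self):
        rankings = mk_rankings({"A": ["B", "X"], "B": ["A", "X"], "X": ["A", "B"]})
        mapping = IndicationMapping([("I", "A"), ("I", "B")])
        assert indication_accuracy(rankings, mapping, "I", 10) == 100.0

    def test_partners_beyond_cutoff(self):
        rankings = mk_rankings({"A": ["X", "Y", "B"], "B": ["X", "Y", "A"]})
        mapping = IndicationMapping([("I", "A"), ("I", "B")])
        assert indication_accuracy(rankings, mapping, "I", 2) == 0.0

    def test_three_drug_toy(self):
        # exactly two of the three lists recover a partner within the top 2
        rankings = mk_rankings(
            {
                "A": ["B", "X", "Y", "C"],
                "B": ["X", "A", "Y", "C"],
                "C": ["X", "Y", "A", "B"],
            }
        )
        mapping = IndicationMapping([("I", "A"), ("I", "B"), ("I", "C")])
        assert indication_accuracy(rankings, mapping, "I", 2) == pytest.approx(200 / 3)

    def test_single_drug_indication_rejected(self):
        rankings = mk_rankings({"A": ["X"], "X": ["A"]})
        mapping = IndicationMapping([("I", "A")])
        with pytest.raises(ValueError):
            indication_accuracy(rankings, mapping, "I", 5)


class TestAverageIndicationAccuracy:
    def test_mean_of_one(self):
        rankings = mk_rankings({"A": ["B", "X"], "B": ["A", "X"], "X": ["A", "B"]})
        mapping = IndicationMapping([("I", "A"), ("I", "B")])
        assert average_indication_accuracy(rankings, mapping, 10) == indication_accuracy(
            rankings, mapping, "I", 10
        )

    def test_arithmetic_mean(self):
        rankings = mk_rankings(
            {
                "A": ["B", "C", "D"],
                "B": ["A", "C", "D"],
                "C": ["A", "B", "D"],
                "D": ["A", "B", "C"],
            }
        )
        mapping = IndicationMapping(
            [("I1", "A"), ("I1", "B"), ("I2", "C"), ("I2", "D")]
        )
        # I1 drugs are mutually first (IA 100); I2 drugs never see each other in top-1
        assert average_indication_accuracy(rankings, mapping, 1) == 50.0

    def test_matches_per_indication_recount(self):
        rng = np.random.default_rng(11)
        matrix = random_grid_matrix(rng, 12, 6)
        rankings = all_rankings(matrix)
        ids = matrix.compound_ids
        mapping = IndicationMapping(
            [(f"I{j}", ids[2 * j + d]) for j in range(5) for d in range(2)]
        )
        for k in (1, 3, 5):
            expected = np.mean(
                [indication_accuracy(rankings, mapping, f"I{j}", k) for j in range(5)]
            )
            assert average_indication_accuracy(rankings, mapping, k) == pytest.approx(expected)


class TestNewIndicationAccuracy:
    def test_direct_recovery(self):
        rankings = mk_rankings({"A": ["B", "X"], "B": ["A", "X"], "X": ["A", "B"]})
        mapping = IndicationMapping([("I", "A"), ("I", "B")])
        assert new_indication_accuracy(rankings, mapping, "I", 1) == 100.0

    def test_withheld_absent_from_all_windows(self):
        rankings = mk_rankings(
            {"A": ["X", "Y", "B"], "B": ["X", "Y", "A"], "X": ["A", "B", "Y"], "Y": ["A", "B", "X"]}
        )
        mapping = IndicationMapping([("I", "A"), ("I", "B")])
        # with cutoff 2 the partners' windows never contain the withheld drug
        assert new_indication_accuracy(rankings, mapping, "I", 10, cutoff=2) == 0.0

    def test_three_drug_toy_matches_hand_enumeration(self):
        rankings = mk_rankings(
            {
                "A": ["B", "C", "X"],
                "B": ["C", "A", "X"],
                "C": ["X", "A", "B"],
            }
        )
        mapping = IndicationMapping([("I", "A"), ("I", "B"), ("I", "C")])
        # cutoff 2 windows: A->{B,C}, B->{C,A}, C->{X,A}
        # withhold A: consensus from B,C counts: C:1(B@0), A:2(B@1,C@1), X:1(C@0)
        #   -> order A(2,avg1), C(1,avg0), X(1,avg0 tie by id C<X): A at position 0 -> hit
        # withhold B: consensus from A,C: B:1@0, C:1@1, X:1@0, A:1@1
        #   -> order by avg then id: B(0), X(0), A(1), C(1) -> B at 0 -> hit at k>=1
        # withhold C: consensus from A,B: B:1@0, C:2@(1,0)->avg0.5, A:1@1
        #   -> C(2), B(1,0), A(1,1) -> C at 0 -> hit
        assert new_indication_accuracy(rankings, mapping, "I", 1, cutoff=2) == 100.0
        loo = leave_one_out_consensus(rankings, ["A", "B", "C"], cutoff=2)
        assert loo["A"] == ["A", "C", "X"]
        assert loo["B"] == ["B", "X", "A", "C"]
        assert loo["C"] == ["C", "B", "A"]


class TestNdcg:
    def test_perfect_ranking(self):
        r = SimilarityRanking("q", [("R", 0.1), ("X", 0.2)])
        assert ndcg_at_k(r, {"R"}, 1) == 1.0

    def test_zero_gain(self):
        r = SimilarityRanking("q", [("X", 0.1), ("Y", 0.2), ("R", 0.3)])
        assert ndcg_at_k(r, {"R"}, 2) == 0.0

    def test_hand_discount(self):
        r = SimilarityRanking("q", [("X", 0.1), ("R", 0.2)])
        assert ndcg_at_k(r, {"R"}, 2) == pytest.approx(1 / math.log2(3))

    def test_empty_relevant_rejected(self):
        r = SimilarityRanking("q", [("X", 0.1)])
        with pytest.raises(ValueError):
            ndcg_at_k(r, set(), 1)


class TestNewNdcg:
    def test_ideal(self):
        loo = {"A": ["A", "X"], "B": ["B", "Y"]}
        assert new_ndcg_at_k(loo, 10) == pytest.approx(1.0)

    def test_zero(self):
        loo = {"A": ["X", "Y"], "B": ["X", "Y"]}
        assert new_ndcg_at_k(loo, 10) == 0.0

    def test_hand_value_one_recovery_one_miss(self):
        loo = {"A": ["X", "A"], "B": ["X", "Y"]}
        expected = (1 / math.log2(3)) / (1 + 1 / math.log2(3))
        assert new_ndcg_at_k(loo, 10) == pytest.approx(expected)

    def test_bounded_by_one_under_position_collisions(self):
        # three withheld drugs all recovered first in their own lists
        loo = {d: [d, "X"] for d in "ABC"}
        assert new_ndcg_at_k(loo, 10) == pytest.approx(1.0)


class TestHypergeometricControl:
    def test_cutoff_spans_whole_list(self):
        assert hypergeometric_expected_ia(50, 5, 49) == 100.0

    def test_hand_value(self):
        assert hypergeometric_expected_ia(101, 2, 10) == pytest.approx(10.0)

    def test_all_relevant(self):
        assert hypergeometric_expected_ia(30, 30, 1) == 100.0

    @pytest.mark.parametrize("N,n,k", [(10, 1, 5), (10, 11, 5), (10, 5, 0), (10, 5, 10)])
    def test_bounds(self, N, n, k):
        with pytest.raises(ValueError):
            hypergeometric_expected_ia(N, n, k)


class TestMetricProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_metrics_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_grid_matrix(rng, 12, 8)
        rankings = all_rankings(matrix)
        ids = matrix.compound_ids
        mapping = IndicationMapping(
            [("I1", ids[0]), ("I1", ids[1]), ("I1", ids[2]), ("I2", ids[3]), ("I2", ids[4])]
        )
        cutoffs = [1, 2, 4, 8, 11]
        report = run_benchmark(rankings, mapping, cutoffs, consensus_cutoff=4)
        for metric_values in list(report.per_indication.values()) + [report.averages]:
            for by_k in metric_values.values():
                values = [by_k[k] for k in cutoffs]
                assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_averages_are_means(self, fixture_rankings, fixture_study):
        report = run_benchmark(fixture_rankings, fixture_study.mapping, [2, 5])
        for metric, avg_name in [("IA", "AIA"), ("nIA", "nAIA"), ("NDCG", "NDCG"), ("nNDCG", "nNDCG")]:
            for k in (2, 5):
                expected = np.mean(
                    [v[metric][k] for v in report.per_indication.values()]
                )
                assert report.averages[avg_name][k] == pytest.approx(expected)

    def test_ndcg_bounded(self, fixture_rankings, fixture_study):
        report = run_benchmark(fixture_rankings, fixture_study.mapping, [1, 3, 7])
        for values in report.per_indication.values():
            for metric in ("NDCG", "nNDCG"):
                assert all(0.0 <= v <= 1.0 + 1e-12 for v in values[metric].values())


class TestRandomMatrixControl:
    def test_same_seed_reproduces(self):
        study = generate_study(
            SynthConfig(n_compounds=30, n_proteins=20, focal_indication_size=6,
                        other_indication_size=3, signal_proteins_per_indication=2,
                        gold_size=5, gold_top_window=10, seed=3)
        )
        kwargs = dict(cutoffs=[5], n_reps=5, seed=42, metrics=("IA", "NDCG"))
        c1 = random_matrix_control(study.matrix, study.mapping, **kwargs)
        c2 = random_matrix_control(study.matrix, study.mapping, **kwargs)
        assert c1.averages == c2.averages
        assert c1.per_indication == c2.per_indication

    def test_hypergeometric_control_shape(self, fixture_rankings, fixture_study):
        control = hypergeometric_control(fixture_rankings, fixture_study.mapping, [2, 5])
        n = fixture_study.matrix.n_compounds
        assert control["per_indication"]["IND_A"][2] == pytest.approx(
            hypergeometric_expected_ia(n, 3, 2)
        )
        assert set(control["averages"]["AIA"]) == {2, 5}
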
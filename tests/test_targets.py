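import numpy as np
import pytest

from drugsig import (
    InteractionMatrix,
    TargetList,
    bin_relative_frequency,
    consensus_targets,
    jaccard_coefficient,
    overlap_analysis,
    overlap_percentage,
    read_gold_standard,
    top_targets,
)
from conftest import random_grid_matrix
from oracles import brute_consensus_targets, brute_top_targets


class TestTopTargets:
    def test_truncation_noop_on_small_proteome(self):
        matrix = InteractionMatrix(["A"], ["P1", "P2", "P3"], [[0.2, 0.9, 0.5]])
        targets = top_targets(matrix, "A", n=100)
        assert [pid for pid, _ in targets.entries] == ["P2", "P3", "P1"]

    def test_score_ties_break_by_protein_id(self):
        matrix = InteractionMatrix(["A"], ["PB", "PA"], [[0.5, 0.5]])
        targets = top_targets(matrix, "A", n=2)
        assert [pid for pid, _ in targets.entries] == ["PA", "PB"]

    def test_unknown_compound(self, fixture_study):
        with pytest.raises(KeyError):
            top_targets(fixture_study.matrix, "nope")

    def test_score_floor(self):
        matrix = InteractionMatrix(["A"], ["P1", "P2"], [[0.9, 0.1]])
        assert len(top_targets(matrix, "A", n=5, score_floor=0.5)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_sort(self, seed):
        rng = np.random.default_rng(300 + seed)
        matrix = random_grid_matrix(rng, 4, int(rng.integers(2, 11)))
        for cid in matrix.compound_ids:
            expected = brute_top_targets(
                matrix.protein_ids, matrix.signature(cid), n=5
            )
            got = top_targets(matrix, cid, n=5).entries
            assert got == expected


class TestConsensusTargets:
    def test_single_drug_degenerate(self, fixture_study):
        rows = consensus_targets(fixture_study.matrix, ["C1"], n=3)
        own = top_targets(fixture_study.matrix, "C1", n=3)
        assert [(r.protein_id, r.consensus_score) for r in rows] == [
            (pid, 1) for pid, _ in own.entries
        ]

    def test_hand_means(self):
        # protein PX sits at positions 2 and 4 with scores 0.7 and 0.6 on two
        # of three lists
        matrix = InteractionMatrix(
            ["A", "B", "C"],
            ["P1", "P2", "PX", "P4", "P5", "P6"],
            [
                [1.0, 0.9, 0.7, 0.65, 0.5, 0.4],   # PX at position 2, score 0.7
                [1.0, 0.9, 0.6, 0.8, 0.7, 0.05],   # PX at position 4, score 0.6
                [1.0, 0.9, 0.0, 0.8, 0.7, 0.6],    # PX outside the top 5
            ],
        )
        rows = consensus_targets(matrix, ["A", "B", "C"], n=5)
        px = next(r for r in rows if r.protein_id == "PX")
        assert px.consensus_score == 2
        assert px.average_rank == pytest.approx(3.0)
        assert px.average_score == pytest.approx(0.65)

    def test_empty_drug_set_rejected(self, fixture_study):
        with pytest.raises(ValueError):
            consensus_targets(fixture_study.matrix, [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(400 + seed)
        matrix = random_grid_matrix(rng, 6, 8)
        drugs = list(rng.choice(matrix.compound_ids, size=3, replace=False))
        got = consensus_targets(matrix, drugs, n=5)
        expected = brute_consensus_targets(
            matrix.protein_ids,
            {d: matrix.signature(d).tolist() for d in drugs},
            n=5,
        )
        assert [
            (r.protein_id, r.consensus_score, pytest.approx(r.average_rank), pytest.approx(r.average_score))
            for r in got
        ] == [(pid, c, pytest.approx(ar), pytest.approx(sc)) for pid, c, ar, sc in expected]


def make_target_list(n=100):
    return TargetList("D", [(f"P{i:03d}", 1.0 - i * 0.005) for i in range(n)])


class TestBinRelativeFrequency:
    def test_single_bin_mass(self):
        targets = make_target_list()
        gold = [f"P{i:03d}" for i in (0, 5, 19)]
        assert bin_relative_frequency(targets, gold).tolist() == [1, 0, 0, 0, 0]

    def test_hand_binning(self):
        targets = make_target_list()
        gold = ["P005", "P025", "P085"]
        np.testing.assert_allclose(
            bin_relative_frequency(targets, gold), [1 / 3, 1 / 3, 0, 0, 1 / 3]
        )

    def test_empty_gold_gives_zero_vector(self, caplog):
        targets = make_target_list()
        assert bin_relative_frequency(targets, []).sum() == 0.0

    def test_sums_to_one_when_any_intersection(self):
        rng = np.random.default_rng(2)
        targets = make_target_list()
        for _ in range(20):
            gold = rng.choice([p for p, _ in targets.entries], size=7, replace=False)
            assert bin_relative_frequency(targets, gold.tolist()).sum() == pytest.approx(1.0)


class TestOverlapPercentage:
    def test_full_coverage(self):
        targets = make_target_list()
        gold = ["P000", "P001"]
        assert overlap_percentage(targets, gold, 10) == 100.0

    def test_disjoint(self):
        targets = make_target_list()
        assert overlap_percentage(targets, ["ZZZ"], 100) == 0.0

    def test_hand_fraction(self):
        targets = make_target_list()
        gold = ["P000", "P001", "P002"] + [f"Z{i}" for i in range(7)]
        assert overlap_percentage(targets, gold, 100) == pytest.approx(30.0)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            overlap_percentage(make_target_list(), [], 10)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        targets = make_target_list()
        gold = rng.choice([p for p, _ in targets.entries], size=10, replace=False).tolist()
        values = [overlap_percentage(targets, gold, k) for k in (10, 20, 50, 100)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestJaccard:
    def test_identity(self):
        targets = TargetList("D", [("P1", 0.9), ("P2", 0.8)])
        assert jaccard_coefficient(targets, ["P1", "P2"], 2) == 1.0

    def test_disjoint(self):
        targets = TargetList("D", [("P1", 0.9)])
        assert jaccard_coefficient(targets, ["P2"], 1) == 0.0

    def test_hand_value(self):
        targets = TargetList("D", [("a", 0.9), ("b", 0.8), ("c", 0.7)])
        assert jaccard_coefficient(targets, ["b", "c", "d"], 3) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard_coefficient(TargetList("D", []), [], 5)

    def test_bounded(self):
        rng = np.random.default_rng(4)
        targets = make_target_list()
        for _ in range(20):
            gold = rng.choice(
                [p for p, _ in targets.entries] + ["X1", "X2"], size=5, replace=False
            ).tolist()
            for k in (10, 50, 100):
                assert 0.0 <= jaccard_coefficient(targets, gold, k) <= 1.0


class TestOverlapAnalysis:
    def test_planted_top20_gold_concentrates_in_first_bin(self):
        rng = np.random.default_rng(5)
        targets = make_target_list()
        gold = rng.choice([f"P{i:03d}" for i in range(20)], size=8, replace=False).tolist()
        result = overlap_analysis(targets, gold)
        assert np.argmax(result.bin_relative_freq) == 0
        assert result.overlap_percent_at[100] == 100.0

    def test_gold_standard_reader(self, tmp_path):
        p = tmp_path / "gold.txt"
        p.write_text("# comment\nP1\nP2  # trailing\n\nP1\nP3\n")
        assert read_gold_standard(p) == ["P1", "P2", "P3"]
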
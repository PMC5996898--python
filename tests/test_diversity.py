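import numpy as np
import pandas as pd
import pytest

from phyllo import (
    diversity_residuals,
    family_variance_ranks,
    group_bias_test,
    median_rank,
)
from phyllo.diversity import DiversityTable
from phyllo.errors import ValidationError


def make_table(counts: dict, ranks: np.ndarray) -> DiversityTable:
    families = list(counts)
    return DiversityTable(
        counts=pd.Series(counts, name="count"),
        variances=pd.DataFrame(
            np.zeros_like(ranks, dtype=float), index=families
        ),
        ranks=pd.DataFrame(ranks, index=families),
    )


def scores_for(families, variance_by_family, seed=0, n_base=20):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, fam in enumerate(families):
        n = n_base * (i + 1)  # unequal family sizes
        sd = np.sqrt(variance_by_family[fam])
        blocks.append(rng.normal(scale=sd, size=(n, 1)))
        labels += [fam] * n
    return np.vstack(blocks), np.array(labels)


class TestFamilyVarianceRanks:
    def test_tied_variances_get_average_ranks(self):
        scores = np.array(
            [[-2.0], [2.0], [-1.0], [1.0], [-1.0], [1.0]]
        )  # variances A:8, B:2, C:2
        fams = np.array(["A", "A", "B", "B", "C", "C"])
        table = family_variance_ranks(scores, fams)
        assert table.ranks.loc["A"].iloc[0] == 1.0
        assert table.ranks.loc["B"].iloc[0] == 2.5
        assert table.ranks.loc["C"].iloc[0] == 2.5

    def test_constant_family_gets_last_rank(self):
        scores = np.array([[0.0], [0.0], [1.0], [-1.0]])
        fams = np.array(["flat", "flat", "varied", "varied"])
        table = family_variance_ranks(scores, fams)
        assert table.variances.loc["flat"].iloc[0] == 0.0
        assert table.ranks.loc["flat"].iloc[0] == 2.0

    def test_ranks_match_sorting_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(60, 4)) * rng.uniform(0.5, 3.0, size=(60, 4))
        fams = np.repeat([f"F{i}" for i in range(6)], 10)
        table = family_variance_ranks(scores, fams)
        for j, col in enumerate(table.ranks.columns):
            variances = table.variances.iloc[:, j].to_numpy()
            # brute-force average ranks, descending
            expected = np.empty_like(variances)
            for i, v in enumerate(variances):
                greater = np.count_nonzero(variances > v)
                equal = np.count_nonzero(variances == v)
                expected[i] = greater + (equal + 1) / 2.0
            np.testing.assert_allclose(table.ranks.iloc[:, j].to_numpy(), expected)

    def test_rank_columns_sum_to_triangular_number(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(40, 5))
        fams = np.repeat(list("ABCDEFGH"), 5)
        table = family_variance_ranks(scores, fams)
        F = 8
        np.testing.assert_allclose(table.ranks.sum(axis=0), F * (F + 1) / 2.0)

    def test_shift_invariance_per_pc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(30, 3))
        fams = np.repeat(["x", "y", "z"], 10)
        base = family_variance_ranks(scores, fams)
        shifted = scores.copy()
        shifted[:, 1] += 77.0
        table = family_variance_ranks(shifted, fams)
        pd.testing.assert_frame_equal(table.ranks, base.ranks)
        pd.testing.assert_frame_equal(table.variances, base.variances)

    def test_duplicating_samples_keeps_population_variance_ranks(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(30, 2))
        fams = np.repeat(["x", "y", "z"], 10)
        base = family_variance_ranks(scores, fams, ddof=0)
        doubled = family_variance_ranks(
            np.vstack([scores, scores]), np.concatenate([fams, fams]), ddof=0
        )
        np.testing.assert_allclose(
            doubled.variances.to_numpy(), base.variances.to_numpy(), atol=1e-12
        )
        pd.testing.assert_frame_equal(doubled.ranks, base.ranks)

    def test_single_family_rejected(self):
        with pytest.raises(ValidationError):
            family_variance_ranks(np.zeros((4, 1)), np.array(["a"] * 4))


class TestMedianRank:
    @pytest.mark.parametrize(
        "ranks, expected",
        [([2.0, 3.0, 1.0], 2.0), ([1.0, 2.0, 3.0, 4.0], 2.5), ([3.0, 3.0, 3.0], 3.0)],
    )
    def test_values(self, ranks, expected):
        table = make_table(
            {"A": 5, "B": 5}, np.vstack([ranks, ranks])
        )
        assert median_rank(table).loc["A"] == expected


class TestDiversityResiduals:
    def test_perfect_linear_relationship_gives_zero_residuals(self):
        counts = {"A": 10, "B": 100, "C": 1000}
        # -median_rank exactly linear in log10(count): median ranks -1, -2, -3
        ranks = np.array([[1.0], [2.0], [3.0]])
        residuals = diversity_residuals(make_table(counts, ranks))
        np.testing.assert_allclose(residuals.to_numpy(), 0.0, atol=1e-9)

    def test_hand_computed_ols_residuals(self):
        counts = {"A": 10, "B": 100, "C": 1000, "D": 10000}
        ranks = np.array([[4.0], [3.0], [2.0], [0.5]])  # -median ranks -4,-3,-2,-0.5
        residuals = diversity_residuals(make_table(counts, ranks))
        np.testing.assert_allclose(
            residuals.to_numpy(), [0.1, -0.05, -0.2, 0.15], atol=1e-12
        )

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(7)
        counts = {f"F{i}": int(c) for i, c in enumerate(rng.integers(5, 500, 6))}
        ranks = rng.uniform(1, 6, size=(6, 4))
        residuals = diversity_residuals(make_table(counts, ranks))
        assert residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_equal_counts_rejected(self):
        counts = {"A": 10, "B": 10, "C": 10}
        with pytest.raises(ValidationError, match="singular"):
            diversity_residuals(make_table(counts, np.ones((3, 2))))

    def test_count_doubling_leaves_residuals_unchanged(self):
        fams = ["A", "B", "C", "D"]
        var = {"A": 4.0, "B": 2.0, "C": 1.0, "D": 0.5}
        scores, labels = scores_for(fams, var, seed=8)
        table = family_variance_ranks(scores, labels, ddof=0)
        base = diversity_residuals(table)
        doubled_table = family_variance_ranks(
            np.vstack([scores, scores]), np.concatenate([labels, labels]), ddof=0
        )
        doubled = diversity_residuals(doubled_table)
        np.testing.assert_allclose(doubled.to_numpy(), base.to_numpy(), atol=1e-9)


class TestGroupBiasTest:
    def test_six_positive_residuals_exact_p(self):
        residuals = pd.Series(
            [0.3, 0.7, 1.1, 0.2, 0.9, 0.4, -0.5, 0.0],
            index=list("ABCDEFGH"),
        )
        p = group_bias_test(residuals, list("ABCDEF"))
        assert p == pytest.approx(0.03125, abs=1e-12)

    def test_perfectly_symmetric_pair_gives_p_one(self):
        residuals = pd.Series([0.4, -0.4], index=["A", "B"])
        assert group_bias_test(residuals, ["A", "B"]) == pytest.approx(1.0)

    def test_single_member_gives_p_one(self):
        residuals = pd.Series([0.7, -0.1], index=["A", "B"])
        assert group_bias_test(residuals, ["A"]) == pytest.approx(1.0)

    def test_zero_residuals_dropped_with_warning(self):
        residuals = pd.Series([0.0, 0.5, -0.3], index=["A", "B", "C"])
        with pytest.warns(RuntimeWarning, match="zero residual"):
            p = group_bias_test(residuals, ["A", "B", "C"])
        assert 0.0 < p <= 1.0

    def test_empty_group_rejected(self):
        residuals = pd.Series([0.5], index=["A"])
        with pytest.raises(ValidationError):
            group_bias_test(residuals, ["missing"])
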
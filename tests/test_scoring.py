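"""Residuals, absolute-residual ranking, replicate averaging, z-score baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ssemlasso as sl
from ssemlasso.scoring import ResidualProfile, round_half_up
from ssemlasso.training import InteractionNetwork


def make_network(B, means=None, genes=None):
    p = B.shape[0]
    genes = genes or [f"g{i}" for i in range(p)]
    means = np.zeros(p) if means is None else means
    return InteractionNetwork(genes=list(genes), B_hat=B, train_means=means)


class TestComputeResiduals:
    def test_identity_network_returns_centered_vector(self):
        net = make_network(np.zeros((4, 4)), means=np.array([1.0, 2.0, 3.0, 4.0]))
        y = np.array([2.0, 2.0, 5.0, 3.0])
        profile = sl.compute_residuals(net, y)
        assert np.allclose(profile.residuals, y - net.train_means)

    def test_null_experiment_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        B = rng.normal(scale=0.1, size=(5, 5))
        np.fill_diagonal(B, 0.0)
        means = rng.normal(8, 1, size=5)
        net = make_network(B, means=means)
        profile = sl.compute_residuals(net, means.copy())
        assert np.allclose(profile.residuals, 0.0)

    def test_hand_computed_three_gene_case(self):
        B = np.zeros((3, 3))
        B[0, 1] = 0.5
        net = make_network(B)
        profile = sl.compute_residuals(net, np.array([1.0, 2.0, 0.0]))
        assert np.allclose(profile.residuals, [0.0, 2.0, 0.0])

    def test_gene_universe_mismatch_rejected(self):
        net = make_network(np.zeros((3, 3)))
        y = pd.Series([1.0, 2.0, 3.0], index=["g0", "g1", "OTHER"])
        with pytest.raises(ValueError, match="OTHER"):
            sl.compute_residuals(net, y)


class TestRankGenes:
    def test_three_value_example(self):
        profile = ResidualProfile(
            genes=["a", "b", "c"],
            y_pert=np.zeros(3),
            residuals=np.array([0.1, -5.0, 2.0]),
        )
        assert sl.rank_genes(profile).rank.tolist() == [3, 1, 2]

    def test_all_ties_keep_gene_order(self):
        profile = ResidualProfile(
            genes=list("abcde"), y_pert=np.zeros(5), residuals=np.ones(5)
        )
        assert sl.rank_genes(profile).rank.tolist() == [1, 2, 3, 4, 5]

    def test_agrees_with_argsort_oracle_at_scale(self):
        rng = np.random.default_rng(0)
        r = rng.normal(size=1000)
        profile = ResidualProfile(
            genes=[f"g{i}" for i in range(1000)], y_pert=np.zeros(1000), residuals=r
        )
        ranking = sl.rank_genes(profile)
        assert sorted(ranking.rank.tolist()) == list(range(1, 1001))
        order = np.argsort(-np.abs(r), kind="stable")
        expected = np.empty(1000, dtype=int)
        expected[order] = np.arange(1, 1001)
        assert np.array_equal(ranking.rank, expected)

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=30))
    def test_rank_is_always_a_permutation(self, values):
        residuals = np.array(values)
        profile = ResidualProfile(
            genes=[f"g{i}" for i in range(len(values))],
            y_pert=np.zeros(len(values)),
            residuals=residuals,
        )
        ranking = sl.rank_genes(profile)
        assert sorted(ranking.rank.tolist()) == list(range(1, len(values) + 1))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        r = rng.normal(size=50)
        r[np.abs(r) < 0.05] += 0.1  # keep scores distinct so ties play no role
        genes = [f"g{i}" for i in range(50)]
        base = sl.rank_genes(ResidualProfile(genes=genes, y_pert=np.zeros(50), residuals=r))
        perm = rng.permutation(50)
        permuted = sl.rank_genes(
            ResidualProfile(
                genes=[genes[i] for i in perm], y_pert=np.zeros(50), residuals=r[perm]
            )
        )
        for g in genes:
            assert base.rank_of(g) == permuted.rank_of(g)


class TestAverageRankings:
    def _ranking(self, ranks, genes=None):
        ranks = np.asarray(ranks)
        genes = genes or [f"g{i}" for i in range(len(ranks))]
        scores = (len(ranks) + 1.0 - ranks).astype(float)
        return sl.GeneRanking(genes=genes, rank=ranks, abs_residual=scores)

    def test_idempotent_on_identical_replicates(self):
        r = self._ranking([2, 1, 3])
        table = sl.average_rankings([r, r])
        assert table["mean_rank"].tolist() == [2.0, 1.0, 3.0]

    def test_arithmetic_mean_and_display_rounding(self):
        a = self._ranking([3, 1, 2, 4])
        b = self._ranking([4, 2, 1, 3])
        table = sl.average_rankings([a, b])
        assert table.loc["g0", "mean_rank"] == 3.5
        assert table.loc["g0", "display_rank"] == 4  # half-up

    def test_universe_mismatch_rejected(self):
        a = self._ranking([1, 2])
        b = self._ranking([1, 2], genes=["x", "y"])
        with pytest.raises(ValueError):
            sl.average_rankings([a, b])

    def test_round_half_up_convention(self):
        assert round_half_up(3.5) == 4
        assert round_half_up(2.5) == 3
        assert round_half_up(2.4) == 2
        assert round_half_up(-2.5) == -3


class TestZScoreRanking:
    def test_vector_at_training_means_ranks_in_gene_order(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            rng.normal(8, 1, size=(6, 30)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(30)],
        )
        comp = sl.ExpressionCompendium(frame)
        ranking = sl.zscore_ranking(comp, comp.values.mean(axis=1))
        assert ranking.rank.tolist() == [1, 2, 3, 4, 5, 6]

    def test_ten_sigma_shift_ranks_first(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            rng.normal(8, 1, size=(10, 50)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(50)],
        )
        comp = sl.ExpressionCompendium(frame)
        y = comp.values.mean(axis=1)
        y[7] += 10 * comp.values.std(axis=1, ddof=1)[7]
        assert sl.zscore_ranking(comp, y).rank_of("g7") == 1

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.normal(8, 1, size=(40, 25)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(25)],
        )
        comp = sl.ExpressionCompendium(frame)
        y = rng.normal(8, 1, size=40)
        ranking = sl.zscore_ranking(comp, y)
        z = np.abs((y - frame.mean(axis=1)) / frame.std(axis=1, ddof=1))
        order = np.argsort(-z.to_numpy(), kind="stable")
        expected = np.empty(40, dtype=int)
        expected[order] = np.arange(1, 41)
        assert np.array_equal(ranking.rank, expected)

    def test_zero_variance_gene_warns_and_scores_zero(self):
        frame = pd.DataFrame(
            np.vstack([np.ones(10), np.random.default_rng(0).normal(size=(2, 10))]),
            index=["flat", "g1", "g2"],
            columns=[f"s{j}" for j in range(10)],
        )
        comp = sl.ExpressionCompendium(frame)
        with pytest.warns(UserWarning, match="zero training variance"):
            ranking = sl.zscore_ranking(comp, np.array([5.0, 0.0, 0.0]))
        assert ranking.abs_residual[0] == 0.0


class TestTargetRecovery:
    """Target-resolution behaviour on the reference synthetic scenario."""

    def test_true_target_ranks_in_top_percent_of_genes(self, recovery_study):
        hits = [
            r["ssem_rank"] <= max(1, int(np.ceil(0.01 * r["p"]))) for r in recovery_study
        ]
        assert np.mean(hits) >= 0.8

    def test_ssem_median_target_rank_not_worse_than_zscore(self, recovery_study):
        ssem = np.median([r["ssem_rank"] for r in recovery_study])
        zsc = np.median([r["z_rank"] for r in recovery_study])
        assert ssem <= zsc
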
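import numpy as np
import pandas as pd
import pytest

from metqg.errors import CompletenessError, DegenerateError, GeometryError
from metqg.gge import (aec_analysis, center_table, decompose, fit_gge,
                       stability_ranking, which_won_where)


def _random_rank2_table(rng, m=6, q=3, labels=None):
    """A random column-centered table of exact rank <= 2."""
    M = rng.normal(size=(m, q))
    C = M - M.mean(axis=0)
    U, d, Vt = np.linalg.svd(C, full_matrices=False)
    d[2:] = 0.0
    C2 = U @ np.diag(d) @ Vt
    idx = labels or [f"g{i}" for i in range(m)]
    return pd.DataFrame(C2, index=idx, columns=[f"e{j}" for j in range(q)])


class TestCentering:
    def test_column_means_removed(self):
        t = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 8.0]})
        c = center_table(t)
        assert np.allclose(c["A"], [-1, 0, 1])
        assert np.allclose(c.mean(axis=0), 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(5, 3)))
        once = center_table(t)
        pd.testing.assert_frame_equal(center_table(once), once)

    def test_constant_column_becomes_zero(self):
        t = pd.DataFrame({"A": [2.0, 2.0, 2.0], "B": [1.0, 2.0, 3.0]})
        assert np.allclose(center_table(t)["A"], 0.0)

    def test_missing_cells_rejected(self):
        t = pd.DataFrame({"A": [1.0, np.nan], "B": [1.0, 2.0]})
        with pytest.raises(CompletenessError):
            center_table(t)


class TestDecompose:
    def test_rank1_single_component(self):
        u = np.array([1.0, 0.0, -1.0])
        t = pd.DataFrame(np.outer(u, [1.0, 2.0]), index=list("abc"),
                         columns=["e1", "e2"])
        b = decompose(t)
        assert b.var_fraction.iloc[0] == pytest.approx(100.0)

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(1)
        b = fit_gge(pd.DataFrame(rng.normal(size=(8, 4))))
        assert b.var_fraction.sum() == pytest.approx(100.0)

    def test_reconstruction_exact_at_full_rank(self):
        rng = np.random.default_rng(2)
        t = center_table(pd.DataFrame(rng.normal(size=(7, 3))))
        for f in (0.0, 0.5, 1.0):
            b = decompose(t, f=f)
            assert np.allclose(b.reconstruct(rank=3), t, atol=1e-10)

    def test_row_scores_centered(self):
        rng = np.random.default_rng(3)
        b = fit_gge(pd.DataFrame(rng.normal(size=(9, 4))))
        assert np.allclose(b.row_scores.mean(axis=0), 0.0, atol=1e-10)

    def test_zero_table_rejected(self):
        with pytest.raises(DegenerateError):
            decompose(pd.DataFrame(np.zeros((4, 3))))


class TestWhichWonWhere:
    def test_triangle_by_construction(self):
        pts = pd.DataFrame([[2.0, 0.0], [-1.0, 1.5], [-1.0, -1.5]],
                           index=["a", "b", "c"], columns=["e1", "e2"])
        # give the two columns exact rank-2 structure: identity conditions
        b = decompose(pts)
        www = which_won_where(b)
        # condition e1 points along the first axis: its winner is the
        # genotype with the largest centered e1 value
        assert www.winners["e1"] == pts["e1"].idxmax()
        assert set(www.hull_vertices) == {"a", "b", "c"}

    @pytest.mark.parametrize("seed", range(25))
    def test_winner_equals_argmax_on_rank2_tables(self, seed):
        """On a rank-2 table the sector winner is exactly the per-column
        argmax of the (reconstructed = original) centered data."""
        rng = np.random.default_rng(seed)
        t = _random_rank2_table(rng)
        b = decompose(t)
        www = which_won_where(b)
        for cond in t.columns:
            assert www.winners[cond] == t[cond].idxmax()

    def test_svp_invariance_of_winners(self):
        rng = np.random.default_rng(99)
        t = _random_rank2_table(rng)
        winners = [which_won_where(decompose(t, f=f)).winners
                   for f in (0.0, 0.5, 1.0)]
        assert winners[0] == winners[1] == winners[2]

    def test_rotation_invariance_of_sectors(self):
        rng = np.random.default_rng(7)
        t = _random_rank2_table(rng)
        b = decompose(t)
        www = which_won_where(b)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        b2 = decompose(t)
        b2.row_scores.iloc[:, :2] = b.row_scores.to_numpy()[:, :2] @ R.T
        b2.col_scores.iloc[:, :2] = b.col_scores.to_numpy()[:, :2] @ R.T
        assert which_won_where(b2).winners == www.winners

    def test_collinear_scores_rejected(self):
        t = pd.DataFrame(np.outer([1.0, 0.5, -0.5, -1.0], [1.0, 2.0]),
                         index=list("abcd"), columns=["e1", "e2"])
        b = decompose(t)
        with pytest.raises(GeometryError):
            which_won_where(b)


class TestAEC:
    def test_genotype_on_axis_has_zero_stability(self):
        # two identical conditions define the average-environment axis
        t = pd.DataFrame({"e1": [3.0, -1.0, -1.0, -1.0],
                          "e2": [3.0, -1.0, -1.0, -1.0]},
                         index=list("abcd"))
        b = decompose(t)
        aec = aec_analysis(b)
        assert aec.loc["a", "stability"] == pytest.approx(0.0, abs=1e-10)
        assert aec.loc["a", "ideal_distance"] == pytest.approx(0.0, abs=1e-10)
        assert aec.loc["a", "ideal_rank"] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_performance_orders_like_row_means(self, seed):
        """AEC abscissa projections order genotypes exactly like the row
        means of the rank-2 reconstruction."""
        rng = np.random.default_rng(seed)
        t = _random_rank2_table(rng)
        b = decompose(t)
        aec = aec_analysis(b)
        proj_order = aec["mean_performance"].sort_values().index.tolist()
        mean_order = t.mean(axis=1).sort_values().index.tolist()
        assert proj_order == mean_order

    def test_stability_matches_cross_condition_variance(self):
        """With condition scores spread only along the AEC ordinate, the
        per-genotype variance of table values is a monotone function of the
        |ordinate projection|."""
        # orthogonal, centered latent genotype columns keep the two condition
        # score vectors at equal norm, so their difference lies exactly on
        # the AEC ordinate
        g = np.array([[2.0, 1.0], [-2.0, 2.0], [1.0, 2.5], [-1.0, 0.5],
                      [0.0, -6.0]])
        c = np.array([[1.0, 0.8], [1.0, -0.8]])  # same abscissa, +- ordinate
        t = pd.DataFrame(g @ c.T, index=list("abcde"), columns=["e1", "e2"])
        b = decompose(t)
        aec = aec_analysis(b)
        var_order = t.var(axis=1).sort_values().index.tolist()
        stab_order = aec["stability"].sort_values().index.tolist()
        assert var_order == stab_order

    def test_dominating_genotype_ranks_first_everywhere(self):
        t = pd.DataFrame({"e1": [5.0, 1.0, 0.0], "e2": [6.0, 0.5, 1.0]},
                         index=["top", "mid", "low"])
        b = decompose(t)
        rank = stability_ranking(b)
        assert rank.index[0] == "top"
        assert rank.loc["top", "ideal_rank"] == 1

    def test_ranking_permutation_invariant(self):
        rng = np.random.default_rng(4)
        t = _random_rank2_table(rng)
        r1 = stability_ranking(decompose(t))
        shuffled = t.sample(frac=1.0, random_state=1)
        r2 = stability_ranking(decompose(shuffled))
        assert r1.index.tolist() == r2.index.tolist()
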
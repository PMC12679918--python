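import numpy as np
import pandas as pd
import pytest

from strigamet import gge


def additive_matrix():
    g = np.array([0.0, 1.0, 2.0, 4.0])
    e = np.array([10.0, 12.0, 9.0])
    Y = pd.DataFrame(
        g[:, None] + e[None, :],
        index=[f"G{i}" for i in range(4)],
        columns=[f"E{j}" for j in range(3)],
    )
    return Y


def rank2_matrix():
    g = np.array([0.0, 1.0, 2.0, 4.0, 5.0])
    e = np.array([10.0, 12.0, 9.0, 11.0])
    gam = np.array([1.0, -1.0, 0.5, -0.5, 0.0])
    dlt = np.array([0.5, -0.5, 1.0, -1.0])
    Y = g[:, None] + e[None, :] + np.outer(gam, dlt)
    return pd.DataFrame(Y, index=[f"G{i}" for i in range(5)], columns=[f"E{j}" for j in range(4)])


def charpoly_singular_values(M):
    """Oracle: singular values via the characteristic polynomial of the 3x3
    Gram matrix, independent of any SVD routine."""
    G = M.T @ M
    tr = np.trace(G)
    minors = (
        G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
        + G[0, 0] * G[2, 2] - G[0, 2] * G[2, 0]
        + G[1, 1] * G[2, 2] - G[1, 2] * G[2, 1]
    )
    det = np.linalg.det(G)
    eig = np.roots([1.0, -tr, minors, -det])
    eig = np.clip(np.real(eig), 0, None)
    return np.sqrt(np.sort(eig)[::-1])


class TestFitGge:
    def test_column_centering(self):
        model = gge.fit_gge(rank2_matrix())
        np.testing.assert_allclose(model.centered.mean(axis=0), 0.0, atol=1e-10)

    def test_additive_matrix_is_rank_one(self):
        model = gge.fit_gge(additive_matrix())
        assert model.pct_explained["PC1"] == pytest.approx(100.0, abs=1e-8)

    def test_three_by_three_toy_matches_charpoly_oracle(self):
        Y = pd.DataFrame(
            [[8.0, 3.0, 4.0], [1.0, 5.0, 9.0], [6.0, 7.0, 2.0]],
            index=list("abc"),
            columns=list("xyz"),
        )
        model = gge.fit_gge(Y)
        centered = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        expected = charpoly_singular_values(centered)
        np.testing.assert_allclose(model.singular_values, expected, atol=1e-10)

    def test_rank_two_explained(self):
        model = gge.fit_gge(rank2_matrix())
        assert model.pct_explained[["PC1", "PC2"]].sum() == pytest.approx(100.0, abs=1e-8)

    def test_pct_explained_sums_to_100(self):
        rng = np.random.default_rng(2)
        Y = pd.DataFrame(rng.normal(5, 2, (8, 5)))
        model = gge.fit_gge(Y)
        assert model.pct_explained.sum() == pytest.approx(100.0, abs=1e-8)

    def test_scores_reconstruct_centered_matrix(self):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(5, 2, (7, 4)))
        for mode in gge.SVP_MODES:
            model = gge.fit_gge(Y, svp_mode=mode)
            recon = model.genotype_scores.to_numpy() @ model.environment_scores.to_numpy().T
            np.testing.assert_allclose(recon, model.centered.to_numpy(), atol=1e-8)

    def test_svp_mode_changes_scores_not_pct(self):
        Y = rank2_matrix()
        m1 = gge.fit_gge(Y, "genotype_focused")
        m2 = gge.fit_gge(Y, "symmetric")
        pd.testing.assert_series_equal(m1.pct_explained, m2.pct_explained)
        assert not np.allclose(m1.genotype_scores, m2.genotype_scores)

    def test_centering_invariance(self):
        Y = rank2_matrix()
        m1 = gge.fit_gge(Y)
        m2 = gge.fit_gge(Y + 17.3)
        np.testing.assert_allclose(m1.singular_values, m2.singular_values, atol=1e-8)
        np.testing.assert_allclose(
            gge.mean_vs_stability(m1)["abscissa"], gge.mean_vs_stability(m2)["abscissa"], atol=1e-8
        )

    def test_environment_permutation_equivariance(self):
        Y = rank2_matrix()
        perm = ["E2", "E0", "E3", "E1"]
        m1 = gge.fit_gge(Y)
        m2 = gge.fit_gge(Y[perm])
        np.testing.assert_allclose(m1.singular_values, m2.singular_values, atol=1e-8)
        s1 = gge.mean_vs_stability(m1)
        s2 = gge.mean_vs_stability(m2)
        np.testing.assert_allclose(s1["abscissa"], s2["abscissa"], atol=1e-8)
        np.testing.assert_allclose(
            np.abs(s1["ordinate"]), np.abs(s2["ordinate"]), atol=1e-8
        )

    def test_missing_cell_rejected(self):
        Y = rank2_matrix()
        Y.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing cell"):
            gge.fit_gge(Y)

    def test_all_equal_matrix_degenerate(self):
        Y = pd.DataFrame(np.full((4, 3), 5.0))
        model = gge.fit_gge(Y)
        assert model.degenerate
        with pytest.raises(ValueError, match="degenerate"):
            gge.mean_vs_stability(model)


class TestMeanVsStability:
    def test_additive_case(self):
        Y = additive_matrix()
        model = gge.fit_gge(Y)
        stab = gge.mean_vs_stability(model)
        np.testing.assert_allclose(stab["ordinate"], 0.0, atol=1e-8)
        marg = Y.mean(axis=1)
        assert list(stab.sort_values("abscissa", ascending=False).index) == list(
            marg.sort_values(ascending=False).index
        )
        assert np.corrcoef(stab["abscissa"], marg)[0, 1] > 0.999

    def test_rank2_matches_2d_projection_oracle(self):
        model = gge.fit_gge(rank2_matrix())
        stab = gge.mean_vs_stability(model)
        e2 = model.environment_scores[["PC1", "PC2"]].to_numpy()
        g2 = model.genotype_scores[["PC1", "PC2"]].to_numpy()
        aea = e2.mean(axis=0)
        aea = aea / np.hypot(*aea)
        expect_abs = g2 @ aea
        if np.corrcoef(expect_abs, model.Y.mean(axis=1))[0, 1] < 0:
            expect_abs = -expect_abs
            aea = -aea
        # perpendicular component via the 2-D cross product
        expect_ord = g2[:, 0] * aea[1] - g2[:, 1] * aea[0]
        np.testing.assert_allclose(stab["abscissa"], expect_abs, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(stab["ordinate"]), np.abs(expect_ord), atol=1e-10
        )

    def test_rotation_invariance(self):
        """Rotating both score sets in the PC1-PC2 plane by the same orthogonal
        matrix leaves the AEA projections unchanged."""
        model = gge.fit_gge(rank2_matrix())
        before = gge.mean_vs_stability(model)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        model.genotype_scores[["PC1", "PC2"]] = (
            model.genotype_scores[["PC1", "PC2"]].to_numpy() @ R.T
        )
        model.environment_scores[["PC1", "PC2"]] = (
            model.environment_scores[["PC1", "PC2"]].to_numpy() @ R.T
        )
        after = gge.mean_vs_stability(model)
        np.testing.assert_allclose(before["abscissa"], after["abscissa"], atol=1e-8)
        np.testing.assert_allclose(
            np.abs(before["ordinate"]), np.abs(after["ordinate"]), atol=1e-8
        )

    def test_abscissa_ranking_stable_across_svp(self):
        Y = rank2_matrix()
        r1 = gge.mean_vs_stability(gge.fit_gge(Y, "genotype_focused"))["mean_rank"]
        r2 = gge.mean_vs_stability(gge.fit_gge(Y, "symmetric"))["mean_rank"]
        pd.testing.assert_series_equal(r1, r2)


class TestSelectAndPlot:
    def make_inputs(self, n_hyb=20, n_env=4, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"H{i:02d}" for i in range(n_hyb)] + ["CHK1", "CHK2"]
        Y = pd.DataFrame(
            rng.normal(4, 1, (len(names), n_env)),
            index=names,
            columns=[f"E{j}" for j in range(n_env)],
        )
        score = pd.Series(rng.normal(size=len(names)), index=names)
        return Y, score, ["CHK1", "CHK2"]

    def test_twelve_entry_subset(self, tmp_path):
        Y, score, checks = self.make_inputs()
        model, stab, fig = gge.select_and_plot(
            Y, score, checks, k_best=8, k_worst=3, figure_path=tmp_path / "g.svg"
        )
        assert model.Y.shape[0] == 12
        assert (tmp_path / "g.svg").exists()
        # axis labels carry the model's own PC percentages
        ax = fig.axes[0]
        assert f"{model.pct_explained['PC1']:.0f}%" in ax.get_xlabel()
        assert f"{model.pct_explained['PC2']:.0f}%" in ax.get_ylabel()
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_all_best_no_worst_is_full_hybrid_set(self):
        Y, score, checks = self.make_inputs()
        chosen = gge.select_entries(score, checks, k_best=20, k_worst=0,
                                    include_best_check=False)
        assert sorted(chosen) == sorted(h for h in score.index if h.startswith("H"))

    def test_too_few_entries_rejected(self):
        Y, score, checks = self.make_inputs(n_hyb=5)
        with pytest.raises(ValueError, match="hybrids"):
            gge.select_entries(score, checks, k_best=8, k_worst=3)

    def test_best_check_included(self):
        Y, score, checks = self.make_inputs()
        chosen = gge.select_entries(score, checks, k_best=3, k_worst=2)
        best_check = score[checks].idxmax()
        assert best_check in chosen
        assert len(chosen) == 6
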
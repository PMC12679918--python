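import numpy as np
import pandas as pd
import pytest

from strigamet import anova

from conftest import balanced_toy


def brute_force_ss(df):
    """Means-decomposition oracle for complete balanced layouts with one block
    per replicate: SS = sum over groups of n * (group mean - reference)^2."""
    y = df["y"]
    grand = y.mean()
    ss = {}
    env_means = df.groupby("env")["y"].mean()
    n_env = df.groupby("env").size()
    ss["Environment"] = float((n_env * (env_means - grand) ** 2).sum())
    rep_means = df.groupby(["env", "rep"])["y"].mean()
    n_rep = df.groupby(["env", "rep"]).size()
    ss["Rep(E)"] = float(
        (n_rep * (rep_means - env_means.reindex(rep_means.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    ss["Block(ExRep)"] = 0.0  # block == rep in these toys
    ent_means = df.groupby("entry")["y"].mean()
    n_ent = df.groupby("entry").size()
    ss["Hybrid"] = float((n_ent * (ent_means - grand) ** 2).sum())
    cell = df.groupby(["entry", "env"])["y"].mean()
    n_cell = df.groupby(["entry", "env"]).size()
    dev = (
        cell
        - ent_means.reindex(cell.index.get_level_values(0)).to_numpy()
        - env_means.reindex(cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss["HybridxE"] = float((n_cell * dev**2).sum())
    total = float(((y - grand) ** 2).sum())
    ss["Error"] = total - sum(ss.values())
    return ss


class TestCombinedAnova:
    def test_matches_brute_force_on_hand_picked_toy(self):
        values = [7, 9, 4, 6, 12, 15, 10, 11]  # 2 entries x 2 envs x 2 reps
        toy = balanced_toy(2, 2, 2, values)
        tab = anova.combined_anova(toy, "y")
        oracle = brute_force_ss(toy)
        got = dict(zip(tab["source"], tab["sum_sq"]))
        for src, expected in oracle.items():
            assert got[src] == pytest.approx(expected, abs=1e-8), src

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("shape", [(3, 2, 2), (4, 3, 2), (2, 3, 3)])
    def test_matches_brute_force_on_random_balanced_toys(self, shape, seed):
        toy = balanced_toy(*shape, seed=seed)
        tab = anova.combined_anova(toy, "y")
        oracle = brute_force_ss(toy)
        got = dict(zip(tab["source"], tab["sum_sq"]))
        for src, expected in oracle.items():
            assert got[src] == pytest.approx(expected, abs=1e-8), src

    def test_df_identities(self, small_trial):
        tab = anova.combined_anova(small_trial, "YIELD")
        assert tab["df"].sum() == len(small_trial) - 1
        ms = tab["sum_sq"] / tab["df"]
        np.testing.assert_allclose(ms, tab["mean_sq"])
        # component SS add up to the total SS
        y = small_trial["YIELD"]
        total = ((y - y.mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_denominator_structure(self, small_trial):
        tab = anova.combined_anova(small_trial, "YIELD").set_index("source")
        assert tab.loc["Hybrid", "denominator"] == "HybridxE"
        assert tab.loc["Environment", "denominator"] == "Rep(E)"
        ms = tab["mean_sq"]
        assert tab.loc["Hybrid", "f_value"] == pytest.approx(
            ms["Hybrid"] / ms["HybridxE"]
        )

    def test_row_order_invariance(self, small_trial):
        tab = anova.combined_anova(small_trial, "YIELD")
        shuffled = small_trial.sample(frac=1.0, random_state=9)
        tab2 = anova.combined_anova(shuffled, "YIELD")
        pd.testing.assert_frame_equal(
            tab.reset_index(drop=True), tab2.reset_index(drop=True)
        )

    def test_missing_entry_env_combination_rejected(self, small_trial):
        broken = small_trial[
            ~((small_trial["entry"] == "H001") & (small_trial["env"] == small_trial["env"].iloc[0]))
        ]
        with pytest.raises(ValueError, match="H001"):
            anova.combined_anova(broken, "YIELD")

    def test_no_interaction_f_near_one(self):
        """With var_gxe = 0 the Hybrid x E F statistic sits in the Monte-Carlo
        null band [0.8, 1.25] at the default trial size."""
        from strigamet import simdata

        design = simdata.TrialDesign(seed=20)
        truth = simdata.GroundTruth.default(
            design.n_entries, seed=20, var_gxe=0.0, yield_penalty_per_damage=0.0
        )
        rec = simdata.simulate_trial(design, truth)
        tab = anova.combined_anova(rec, "YIELD").set_index("source")
        assert 0.8 <= tab.loc["HybridxE", "f_value"] <= 1.25


class TestLsMeans:
    def test_balanced_toy_equals_arithmetic_means(self):
        toy = balanced_toy(3, 2, 2, seed=3)
        res = anova.ls_means(toy, "y")
        raw = toy.groupby("entry")["y"].mean()
        pd.testing.assert_series_equal(
            res.means, raw.rename("y"), check_names=False, atol=1e-10, rtol=0
        )

    def test_constant_trait(self):
        toy = balanced_toy(3, 2, 2, values=[5.0] * 12)
        res = anova.ls_means(toy, "y")
        np.testing.assert_allclose(res.means, 5.0, atol=1e-10)

    def test_unbalanced_matches_sum_contrast_oracle(self):
        """Dropping one block: LS means must match an emmeans-style fit with
        sum-to-zero contrasts (independent normal-equations oracle)."""
        import statsmodels.formula.api as smf

        toy = balanced_toy(4, 3, 2, seed=8)
        toy["cell"] = (
            toy["env"].astype(str) + "_" + toy["rep"].astype(str) + "_" + toy["block"].astype(str)
        )
        # unbalance: drop two plots
        toy = toy.drop(index=[0, 13]).reset_index(drop=True)
        res = anova.ls_means(toy, "y")
        fit = smf.ols("y ~ C(entry, Sum) + C(cell, Sum)", data=toy).fit()
        entries = sorted(toy["entry"].unique())
        eff = {
            e: fit.params.get(f"C(entry, Sum)[S.{e}]", np.nan) for e in entries[:-1]
        }
        eff[entries[-1]] = -sum(eff.values())
        oracle = {e: fit.params["Intercept"] + eff[e] for e in entries}
        for e in entries:
            assert res.means[e] == pytest.approx(oracle[e], abs=1e-8)

    def test_balance_shift_localized(self):
        """Removing a block changes LS means while preserving the mean of the
        fitted entry effects (up to the model's intercept aliasing)."""
        toy = balanced_toy(4, 2, 2, seed=5)
        full = anova.ls_means(toy, "y").means
        reduced = anova.ls_means(toy.drop(index=[2]), "y").means
        assert not np.allclose(full, reduced)
        # contrasts between entries unaffected by the dropped plot's block peers
        assert full.index.equals(reduced.index)


class TestLsd:
    def test_zero_error_ms(self):
        assert anova.lsd(0.0, 10, 2) == 0.0

    def test_normal_limit(self):
        assert anova.lsd(2.0, 10**6, 4, alpha=0.05) == pytest.approx(1.96, abs=1e-3)

    def test_scaling_law(self):
        a = anova.lsd(3.0, 50, 4)
        b = anova.lsd(3.0, 50, 8)
        assert a / b == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            anova.lsd(1.0, 0.5, 4)


def test_ls_means_table_footer(small_trial):
    sub = small_trial[small_trial["treatment"] == "infested"]
    table = anova.ls_means_table(sub, ["YIELD", "SHD2"])
    assert list(table.index[-4:]) == ["Mean", "Max", "Min", "LSD(0.05)"]
    body = table.iloc[:-4]
    assert table.loc["Max", "YIELD"] == pytest.approx(body["YIELD"].max())


def test_significance_stars():
    assert anova.significance_stars(0.0001) == "***"
    assert anova.significance_stars(0.005) == "**"
    assert anova.significance_stars(0.03) == "*"
    assert anova.significance_stars(0.5) == "ns"
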
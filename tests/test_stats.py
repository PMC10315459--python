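import numpy as np
import pytest

from facesym.stats import boot_welch_t, tukey_hsd, two_way_anova


def crossed_design(rng, n_cell=30, eth_shift=None, levels=6):
    eth_names = [f"E{i}" for i in range(levels)]
    scores, sex, eth = [], [], []
    for e, name in enumerate(eth_names):
        for s in ("female", "male"):
            mu = eth_shift.get(name, 0.0) if eth_shift else 0.0
            scores.append(rng.normal(mu, 1.0, n_cell))
            sex += [s] * n_cell
            eth += [name] * n_cell
    return np.concatenate(scores), sex, eth


class TestTwoWayAnova:
    def test_planted_ethnicity_effect(self):
        rng = np.random.default_rng(0)
        scores, sex, eth = crossed_design(rng, eth_shift={"E3": 2.0})
        res = two_way_anova(scores, sex, eth)
        assert res.table.loc["ethnicity", "p"] < 1e-3
        assert res.table.loc["sex", "p"] > 0.001  # no planted sex effect
        assert res.table["df"].sum() == len(scores) - 1

    def test_type2_equals_type1_when_balanced(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(1)
        scores, sex, eth = crossed_design(rng, n_cell=10, levels=3)
        df = pd.DataFrame({"score": scores, "sex": sex, "ethnicity": eth})
        model = smf.ols("score ~ C(sex) * C(ethnicity)", data=df).fit()
        t1 = sm.stats.anova_lm(model, typ=1)
        res = two_way_anova(scores, sex, eth)
        np.testing.assert_allclose(
            res.table.loc["sex", "SS"], t1.loc["C(sex)", "sum_sq"], rtol=1e-8
        )
        np.testing.assert_allclose(
            res.table.loc["ethnicity", "SS"],
            t1.loc["C(ethnicity)", "sum_sq"],
            rtol=1e-8,
        )

    def test_constant_scores_degenerate(self):
        sex = ["female", "male"] * 20
        eth = (["E0"] * 20) + (["E1"] * 20)
        with pytest.warns(UserWarning, match="identical"):
            res = two_way_anova(np.ones(40), sex, eth)
        assert np.allclose(res.table["SS"].iloc[:3], 0.0)
        assert np.isnan(res.table.loc["sex", "F"])

    def test_empty_cell_rejected(self):
        scores = np.arange(30.0)
        sex = ["female"] * 10 + ["male"] * 20
        eth = ["E0"] * 10 + ["E1"] * 20  # no (female, E1) cell
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_anova(scores, sex, eth)

    def test_diagnostics_reported(self):
        rng = np.random.default_rng(2)
        scores, sex, eth = crossed_design(rng, n_cell=15, levels=2)
        res = two_way_anova(scores, sex, eth)
        assert 0 <= res.shapiro_p <= 1
        assert 0 <= res.bartlett_p <= 1


class TestTukeyHsd:
    def test_planted_group_pattern(self):
        # one group shifted by 3 pooled SD: its 5 pairs significant,
        # the remaining 10 pairs mostly not, across seeds
        hits, false = 0, 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            groups = [f"G{i}" for i in range(6)]
            scores, labels = [], []
            for g in groups:
                mu = 3.0 if g == "G2" else 0.0
                scores.append(rng.normal(mu, 1.0, 30))
                labels += [g] * 30
            res = tukey_hsd(np.concatenate(scores), labels)
            sig = res[res["reject"]]
            involves = sig["group1"].eq("G2") | sig["group2"].eq("G2")
            if involves.sum() == 5 and len(sig) == involves.sum():
                hits += 1
            false += int((~involves).sum() > 0)
        assert hits >= int(0.9 * reps)
        assert false <= int(0.2 * reps)

    def test_null_type_one_rate(self):
        # two identical groups: rejection rate at the nominal level
        rejections = 0
        reps = 300
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            scores = rng.standard_normal(40)
            labels = ["a"] * 20 + ["b"] * 20
            res = tukey_hsd(scores, labels)
            rejections += int(res["reject"].iloc[0])
        assert rejections / reps <= 0.07

    def test_pair_order_irrelevant(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15)])
        res1 = tukey_hsd(scores, ["a"] * 15 + ["b"] * 15)
        res2 = tukey_hsd(scores[::-1], (["b"] * 15 + ["a"] * 15)[::-1])
        assert np.isclose(
            abs(res1["mean_diff"].iloc[0]), abs(res2["mean_diff"].iloc[0])
        )
        assert np.isclose(res1["p_adj"].iloc[0], res2["p_adj"].iloc[0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            tukey_hsd(np.arange(5.0), ["a"] * 5)


class TestBootWelch:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = boot_welch_t(x, x.copy(), n_boot=200, seed=0)
        assert res.t_obs == 0.0
        assert res.p_classical == 1.0
        assert res.mean_diff == 0.0

    def test_determinism(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        r1 = boot_welch_t(x, y, n_boot=300, seed=7)
        r2 = boot_welch_t(x, y, n_boot=300, seed=7)
        assert r1 == r2

    def test_exchangeability_with_mirrored_seeds(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 25), rng.normal(0.5, 2, 40)
        fwd = boot_welch_t(x, y, n_boot=500, seed=(11, 22))
        rev = boot_welch_t(y, x, n_boot=500, seed=(22, 11))
        assert rev.t_obs == pytest.approx(-fwd.t_obs)
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.p_classical == pytest.approx(fwd.p_classical)
        assert rev.p_bootstrap == pytest.approx(fwd.p_bootstrap)
        assert rev.ci_low == pytest.approx(-fwd.ci_high)
        assert rev.ci_high == pytest.approx(-fwd.ci_low)

    def test_classical_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1.5, 35)
        res = boot_welch_t(x, y, n_boot=200, seed=0)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert np.isclose(res.t_obs, ref.statistic)
        assert np.isclose(res.p_classical, ref.pvalue)
        assert np.isclose(res.satterthwaite_df, ref.df)

    def test_concordance_with_classical_at_study_sizes(self):
        # n = 30 vs 150 with a 0.8 SD shift: bootstrap and classical agree
        # in reject/accept at α = 0.05 for nearly all seeds
        agree = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.8, 1.0, 30)
            y = rng.normal(0.0, 1.0, 150)
            res = boot_welch_t(x, y, n_boot=300, seed=seed)
            agree += int(
                (res.p_bootstrap < 0.05) == (res.p_classical < 0.05)
            )
        assert agree >= int(0.9 * reps)

    def test_null_type_one_rate(self):
        rejections = 0
        reps = 250
        for seed in range(reps):
            rng = np.random.default_rng(5000 + seed)
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            res = boot_welch_t(x, y, n_boot=199, seed=seed)
            rejections += int(res.p_bootstrap < 0.05)
        assert 0.02 <= rejections / reps <= 0.08

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(2, 1, 40), rng.normal(0, 1, 40)
        res = boot_welch_t(x, y, n_boot=500, seed=1)
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            boot_welch_t([1.0, 1.0, 1.0], [2.0, 2.0], n_boot=200, seed=0)
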
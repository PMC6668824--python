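import numpy as np
import pytest

from metamem.univariate import (
    bonferroni,
    cohens_d_avg_sd,
    mixed_anova,
    pooled_t_test,
    pooled_t_test_raw,
    posthoc_stimulus_tests,
)


def brute_force_splitplot(Y, age, stimulus):
    """Independent oracle: direct cell-means summation on a balanced design.

    Computes every effect SS of the 2 (between) x 3 (between) x 2 (within)
    split-plot layout by summing squared deviations of the classical model
    identity over observations.  Valid only when every cell has the same
    number of subjects.
    """
    a_levels = sorted(set(age))
    s_levels = sorted(set(stimulus))
    n = Y.shape[0]
    q = 2
    grand = Y.mean()

    def rows(a=None, s=None):
        idx = np.ones(n, dtype=bool)
        if a is not None:
            idx &= np.asarray(age) == a
        if s is not None:
            idx &= np.asarray(stimulus) == s
        return idx

    ss = {}
    ss["Age"] = sum(rows(a=a).sum() * q * (Y[rows(a=a)].mean() - grand) ** 2 for a in a_levels)
    ss["Stimulus"] = sum(
        rows(s=s).sum() * q * (Y[rows(s=s)].mean() - grand) ** 2 for s in s_levels
    )
    ss["Age:Stimulus"] = sum(
        rows(a, s).sum()
        * q
        * (Y[rows(a, s)].mean() - Y[rows(a=a)].mean() - Y[rows(s=s)].mean() + grand) ** 2
        for a in a_levels
        for s in s_levels
    )
    subj_mean = Y.mean(axis=1)
    ss["Error(between)"] = sum(
        q * ((subj_mean[rows(a, s)] - subj_mean[rows(a, s)].mean()) ** 2).sum()
        for a in a_levels
        for s in s_levels
    )
    t_mean = Y.mean(axis=0)
    ss["TestType"] = n * ((t_mean - grand) ** 2).sum()
    ss["TestType:Age"] = sum(
        rows(a=a).sum()
        * ((Y[rows(a=a)].mean(axis=0) - Y[rows(a=a)].mean() - t_mean + grand) ** 2).sum()
        for a in a_levels
    )
    ss["TestType:Stimulus"] = sum(
        rows(s=s).sum()
        * ((Y[rows(s=s)].mean(axis=0) - Y[rows(s=s)].mean() - t_mean + grand) ** 2).sum()
        for s in s_levels
    )
    # standard identity: mu_ast - mu_as - mu_at - mu_st + mu_a + mu_s + mu_t - mu
    ss["TestType:Age:Stimulus"] = sum(
        rows(a, s).sum()
        * (
            (
                Y[rows(a, s)].mean(axis=0)
                - Y[rows(a, s)].mean()
                - Y[rows(a=a)].mean(axis=0)
                + Y[rows(a=a)].mean()
                - Y[rows(s=s)].mean(axis=0)
                + Y[rows(s=s)].mean()
                + t_mean
                - grand
            )
            ** 2
        ).sum()
        for a in a_levels
        for s in s_levels
    )
    total = ((Y - grand) ** 2).sum()
    ss["Error(within)"] = total - sum(ss.values())
    return ss, total


def _balanced_design(rng, per_cell=4):
    age, stim, blocks = [], [], []
    for a in ("old", "young"):
        for s in ("names", "nonwords", "words"):
            age += [a] * per_cell
            stim += [s] * per_cell
            blocks.append(rng.normal(size=(per_cell, 2)))
    return np.vstack(blocks), np.array(age), np.array(stim)


class TestMixedAnova:
    def test_all_equal_scores_give_zero_F(self):
        Y = np.full((12, 2), 0.4)
        age = np.array(["young"] * 6 + ["old"] * 6)
        stim = np.array(["words", "names", "nonwords"] * 4)
        table = mixed_anova(Y, age, stim)
        effects = table.drop(index=["Error(between)", "Error(within)"])
        assert np.allclose(effects["F"].fillna(0.0), 0.0)

    def test_balanced_fixture_matches_brute_force(self):
        rng = np.random.default_rng(42)
        Y, age, stim = _balanced_design(rng, per_cell=2)
        table = mixed_anova(Y, age, stim)
        oracle, total = brute_force_splitplot(Y, age, stim)
        for effect, ss in oracle.items():
            assert table.loc[effect, "SS"] == pytest.approx(ss, abs=1e-10)
        assert table["SS"].sum() == pytest.approx(total, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ss_conservation_on_random_balanced_data(self, seed):
        rng = np.random.default_rng(seed)
        Y, age, stim = _balanced_design(rng, per_cell=5)
        table = mixed_anova(Y, age, stim)
        total = ((Y - Y.mean()) ** 2).sum()
        assert abs(table["SS"].sum() - total) < 1e-9

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        Y, age, stim = _balanced_design(rng, per_cell=3)
        table = mixed_anova(Y, age, stim)
        n = Y.shape[0]
        assert table.loc["Error(between)", "df"] == n - 6
        assert table.loc["Error(within)", "df"] == n - 6
        assert table.loc["Stimulus", "df"] == 2

    def test_unbalanced_unweighted_means_hand_computation(self):
        # 10 subjects, cells of unequal size; Age marginal means are
        # unweighted over stimulus cells with the harmonic cell size as n
        Y = np.array(
            [[1.0, 2.0], [2.0, 3.0], [0.0, 1.0],
             [4.0, 5.0], [5.0, 4.0],
             [1.0, 0.0], [2.0, 1.0],
             [6.0, 7.0], [7.0, 8.0], [8.0, 6.0]]
        )
        age = np.array(["y"] * 5 + ["o"] * 5)
        stim = np.array(["w", "w", "w", "n", "n", "w", "w", "n", "n", "n"])
        table = mixed_anova(Y, age, stim)
        cell = {
            ("y", "w"): Y[0:3].mean(), ("y", "n"): Y[3:5].mean(),
            ("o", "w"): Y[5:7].mean(), ("o", "n"): Y[7:10].mean(),
        }
        n_tilde = 4 / (1 / 3 + 1 / 2 + 1 / 2 + 1 / 3)
        a_means = {
            "y": (cell[("y", "w")] + cell[("y", "n")]) / 2,
            "o": (cell[("o", "w")] + cell[("o", "n")]) / 2,
        }
        grand = np.mean(list(cell.values()))
        expected_ss_age = 2 * n_tilde * 2 * sum((m - grand) ** 2 for m in a_means.values())
        assert table.loc["Age", "SS"] == pytest.approx(expected_ss_age, abs=1e-10)

    def test_missing_score_names_subject(self):
        Y = np.array([[0.1, 0.2], [0.3, np.nan], [0.2, 0.1], [0.0, 0.4]])
        age = np.array(["young", "young", "old", "old"])
        stim = np.array(["words"] * 4)
        with pytest.raises(ValueError, match="1"):
            mixed_anova(Y, age, stim)

    def test_empty_cell_rejected(self):
        Y = np.zeros((4, 2))
        age = np.array(["young", "young", "old", "old"])
        stim = np.array(["words", "words", "names", "names"])
        with pytest.raises(ValueError, match="empty"):
            mixed_anova(Y, age, stim)


class TestPooledT:
    def test_equal_means_give_zero(self):
        res = pooled_t_test(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.t == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_group_swap_antisymmetry(self):
        a = pooled_t_test(3.0, 1.0, 20, 2.0, 1.5, 25)
        b = pooled_t_test(2.0, 1.5, 25, 3.0, 1.0, 20)
        assert a.t == pytest.approx(-b.t)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed)

    def test_summary_equals_raw_form(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(2.0, 1.0, size=30)
        x2 = rng.normal(1.5, 1.2, size=25)
        raw = pooled_t_test_raw(x1, x2)
        summ = pooled_t_test(
            x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
        )
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        assert raw.p_two_tailed == pytest.approx(summ.p_two_tailed, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_item_fatigue_age_difference(self):
        # young report more item-test fatigue than old: t(104) = 4.207, d = .82
        res = pooled_t_test(2.79, 1.13, 57, 1.88, 1.09, 49, m_tests=18)
        assert res.df == 104
        assert res.t == pytest.approx(4.207, abs=0.01)
        assert res.cohens_d == pytest.approx(0.82, abs=0.005)
        assert res.p_bonferroni < 0.0015  # prints as < .001 from unrounded data


class TestCohensD:
    @pytest.mark.parametrize(
        "m1,sd1,m2,sd2,expected",
        [
            (12.91, 0.96, 16.17, 2.36, 1.96),  # years of education
            (8.86, 1.29, 7.31, 2.41, 0.84),    # self-rated hearing
            (22.07, 4.16, 29.06, 4.99, 1.53),  # vocabulary
        ],
    )
    def test_demographic_effect_sizes(self, m1, sd1, m2, sd2, expected):
        assert cohens_d_avg_sd(m1, sd1, m2, sd2) == pytest.approx(expected, abs=0.005)

    def test_mean_of_sds_convention_not_pooled(self):
        # for the education row only the mean-of-SDs form reproduces 1.96;
        # the pooled-SD convention gives ~1.86 with these group sizes
        pooled_sd = np.sqrt((56 * 0.96**2 + 48 * 2.36**2) / 104)
        assert abs(12.91 - 16.17) / pooled_sd == pytest.approx(1.86, abs=0.005)
        assert cohens_d_avg_sd(12.91, 0.96, 16.17, 2.36) == pytest.approx(1.96, abs=0.005)

    def test_equal_means_and_validation(self):
        assert cohens_d_avg_sd(3.0, 1.0, 3.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            cohens_d_avg_sd(1.0, 0.0, 2.0, 0.0)


class TestPosthoc:
    def test_df_convention_pools_item_and_associate(self):
        rng = np.random.default_rng(9)
        stim = np.array(["words"] * 36 + ["names"] * 36 + ["nonwords"] * 34)
        item = rng.normal(0.5, 0.2, size=106)
        assoc = rng.normal(0.45, 0.2, size=106)
        results = posthoc_stimulus_tests(item, assoc, stim)
        assert results[("words", "names")].df == 142
        assert results[("words", "nonwords")].df == 138
        assert results[("names", "nonwords")].df == 138

    def test_identical_distributions_give_small_t(self):
        stim = np.array(["words", "names", "nonwords"] * 20)
        item = np.tile([0.5, 0.5, 0.5], 20)
        assoc = np.tile([0.4, 0.4, 0.4], 20)
        results = posthoc_stimulus_tests(item, assoc, stim)
        for res in results.values():
            assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_absent_condition_rejected(self):
        with pytest.raises(ValueError, match="nonwords"):
            posthoc_stimulus_tests(
                np.zeros(4), np.zeros(4), np.array(["words", "words", "names", "names"])
            )


class TestBonferroni:
    def test_multiplication_and_cap(self):
        adjusted = bonferroni([0.001, 0.2], m=18)
        assert adjusted[0] == pytest.approx(0.018)
        assert adjusted[1] == 1.0

    def test_family_thresholds(self):
        # alpha = .05 over 18 tests -> .0028; over 3 tests -> .0167
        assert 0.05 / 18 == pytest.approx(0.0028, abs=5e-5)
        assert 0.05 / 3 == pytest.approx(0.0167, abs=5e-5)

    def test_m_validation(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)
        with pytest.raises(ValueError):
            bonferroni([1.5])
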
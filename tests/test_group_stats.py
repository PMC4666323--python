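"""Group statistics: closed forms, BH-FDR step-up, RM-ANOVAs, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from graspmvpa.group_stats import (
    fdr_bh,
    group_table,
    paired_ttests_fdr,
    rm_anova_classification_contrast,
    rm_anova_roi_hemisphere,
    rm_anova_two_way,
    ttest_vs_chance,
)


def vector_with_moments(n, mean, sd, seed=0):
    """Exact sample mean and (ddof=1) SD by affine rescaling."""
    z = np.random.default_rng(seed).normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestTtestVsChance:
    def test_all_at_chance_gives_t_zero_p_half(self):
        res = ttest_vs_chance(np.full(16, 0.5))
        assert res.degenerate  # zero variance is flagged
        assert res.t == 0.0 and res.p_one_tailed == 0.5

    def test_closed_form_t_for_known_moments(self):
        acc = vector_with_moments(16, 0.6, 0.1)
        res = ttest_vs_chance(acc)
        assert res.df == 15
        assert abs(res.t - 4.0) < 1e-10
        assert abs(res.sem - 0.025) < 1e-12
        # one-tailed p from the closed-form t distribution
        from scipy import stats

        assert abs(res.p_one_tailed - stats.t.sf(4.0, 15)) < 1e-12

    def test_constant_above_chance_is_degenerate_infinite_t(self):
        res = ttest_vs_chance(np.full(8, 0.6))
        assert res.degenerate and res.t == np.inf and res.p_one_tailed == 0.0

    def test_too_short_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ttest_vs_chance(np.array([0.5]))
        with pytest.raises(ValueError):
            ttest_vs_chance(np.array([0.5, np.nan]))


def brute_force_bh(p, q):
    """Step-up by direct enumeration: reject all p <= p_(k*) with
    k* = max{k : p_(k) <= k q / m}."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


class TestFdrBh:
    def test_single_small_p_rejected_with_its_own_alpha(self):
        reject, alpha = fdr_bh(np.array([0.01]), q=0.05)
        assert reject.tolist() == [True] and alpha == 0.01

    def test_matches_brute_force_step_up(self):
        p = np.array([0.001, 0.02, 0.04, 0.2])
        reject, alpha = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(reject, brute_force_bh(p, 0.05))
        assert alpha == p[reject].max()

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        q=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_property_equals_enumeration_oracle(self, p, q):
        p = np.asarray(p)
        reject, _ = fdr_bh(p, q=q)
        np.testing.assert_array_equal(reject, brute_force_bh(p, q))

    def test_all_ones_reject_nothing(self):
        reject, alpha = fdr_bh(np.ones(5), q=0.05)
        assert not reject.any() and alpha is None

    def test_never_more_rejections_than_uncorrected(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=10)
            reject, _ = fdr_bh(p, q=0.05)
            assert reject.sum() <= (p <= 0.05).sum()

    def test_monotone_lowering_p_cannot_shrink_rejections(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=8)
        reject_hi, _ = fdr_bh(p, q=0.05)
        reject_lo, _ = fdr_bh(p * 0.5, q=0.05)
        assert np.all(reject_lo >= reject_hi)  # superset of rejections

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([1.2]))


def hand_anova_two_way(y):
    """Textbook sums-of-squares by explicit loops (independent oracle)."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "SA": 0.0, "SB": 0.0, "SAB": 0.0}
    for i in range(a):
        ss["A"] += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["SA"] += b * (
                y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand
            ) ** 2
        for j in range(b):
            ss["SB"] += a * (
                y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + grand
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss["SAB"] += (
                    y[s, i, j]
                    - y[s, i, :].mean()
                    - y[s, :, j].mean()
                    - y[:, i, j].mean()
                    + y[s].mean()
                    + y[:, i, :].mean()
                    + y[:, :, j].mean()
                    - grand
                ) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["SA"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["SB"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["SAB"] / ((a - 1) * (b - 1) * (n - 1))
    )
    return ss, f_a, f_b, f_ab


class TestRmAnovaTwoWay:
    def test_study_design_degrees_of_freedom(self):
        # 7 ROIs x 2 hemispheres x 16 subjects -> ROI df (6, 90)
        rng = np.random.default_rng(2)
        res = rm_anova_two_way(rng.normal(size=(16, 7, 2)))
        roi = res.effect("roi")
        assert (roi["df_num"], roi["df_den"]) == (6, 90)
        hemi = res.effect("hemisphere")
        assert (hemi["df_num"], hemi["df_den"]) == (1, 15)
        inter = res.effect("roi x hemisphere")
        assert (inter["df_num"], inter["df_den"]) == (6, 90)

    def test_identical_factor_means_give_zero_f(self):
        rng = np.random.default_rng(3)
        y = np.repeat(rng.normal(size=(8, 1, 2)), 5, axis=1)  # no ROI variation
        res = rm_anova_two_way(y)
        assert res.effect("roi")["F"] < 1e-20
        assert res.effect("roi")["partial_eta_sq"] == 0.0

    def test_matches_hand_worked_sums_of_squares(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(4, 2, 2))
        res = rm_anova_two_way(y)
        ss, f_a, f_b, f_ab = hand_anova_two_way(y)
        assert abs(res.effect("roi")["F"] - f_a) < 1e-10
        assert abs(res.effect("hemisphere")["F"] - f_b) < 1e-10
        assert abs(res.effect("roi x hemisphere")["F"] - f_ab) < 1e-10
        assert abs(
            res.effect("roi")["partial_eta_sq"] - ss["A"] / (ss["A"] + ss["SA"])
        ) < 1e-12

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=(6, 3, 2))
        res = rm_anova_two_way(y)
        long = pd.DataFrame(
            [
                {"subject": s, "roi": f"r{i}", "hemi": f"h{j}", "y": y[s, i, j]}
                for s in range(6)
                for i in range(3)
                for j in range(2)
            ]
        )
        ref = pg.rm_anova(
            data=long, dv="y", within=["roi", "hemi"], subject="subject",
            effsize="np2",
        )
        for mine, theirs in [("roi", "roi"), ("hemisphere", "hemi"),
                             ("roi x hemisphere", "roi * hemi")]:
            row = ref[ref["Source"] == theirs].iloc[0]
            assert abs(res.effect(mine)["F"] - row["F"]) < 1e-8
            assert abs(res.effect(mine)["p"] - row["p_unc"]) < 1e-8
            assert abs(res.effect(mine)["partial_eta_sq"] - row["np2"]) < 1e-8
            assert res.effect(mine)["df_num"] == row["ddof1"]
            assert res.effect(mine)["df_den"] == row["ddof2"]

    def test_partial_eta_sq_bounds(self):
        rng = np.random.default_rng(6)
        res = rm_anova_two_way(rng.normal(size=(5, 3, 2)))
        assert ((res.effects["partial_eta_sq"] >= 0)
                & (res.effects["partial_eta_sq"] <= 1)).all()

    def test_gg_correction_shrinks_df_and_keeps_epsilon_bounds(self):
        rng = np.random.default_rng(7)
        res = rm_anova_two_way(rng.normal(size=(10, 4, 2)), gg_correction=True)
        roi = res.effect("roi")
        assert 1.0 / 3.0 - 1e-12 <= roi["gg_epsilon"] <= 1.0
        assert roi["df_num"] <= 3

    def test_missing_cells_rejected(self):
        y = np.ones((4, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_two_way(y)


class TestPairedPosthocs:
    def test_seven_levels_give_21_pairs(self):
        rng = np.random.default_rng(8)
        table, _ = paired_ttests_fdr(rng.normal(size=(16, 7)), [f"r{i}" for i in range(7)])
        assert len(table) == 21

    def test_identical_levels_have_t_zero(self):
        y = np.random.default_rng(9).normal(size=(10, 2))
        y[:, 1] = y[:, 0]
        table, alpha = paired_ttests_fdr(y, ["a", "b"])
        assert table.iloc[0]["t"] == 0.0
        assert alpha is None

    def test_pair_t_equals_one_sample_t_on_differences(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        y = rng.normal(size=(12, 3))
        table, _ = paired_ttests_fdr(y, ["a", "b", "c"])
        for _, row in table.iterrows():
            i = ["a", "b", "c"].index(row["level_a"])
            j = ["a", "b", "c"].index(row["level_b"])
            t_ref, p_ref = stats.ttest_1samp(y[:, i] - y[:, j], 0.0)
            assert abs(row["t"] - t_ref) < 1e-10
            assert abs(row["p"] - p_ref) < 1e-10

    def test_corrected_alpha_is_largest_rejected_p(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(16, 4)) + np.array([0.0, 0.5, 1.0, 1.5])
        table, alpha = paired_ttests_fdr(y, list("abcd"))
        assert alpha == table.loc[table["fdr_rejected"], "p"].max()


class TestClassificationContrast:
    def test_equal_means_give_zero_contrast_f(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(10, 1))
        res = rm_anova_classification_contrast(
            np.repeat(base, 3, axis=1), ["a", "b", "c"]
        )
        assert res.effect("linear_contrast")["F"] < 1e-20

    def test_contrast_estimate_is_last_minus_first(self):
        y = np.array([[0.5, 0.6, 0.7], [0.4, 0.65, 0.9]])
        res = rm_anova_classification_contrast(y, ["a", "b", "c"])
        scores = -y[:, 0] + y[:, 2]
        assert abs(res.effects.attrs["contrast_mean"] - scores.mean()) < 1e-12

    def test_contrast_f_equals_one_sample_t_squared(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        y = rng.normal(size=(16, 3)) + np.array([0.0, 0.1, 0.2])
        res = rm_anova_classification_contrast(y, ["a", "b", "c"])
        t_ref, _ = stats.ttest_1samp(-y[:, 0] + y[:, 2], 0.0)
        assert abs(res.effect("linear_contrast")["F"] - t_ref**2) < 1e-10
        assert res.effect("linear_contrast")["df_den"] == 15

    def test_planted_increasing_trend_detected(self):
        rng = np.random.default_rng(14)
        y = np.tile([0.55, 0.65, 0.75], (16, 1)) + rng.normal(0, 0.05, size=(16, 3))
        res = rm_anova_classification_contrast(y, ["g", "pg", "whg"])
        assert res.effect("linear_contrast")["p"] < 0.01

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_classification_contrast(np.ones((5, 2)), ["a", "b", "c"])


class TestGroupTable:
    @staticmethod
    def fake_decoding(n_subjects=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for roi, hemi, shift in [("A", "L", 0.15), ("A", "R", 0.1),
                                     ("Control", "none", 0.0)]:
                rows.append(
                    {
                        "subject": f"sub-{s:02d}", "roi": roi, "hemisphere": hemi,
                        "classification": "grasp_type",
                        "accuracy": 0.5 + shift + rng.normal(0, 0.03),
                        "n_folds": 18, "n_samples": 36,
                    }
                )
        return pd.DataFrame(rows)

    def test_one_row_per_cell_with_fdr_flags(self):
        table = group_table(self.fake_decoding(), "grasp_type")
        assert len(table) == 3
        assert table.loc[table["roi"] == "A", "fdr_rejected"].all()
        assert not table.loc[table["roi"] == "Control", "fdr_rejected"].any()
        assert table.attrs["corrected_alpha"] is not None

    def test_control_roi_can_be_excluded_from_family(self):
        table = group_table(
            self.fake_decoding(), "grasp_type", exclude_rois=("Control",)
        )
        assert "Control" not in table["roi"].values

    def test_unknown_classification_raises(self):
        with pytest.raises(ValueError):
            group_table(self.fake_decoding(), "nope")


def test_rm_anova_roi_hemisphere_from_decoding_table():
    rng = np.random.default_rng(15)
    rows = []
    for s in range(16):
        subj_base = rng.normal(0, 0.02)
        for i, roi in enumerate("ABCDEFG"):
            for hemi, bump in (("L", 0.03), ("R", 0.0)):
                rows.append(
                    {
                        "subject": f"sub-{s:02d}", "roi": roi, "hemisphere": hemi,
                        "classification": "grasp_type",
                        "accuracy": 0.55 + 0.01 * i + bump + subj_base
                        + rng.normal(0, 0.02),
                    }
                )
    rows.append(
        {"subject": "sub-00", "roi": "Control", "hemisphere": "none",
         "classification": "grasp_type", "accuracy": 0.5}
    )
    decoding = pd.DataFrame(rows)
    res = rm_anova_roi_hemisphere(decoding, "grasp_type")
    roi = res.effect("roi")
    assert (roi["df_num"], roi["df_den"]) == (6, 90)  # control excluded
    assert res.effect("hemisphere")["p"] < 0.01
    assert len(res.posthoc) == 21
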
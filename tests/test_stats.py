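"""Reduction scores, within-subject ANOVA, t-tests, robust correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tntmvpa as t
from tntmvpa.stats import skipped_outliers, mcd_center, _spearman


def brute_force_2x2_anova(Y):
    """Independent sums-of-squares decomposition for subjects x 2 x 2 data,
    written directly from the textbook marginal-mean formulas."""
    n = Y.shape[0]
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))  # subject means
    m_a = Y.mean(axis=(0, 2))  # factor A marginals
    m_b = Y.mean(axis=(0, 1))  # factor B marginals
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    ss_s = 4 * np.sum((m_s - grand) ** 2)
    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = 2 * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = 2 * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (
            Y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    )
    out = {}
    for name, ss_eff, ss_err in (
        ("A", ss_a, ss_sa), ("B", ss_b, ss_sb), ("A:B", ss_ab, ss_sab),
    ):
        F = (ss_eff / 1) / (ss_err / (n - 1))
        eta2g = ss_eff / (ss_eff + ss_s + ss_sa + ss_sb + ss_sab)
        out[name] = (F, eta2g)
    return out


class TestReductionScores:
    def test_worked_example(self):
        cells = pd.DataFrame(
            {
                "subject": [1] * 4,
                "phase": ["pretest", "posttest", "pretest", "posttest"],
                "condition": ["suppress", "suppress", "baseline", "baseline"],
                "value": [4.0, 2.0, 4.0, 3.5],
            }
        )
        out = t.reduction_scores(cells)
        assert out["reduction"].iloc[0] == pytest.approx(1.5)

    def test_equal_cells_give_zero(self):
        cells = pd.DataFrame(
            {
                "subject": [1] * 4,
                "phase": ["pretest", "posttest", "pretest", "posttest"],
                "condition": ["suppress", "suppress", "baseline", "baseline"],
                "value": [3.0] * 4,
            }
        )
        assert t.reduction_scores(cells)["reduction"].iloc[0] == 0.0

    def test_missing_cell_rejected(self):
        cells = pd.DataFrame(
            {
                "subject": [1] * 3,
                "phase": ["pretest", "posttest", "pretest"],
                "condition": ["suppress", "suppress", "baseline"],
                "value": [4.0, 2.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="missing"):
            t.reduction_scores(cells)


class TestRmAnova:
    def test_additive_data_zero_interaction(self):
        n = 10
        rng = np.random.default_rng(0)
        subj = rng.normal(size=n)[:, None, None]
        a_eff = np.array([0.5, -0.5])[None, :, None]
        b_eff = np.array([-1.0, 1.0])[None, None, :]
        Y = subj + a_eff + b_eff
        res = t.rm_anova(Y, ["A", "B"]).set_index("effect")
        assert res.loc["A:B", "F"] == 0.0

    def test_matches_brute_force_oracle_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            Y = rng.normal(size=(rng.integers(5, 20), 2, 2))
            res = t.rm_anova(Y, ["A", "B"]).set_index("effect")
            oracle = brute_force_2x2_anova(Y)
            for eff in ("A", "B", "A:B"):
                F_o, g_o = oracle[eff]
                assert res.loc[eff, "F"] == pytest.approx(F_o, abs=1e-8, rel=1e-8)
                assert res.loc[eff, "eta2g"] == pytest.approx(g_o, abs=1e-10)

    def test_interaction_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            Y = rng.normal(size=(12, 2, 2))
            res = t.rm_anova(Y, ["A", "B"]).set_index("effect")
            dd = (Y[:, 0, 0] - Y[:, 0, 1]) - (Y[:, 1, 0] - Y[:, 1, 1])
            tt = t.one_sample_t(dd, 0.0)
            assert res.loc["A:B", "F"] == pytest.approx(tt.stat**2, abs=1e-8, rel=1e-8)

    def test_matches_pingouin(self):
        """Independent library cross-check of F, p and generalized eta
        squared for a two-way within design."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 15
        Y = rng.normal(size=(n, 2, 2)) + np.array([[0.0, 0.3], [0.5, 1.2]])[None]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 4),
                "A": np.tile(np.repeat(["a1", "a2"], 2), n),
                "B": np.tile(["b1", "b2"], 2 * n),
                "y": Y.reshape(-1),
            }
        )
        pg = pingouin.rm_anova(
            data=long, dv="y", within=["A", "B"], subject="subject",
            detailed=True, effsize="ng2",
        ).set_index("Source")
        res = t.rm_anova(Y, ["A", "B"]).set_index("effect")
        for mine, theirs in (("A", "A"), ("B", "B"), ("A:B", "A * B")):
            assert res.loc[mine, "F"] == pytest.approx(pg.loc[theirs, "F"], rel=1e-6)
            assert res.loc[mine, "p"] == pytest.approx(pg.loc[theirs, "p_unc"], rel=1e-6)
            assert res.loc[mine, "eta2g"] == pytest.approx(pg.loc[theirs, "ng2"], rel=1e-6)

    def test_three_way_runs_and_eta_bounded(self):
        rng = np.random.default_rng(9)
        res = t.rm_anova(rng.normal(size=(10, 2, 2, 2)), ["A", "B", "C"])
        assert len(res) == 7
        assert ((res["eta2g"] >= 0) & (res["eta2g"] <= 1)).all()

    def test_unbalanced_rejected(self):
        Y = np.random.default_rng(0).normal(size=(6, 2, 2))
        Y[2, 1, 1] = np.nan
        with pytest.raises(ValueError, match="unbalanced"):
            t.rm_anova(Y, ["A", "B"])


class TestTTests:
    def test_published_classifier_summaries(self):
        """Accuracy summaries (mean, SD, n) against 50% chance reproduce
        the printed t statistics."""
        res = t.summary_t_vs_chance(80.3, 17.4, 33, chance=50.0)
        assert round(res.stat, 1) == 10.0
        assert res.df == (32,)
        res = t.summary_t_vs_chance(82.6, 16.6, 33, chance=50.0)
        assert round(res.stat, 1) == 11.3
        assert res.p < 0.001

    def test_all_zero_diffs(self):
        res = t.paired_t(np.ones(8), np.ones(8))
        assert res.stat == 0.0 and res.d == 0.0

    def test_zero_variance_nonzero_mean_degenerate(self):
        res = t.one_sample_t(np.full(6, 2.0), 0.0)
        assert np.isinf(res.stat) and res.stat > 0
        assert res.p == 0.0

    def test_paired_equals_one_sample_on_diffs(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = t.paired_t(x, y)
        b = t.one_sample_t(x - y, 0.0)
        assert a.stat == pytest.approx(b.stat)
        assert a.p == pytest.approx(b.p)
        # scipy cross-check
        sp = sps.ttest_rel(x, y)
        assert a.stat == pytest.approx(sp.statistic)
        assert a.p == pytest.approx(sp.pvalue)


class TestTrialwiseCorr:
    def make_trials(self, rng, n_subj=8, n_trials=12, rho=0.0):
        rows = []
        for s in range(n_subj):
            x = rng.normal(size=n_trials)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n_trials)
            rows.append(pd.DataFrame({"subject": s, "evidence": x, "vividness": y}))
        return pd.concat(rows, ignore_index=True)

    def test_perfect_correlation_hits_clip_bound(self):
        rng = np.random.default_rng(0)
        df = self.make_trials(rng, rho=0.0)
        df["vividness"] = df["evidence"]
        res = t.trialwise_corr_test(df)
        assert res.extra["mean_z"] == pytest.approx(np.arctanh(1 - 1e-7))
        # all z sit at the clip bound: zero group variance, degenerate t
        assert res.stat > 0 and np.isinf(res.stat)

    def test_zero_variance_subject_excluded(self):
        rng = np.random.default_rng(1)
        df = self.make_trials(rng, n_subj=6, rho=0.5)
        df.loc[df["subject"] == 0, "vividness"] = 3.0
        res = t.trialwise_corr_test(df)
        assert res.extra["n_excluded"] == 1
        assert res.df == (4,)

    def test_identical_r_across_subjects_zero_variance_path(self):
        # all subjects r = 0.5 exactly -> group sd of z is 0 -> undefined t
        base_x = np.array([0.0, 1.0, 2.0, 3.0])
        base_y = np.array([0.0, 1.0, 0.0, 1.0])
        r = np.corrcoef(base_x, base_y)[0, 1]
        rows = [
            pd.DataFrame({"subject": s, "evidence": base_x, "vividness": base_y})
            for s in range(5)
        ]
        res = t.trialwise_corr_test(pd.concat(rows, ignore_index=True))
        assert res.extra["mean_z"] == pytest.approx(np.arctanh(r))
        assert np.isinf(res.stat)  # zero-variance path, logged as degenerate

    def test_type_one_error_calibrated(self):
        """Null simulation: independent evidence and ratings at n=33
        subjects; rejection rate of the group test stays near 5%."""
        rng = np.random.default_rng(99)
        n_rep = 400
        rejections = 0
        for _ in range(n_rep):
            zs = np.arctanh(
                np.clip(
                    [
                        np.corrcoef(rng.normal(size=10), rng.normal(size=10))[0, 1]
                        for _ in range(33)
                    ],
                    -1 + 1e-7,
                    1 - 1e-7,
                )
            )
            p = sps.ttest_1samp(zs, 0.0).pvalue
            rejections += p < 0.05
        rate = rejections / n_rep
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < half + 1e-12


class TestSkippedSpearman:
    def test_clean_data_equals_plain_spearman(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=33)
        y = 0.5 * x + rng.normal(scale=0.8, size=33)
        res = t.skipped_spearman(x, y, n_boot=200, seed=1)
        assert len(res.outliers) == 0
        plain = sps.spearmanr(x, y).statistic
        assert res.stat == pytest.approx(plain, abs=1e-12)

    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = t.skipped_spearman(x, x, n_boot=100, seed=0)
        assert res.stat == 1.0
        assert res.ci[1] == 1.0

    def test_gross_outliers_flagged_and_resisted(self):
        """30 correlated points plus 3 opposing gross outliers: the
        skipped estimate stays near the clean Spearman while all-points
        Pearson is dragged away."""
        rng = np.random.default_rng(7)
        n = 30
        x = rng.normal(size=n)
        y = 0.6 * x + 0.8 * rng.normal(size=n)
        r_clean = sps.spearmanr(x, y).statistic
        xo = np.concatenate([x, [4.5, 5.0, 5.5]])
        yo = np.concatenate([y, [-5.0, -5.5, -6.0]])
        res = t.skipped_spearman(xo, yo, n_boot=200, seed=3)
        assert set(res.outliers) >= {30, 31, 32}
        assert abs(res.stat - r_clean) < 0.15
        assert abs(np.corrcoef(xo, yo)[0, 1] - r_clean) > 0.3

    def test_translation_common_scale_and_flip_invariance(self):
        """The projection outlier rule commutes with translations, common
        rescaling and axis sign flips (it is not invariant under
        anisotropic affine maps, which reshape the point cloud)."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        a = t.skipped_spearman(x, y, n_boot=50, seed=2)
        b = t.skipped_spearman(3.0 * x - 7.0, 3.0 * y + 2.0, n_boot=50, seed=2)
        assert a.stat == pytest.approx(b.stat, abs=1e-12)
        np.testing.assert_array_equal(a.outliers, b.outliers)
        c = t.skipped_spearman(-x, y, n_boot=50, seed=2)
        assert c.stat == pytest.approx(-a.stat, abs=1e-12)
        np.testing.assert_array_equal(c.outliers, a.outliers)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            t.skipped_spearman(np.arange(5.0), np.arange(5.0))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = t.skipped_spearman(x, y, n_boot=500, seed=4)
        assert res.ci[0] <= res.stat <= res.ci[1]

    def test_determinism(self):
        rng = np.random.default_rng(31)
        x, y = rng.normal(size=15), rng.normal(size=15)
        a = t.skipped_spearman(x, y, n_boot=100, seed=9)
        b = t.skipped_spearman(x, y, n_boot=100, seed=9)
        assert a.stat == b.stat and a.ci == b.ci
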
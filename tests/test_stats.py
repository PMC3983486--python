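"""Split-plot ANOVA, correlation machinery, and their calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socialfeedback import (
    fisher_z_independent,
    hierarchical_f_change,
    hotelling_williams_t,
    one_sample_t,
    pearson_with_ci,
    split_plot_anova,
)


def _long_table(values_by_subject, groups, within_levels=("a", "b"),
                factor="w", group_factor="g"):
    """Build a tidy one-within/one-between score table."""
    rows = []
    for sid, (vals, grp) in enumerate(zip(values_by_subject, groups)):
        for lev, v in zip(within_levels, vals):
            rows.append(
                {"participant_id": f"s{sid}", factor: lev, group_factor: grp,
                 "score": v}
            )
    return pd.DataFrame(rows)


class TestSplitPlotAnova:
    def test_f_equals_t_squared_between_only(self):
        """For a single 2-level between factor the ANOVA F equals the
        squared pooled-variance independent-samples t."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            n1, n2 = rng.integers(8, 20, 2)
            y = np.r_[rng.normal(0, 1, n1), rng.normal(0.7, 1, n2)]
            g = ["A"] * n1 + ["B"] * n2
            df = pd.DataFrame(
                {"participant_id": [f"s{i}" for i in range(n1 + n2)],
                 "g": g, "score": y}
            )
            res = split_plot_anova(df, "score", within=[], between=["g"])
            t, p = sps.ttest_ind(y[:n1], y[n1:])
            eff = {r.effect: r for r in res}["g"]
            assert math.isclose(eff.F, t**2, rel_tol=1e-9)
            assert math.isclose(eff.p, p, rel_tol=1e-9)
            assert eff.df_den == n1 + n2 - 2

    def test_duplicated_cell_gives_zero_within_f(self):
        """If every subject's two within cells are identical the within
        main effect is exactly zero."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=20)
        table = _long_table([(v, v) for v in vals], ["A"] * 10 + ["B"] * 10)
        res = split_plot_anova(table, "score", within=["w"], between=["g"])
        eff = {r.effect: r for r in res}["w"]
        assert eff.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_pingouin_mixed_anova(self):
        """One within x one between balanced design agrees with an
        independent mixed-ANOVA implementation (F, df, p, partial eta
        squared); balanced because the reference uses weighted means while
        this package reports Type III (unweighted) tests."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        n1, n2 = 15, 15
        subj, within, grp, score = [], [], [], []
        for i in range(n1 + n2):
            g = "A" if i < n1 else "B"
            base = rng.normal(0.5 if g == "B" else 0.0, 1.0)
            for w, shift in (("a", 0.0), ("b", 0.6)):
                subj.append(f"s{i}")
                within.append(w)
                grp.append(g)
                score.append(base + shift + rng.normal(0, 0.5))
        df = pd.DataFrame(
            {"participant_id": subj, "w": within, "g": grp, "score": score}
        )
        res = {r.effect: r for r in
               split_plot_anova(df, "score", within=["w"], between=["g"])}
        ref = pg.mixed_anova(df, dv="score", within="w", between="g",
                             subject="participant_id").set_index("Source")
        for ours, theirs in (("g", "g"), ("w", "w"), ("w:g", "Interaction")):
            assert res[ours].F == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert res[ours].p == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)
            assert res[ours].partial_eta_sq == pytest.approx(
                ref.loc[theirs, "np2"], rel=1e-6
            )
            assert res[ours].df_num == ref.loc[theirs, "DF1"]
            assert res[ours].df_den == ref.loc[theirs, "DF2"]

    def test_balanced_design_matches_textbook_decomposition(self):
        """For a balanced one-within/one-between design the classic
        sums-of-squares decomposition (effects + two error strata = total
        SS) reproduces the reported F and partial eta squared values."""
        rng = np.random.default_rng(3)
        n_per = 12
        rows = []
        for i in range(2 * n_per):
            g = "A" if i < n_per else "B"
            for w, shift in (("a", 0.0), ("b", 0.8)):
                rows.append({"participant_id": f"s{i}", "w": w, "g": g,
                             "score": rng.normal(shift + (g == "B") * 0.4, 1.0)})
        df = pd.DataFrame(rows)
        y = df.set_index(["participant_id", "w"])["score"]
        grand = y.mean()
        subj_mean = y.groupby("participant_id").mean()
        g_of = df.drop_duplicates("participant_id").set_index("participant_id")["g"]
        g_mean = df.groupby("g")["score"].mean()
        l_mean = df.groupby("w")["score"].mean()
        lg_mean = df.groupby(["w", "g"])["score"].mean()
        N = 2 * n_per

        ss_g = 2 * sum(n_per * (g_mean[g] - grand) ** 2 for g in ("A", "B"))
        ss_sg = 2 * sum(
            (subj_mean[s] - g_mean[g_of[s]]) ** 2 for s in subj_mean.index
        )
        ss_w = N * sum((l_mean[l] - grand) ** 2 for l in ("a", "b"))
        ss_wg = sum(
            n_per * (lg_mean[(l, g)] - l_mean[l] - g_mean[g] + grand) ** 2
            for l in ("a", "b") for g in ("A", "B")
        )
        ss_ws = sum(
            (y[(s, l)] - subj_mean[s] - lg_mean[(l, g_of[s])] + g_mean[g_of[s]]) ** 2
            for s in subj_mean.index for l in ("a", "b")
        )
        ss_total = ((y - grand) ** 2).sum()
        assert (ss_g + ss_sg + ss_w + ss_wg + ss_ws) == pytest.approx(
            ss_total, rel=1e-8
        )

        res = {r.effect: r for r in
               split_plot_anova(df, "score", within=["w"], between=["g"])}
        assert res["g"].F == pytest.approx(ss_g / (ss_sg / (N - 2)), rel=1e-8)
        assert res["w"].F == pytest.approx(ss_w / (ss_ws / (N - 2)), rel=1e-8)
        assert res["w:g"].F == pytest.approx(ss_wg / (ss_ws / (N - 2)), rel=1e-8)
        assert res["g"].partial_eta_sq == pytest.approx(
            ss_g / (ss_g + ss_sg), rel=1e-8
        )
        assert res["w"].partial_eta_sq == pytest.approx(
            ss_w / (ss_w + ss_ws), rel=1e-8
        )

    def test_error_df_for_study_group_sizes(self):
        """27/24/28/25 in a 2x2 between design -> error df 100; 27/28 with
        one between factor -> error df 53."""
        rng = np.random.default_rng(4)
        rows = []
        sizes = {("German", "Berlin"): 27, ("German", "Beijing"): 24,
                 ("Chinese", "Berlin"): 28, ("Chinese", "Beijing"): 25}
        i = 0
        for (c, p), n in sizes.items():
            for _ in range(n):
                for t in ("self", "other"):
                    rows.append({"participant_id": f"s{i}", "target": t,
                                 "culture": c, "place": p,
                                 "score": rng.normal()})
                i += 1
        df = pd.DataFrame(rows)
        res = split_plot_anova(df, "score", within=["target"],
                               between=["culture", "place"])
        assert all(r.df_den == 100 for r in res)

        berlin = df[df["place"] == "Berlin"]
        res2 = split_plot_anova(berlin, "score", within=["target"],
                                between=["culture"])
        assert all(r.df_den == 53 for r in res2)

    def test_non_two_level_within_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["s0"] * 3, "w": ["a", "b", "c"],
             "g": ["A"] * 3, "score": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="2 levels"):
            split_plot_anova(df, "score", within=["w"], between=["g"])


class TestOneSampleT:
    def test_against_scipy_and_df(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 1.0, 104)
        t, df, p = one_sample_t(x, 0.0)
        t_ref, p_ref = sps.ttest_1samp(x, 0.0)
        assert df == 103
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_mean_equals_null(self):
        t, df, p = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert t == 0.0 and p == 1.0

    def test_zero_variance_off_null(self):
        t, df, p = one_sample_t([2.0, 2.0, 2.0], 0.0)
        assert np.isinf(t) and t > 0 and p == 0.0


class TestPearsonCI:
    def test_printed_interval_r025(self):
        """A correlation of 0.25 at n = 104 has 95% CI (0.06, 0.42)."""
        lo, hi = _ci_for(0.25, 104)
        assert round(lo, 2) == 0.06
        assert round(hi, 2) == 0.42

    def test_printed_interval_r052(self):
        lo, hi = _ci_for(0.52, 104)
        assert round(lo, 2) == 0.36
        assert round(hi, 2) == 0.65

    def test_zero_r_symmetric(self):
        lo, hi = _ci_for(0.0, 50)
        assert math.isclose(lo, -hi, rel_tol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_coverage_at_nominal_95(self):
        """~95% of Fisher CIs contain rho over simulated bivariate-normal
        samples (n = 104, rho = 0.25); accept 93-97%."""
        rng = np.random.default_rng(5)
        rho, n, reps = 0.25, 104, 2000
        cov = [[1, rho], [rho, 1]]
        hits = 0
        for _ in range(reps):
            x, y = rng.multivariate_normal([0, 0], cov, n).T
            res = pearson_with_ci(x, y)
            hits += res.ci_low <= rho <= res.ci_high
        assert 0.93 <= hits / reps <= 0.97


def _ci_for(r_target, n):
    """Construct a sample with an exact correlation, return its CI."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=n)
    y0 = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    y0 = y0 - y0.mean()
    y0 = y0 - x * (x @ y0) / (x @ x)
    y0 /= np.sqrt(y0 @ y0 / n)
    y = r_target * x + np.sqrt(1 - r_target**2) * y0
    res = pearson_with_ci(x, y)
    assert res.r == pytest.approx(r_target, abs=1e-10)
    return res.ci_low, res.ci_high


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_independent(0.4, 30, 0.4, 50)
        assert z == 0.0 and p == 1.0

    def test_two_group_example(self):
        """r1 = 0.05 (n=27) vs r2 = 0.53 (n=28) gives |z| ~ 1.89."""
        z, p = fisher_z_independent(0.05, 27, 0.53, 28)
        assert abs(abs(z) - 1.89) < 0.01
        assert 0.05 < p < 0.07

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_independent(1.0, 30, 0.2, 30)

    def test_p_calibrated_against_permutation(self):
        """The analytic p of the independent-correlation comparison agrees
        with a group-label permutation oracle at n = 50 per group."""
        rng = np.random.default_rng(6)
        n = 50
        cov1 = [[1, 0.5], [0.5, 1]]
        cov2 = [[1, 0.1], [0.1, 1]]
        d1 = rng.multivariate_normal([0, 0], cov1, n)
        d2 = rng.multivariate_normal([0, 0], cov2, n)
        r1 = np.corrcoef(d1.T)[0, 1]
        r2 = np.corrcoef(d2.T)[0, 1]
        z_obs, p_analytic = fisher_z_independent(r1, n, r2, n)
        pooled = np.vstack([d1, d2])
        count = 0
        reps = 2000
        for _ in range(reps):
            idx = rng.permutation(2 * n)
            a, b = pooled[idx[:n]], pooled[idx[n:]]
            za = np.arctanh(np.corrcoef(a.T)[0, 1])
            zb = np.arctanh(np.corrcoef(b.T)[0, 1])
            z_perm = (za - zb) / np.sqrt(2 / (n - 3))
            count += abs(z_perm) >= abs(z_obs)
        p_perm = count / reps
        assert abs(p_perm - p_analytic) < 0.05


class TestWilliams:
    def test_equal_correlations_give_zero(self):
        t, df, p = hotelling_williams_t(0.3, 0.3, 0.1, 50)
        assert t == 0.0 and p == 1.0

    def test_study_sized_example(self):
        """r12=0.32, r13=0.02, r23=-0.01 at n=104: t ~ 2.22, df = 101."""
        t, df, p = hotelling_williams_t(0.32, 0.02, -0.01, 104)
        assert df == 101
        assert abs(t - 2.22) < 0.01
        assert 0.02 < p < 0.04

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            hotelling_williams_t(0.9, -0.9, 0.9, 50)

    def test_type_i_error_calibrated(self):
        """Under the null (r12 = r13) with r23 = 0.3, n = 100, the rejection
        rate at alpha = 0.05 stays within [0.03, 0.07] over 2000 reps."""
        rng = np.random.default_rng(7)
        n, reps = 100, 2000
        rho = 0.2
        cov = np.array([[1, rho, rho], [rho, 1, 0.3], [rho, 0.3, 1]])
        rejections = 0
        for _ in range(reps):
            d = rng.multivariate_normal(np.zeros(3), cov, n)
            R = np.corrcoef(d.T)
            t, df, p = hotelling_williams_t(R[0, 1], R[0, 2], R[1, 2], n)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestFChange:
    def test_study_sized_df(self):
        """One base predictor plus one added at n = 104 -> df (1, 101)."""
        rng = np.random.default_rng(8)
        y = rng.normal(size=104)
        x1, x2 = rng.normal(size=(2, 104))
        f, (d1, d2), p = hierarchical_f_change(y, [x1], [x2])
        assert (d1, d2) == (1, 101)

    def test_no_added_variance_gives_near_zero_f(self):
        rng = np.random.default_rng(9)
        x1 = rng.normal(size=200)
        y = 0.5 * x1 + rng.normal(size=200)
        # added predictor = base + tiny orthogonal perturbation
        x2 = x1 + 1e-6 * rng.normal(size=200)
        f, _, p = hierarchical_f_change(y, [x1], [x2])
        assert f < 4.0  # chance-level: no systematic added variance
        assert p > 0.01

    def test_against_sum_of_squares_oracle(self):
        """F_change matches a direct residual-sum-of-squares computation on
        random designs."""
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(30, 80))
            k_base = int(rng.integers(1, 3))
            k_add = int(rng.integers(1, 3))
            Xb = rng.normal(size=(n, k_base))
            Xa = rng.normal(size=(n, k_add))
            y = Xb @ rng.normal(size=k_base) + 0.3 * Xa @ rng.normal(size=k_add) \
                + rng.normal(size=n)

            def rss(X):
                X1 = np.column_stack([np.ones(n), X])
                beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
                return ((y - X1 @ beta) ** 2).sum()

            rss_base = rss(Xb)
            rss_full = rss(np.column_stack([Xb, Xa]))
            df_den = n - (k_base + k_add) - 1
            f_oracle = ((rss_base - rss_full) / k_add) / (rss_full / df_den)
            f, (d1, d2), p = hierarchical_f_change(y, list(Xb.T), list(Xa.T))
            assert f == pytest.approx(f_oracle, rel=1e-8)
            assert (d1, d2) == (k_add, df_den)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="rank"):
            hierarchical_f_change(y, [x], [x])
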
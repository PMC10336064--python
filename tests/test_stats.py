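"""Group comparisons, covariate-adjusted models and FDR correction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from audphon import (
    chi_square,
    compare_groups,
    fdr_adjust,
    fit_group_model,
    predict_phonology,
)
from audphon.stats import CollinearityError


def exact_ranksum_p(x, y):
    """Enumerate all rank assignments; exact two-sided p for the
    Mann-Whitney U of the first sample (tie-free data only)."""
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestCompareGroups:
    def test_tiny_sample_exact_enumeration(self):
        """x=[1,2], y=[3,4]: U = 0 and exact two-sided p = 1/3."""
        res = compare_groups([1, 2], [3, 4])
        assert res.method == "wilcoxon_ranksum"
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3)
        assert res.p_two_sided == pytest.approx(exact_ranksum_p([1, 2], [3, 4]))

    def test_ranksum_matches_enumeration_oracle(self):
        """Exact rank-sum p equals brute-force enumeration for n <= 8."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            n1, n2 = rng.integers(2, 8, size=2)
            x = rng.permutation(40)[: n1 + n2].astype(float)
            y = list(x[n1:])
            x = list(x[:n1])
            res = compare_groups(x, y, force_method="wilcoxon_ranksum")
            assert res.p_two_sided == pytest.approx(exact_ranksum_p(x, y))

    def test_identical_samples_p_one(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4],
                             force_method="wilcoxon_ranksum")
        assert res.p_two_sided == pytest.approx(1.0)

    def test_power_under_unit_shift(self):
        """1-SD mean shift, n = 100 per group: rejection rate >= 99% at
        alpha = 0.01 over 200 replicates."""
        rng = np.random.default_rng(1)
        rejections = sum(
            compare_groups(rng.normal(1, 1, 100), rng.normal(0, 1, 100)
                           ).p_two_sided < 0.01
            for _ in range(200)
        )
        assert rejections >= 198

    def test_null_type_one_error_calibrated(self):
        """Both groups from the same distribution: rejection rate at
        alpha = 0.05 within [0.03, 0.07] over 1000 replicates."""
        rng = np.random.default_rng(2)
        rej = sum(
            compare_groups(rng.normal(size=20), rng.normal(size=20)
                           ).p_two_sided < 0.05
            for _ in range(1000)
        )
        assert 30 <= rej <= 70

    def test_welch_chosen_for_normal_data(self):
        rng = np.random.default_rng(3)
        res = compare_groups(rng.normal(0, 1, 40), rng.normal(0, 2, 35))
        assert res.method == "t_welch"
        assert res.df is not None and res.df != int(res.df)  # fractional df

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    def test_chi_square_contingency(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.p_two_sided == pytest.approx(1.0)


class TestGroupModel:
    @staticmethod
    def simulate(n=60, delta=1.0, beta_h=0.0, beta_c=0.0, seed=0):
        rng = np.random.default_rng(seed)
        group = np.array(["aphasia"] * (n // 2) + ["control"] * (n // 2))
        hearing = rng.normal(30, 9, n)
        cognition = rng.normal(0, 1, n)
        score = (delta * (group == "aphasia") + beta_h * hearing
                 + beta_c * cognition + rng.normal(0, 1, n))
        return pd.DataFrame(dict(group=group, score=score, hearing=hearing,
                                 cognition=cognition))

    def test_recovers_pure_group_shift(self):
        hits, cov_ns = 0, 0
        n_rep = 30
        for rep in range(n_rep):
            df = self.simulate(delta=1.0, seed=rep)
            mf = fit_group_model(df, "score")
            if abs(mf.params["group"] - 1.0) <= 3 * mf.bse["group"]:
                hits += 1
            if mf.term_p["hearing"] > 0.05 and mf.term_p["cognition"] > 0.05:
                cov_ns += 1
        assert hits >= 0.9 * n_rep
        assert cov_ns >= 0.8 * n_rep  # ~alpha each, jointly a bit lower

    def test_constant_shift_only_moves_intercept(self):
        df = self.simulate(seed=5)
        mf1 = fit_group_model(df, "score")
        df2 = df.assign(score=df["score"] + 10.0)
        mf2 = fit_group_model(df2, "score")
        assert mf2.params["Intercept"] - mf1.params["Intercept"] == pytest.approx(10.0)
        for term in ("group", "hearing", "cognition"):
            assert mf2.params[term] == pytest.approx(mf1.params[term])
            assert mf2.term_f[term] == pytest.approx(mf1.term_f[term])

    def test_smooth_agrees_with_linear_when_truth_linear(self):
        df = self.simulate(n=80, delta=0.8, beta_h=0.05, seed=9)
        lin = fit_group_model(df, "score")
        smo = fit_group_model(df, "score", smooth_hearing=True)
        assert abs(smo.params["group"] - lin.params["group"]) <= lin.bse["group"]

    def test_collinear_design_raises(self):
        df = self.simulate(seed=11)
        df["cognition"] = 2.0 * df["hearing"] - 1.0
        with pytest.raises(CollinearityError):
            fit_group_model(df, "score")


class TestPhonologyPrediction:
    def test_recovers_generating_link(self):
        """Phonology generated with slope -2.70 on the log RTD threshold
        is recovered within 3 SEs."""
        rng = np.random.default_rng(0)
        n = 29
        logrtd = rng.normal(4.4, 0.6, n)
        hearing = rng.normal(30, 9, n)
        cognition = rng.normal(-1.5, 1, n)
        phon = 32 - 2.70 * logrtd + 0.5 * cognition + rng.normal(0, 1.0, n)
        df = pd.DataFrame(dict(group="aphasia", log_rtd=logrtd,
                               hearing=hearing, cognition=cognition,
                               phonology=phon))
        mf = predict_phonology(df, "phonology", "log_rtd")
        assert mf.params["log_rtd"] < 0
        assert abs(mf.params["log_rtd"] - (-2.70)) <= 3 * mf.bse["log_rtd"]

    def test_null_predictor_p_uniform(self):
        """With no generating effect the predictor's p-value is uniform
        (Kolmogorov-Smirnov at alpha = 0.01 over 500 replicates)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        ps = []
        for _ in range(500):
            n = 25
            df = pd.DataFrame(dict(
                task=rng.normal(size=n), hearing=rng.normal(size=n),
                cognition=rng.normal(size=n), y=rng.normal(size=n)))
            ps.append(predict_phonology(df, "y", "task", group_col=None
                                        ).term_p["task"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_perfect_collinearity_raises(self):
        rng = np.random.default_rng(5)
        n = 20
        hearing = rng.normal(size=n)
        df = pd.DataFrame(dict(task=rng.normal(size=n), hearing=hearing,
                               cognition=3 * hearing, y=rng.normal(size=n)))
        with pytest.raises(CollinearityError):
            predict_phonology(df, "y", "task", group_col=None)


def bh_adjust_oracle(p):
    """Step-up BH by the textbook recursion (independent reference)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        adj[i] = prev
    return adj


class TestFdr:
    def test_two_p_values_by_hand(self):
        assert fdr_adjust([0.003, 0.181]) == pytest.approx([0.006, 0.181])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.42]) == pytest.approx([0.42])

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 11))
            assert fdr_adjust(p) == pytest.approx(bh_adjust_oracle(p))

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=10)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.3])
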
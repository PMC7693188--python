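"""Regional statistics: regressions, partial correlation, BH-FDR, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from parcelpvc import (
    bh_fdr,
    compare_groups,
    group_summaries,
    multivariable_regression,
    normalize_parcel_trajectories,
    partial_correlation,
    r_threshold_from_p,
    simple_regression,
)
from parcelpvc.phantom import CohortTable
from parcelpvc.stats import p_from_r


def _cohort(df_extra, n, seed=0):
    rng = np.random.default_rng(seed)
    moca = rng.integers(0, 31, n)
    group = np.select([moca <= 10, moca <= 19], ["0-10", "11-19"], "20-30")
    base = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.normal(74, 6, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.normal(15, 3, n),
            "moca": moca,
            "moca_group": group,
        }
    )
    for k, v in df_extra.items():
        base[k] = v
    return CohortTable(base)


class TestSimpleRegression:
    def test_exact_negative_line(self):
        x = np.linspace(2, 3, 10)
        res = simple_regression(x, 5 - 2 * x)
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-2.0)
        assert res.p < 1e-20

    def test_five_point_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.5, 3.0, 4.5, 4.0])
        res = simple_regression(x, y)
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        t = r_oracle * np.sqrt(3 / (1 - r_oracle**2))
        p_oracle = 2 * sps.t.sf(abs(t), 3)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(400):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            ps.append(simple_regression(x, y).p)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 < frac < 0.10

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            simple_regression(np.ones(5), np.arange(5.0))


class TestMultivariableRegression:
    COEF = {"thickness": -0.5, "education": -0.03, "age": 0.01, "sex": -0.1, "moca": -0.04}

    def _noiseless(self, n=60):
        rng = np.random.default_rng(1)
        thick = rng.normal(2.4, 0.3, n)
        c = _cohort({"thickness_7": thick}, n, seed=1)
        y = 1.5 + sum(
            self.COEF[k] * c.df[k if k != "thickness" else "thickness_7"].to_numpy(dtype=float)
            for k in self.COEF
        )
        c.df["suvr_7"] = y
        return c

    def test_noiseless_recovery(self):
        res = multivariable_regression(self._noiseless(), 7)
        for k, v in self.COEF.items():
            assert res.params[k] == pytest.approx(v, abs=1e-9)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        summary = res.summary()
        assert (summary["ci_low"] <= summary["coef"]).all()
        assert (summary["coef"] <= summary["ci_high"]).all()

    def test_rank_deficiency_names_column(self):
        c = self._noiseless()
        c.df["moca"] = c.df["thickness_7"]  # duplicated predictor
        with pytest.raises(ValueError, match="rank deficient"):
            multivariable_regression(c, 7)

    def test_statsmodels_agreement_with_noise(self):
        import statsmodels.api as sm

        c = self._noiseless(200)
        rng = np.random.default_rng(9)
        c.df["suvr_7"] = c.df["suvr_7"] + rng.normal(0, 0.2, 200)
        res = multivariable_regression(c, 7)
        X = sm.add_constant(
            c.df[["thickness_7", "education", "age", "sex", "moca"]].astype(float)
        )
        ref = sm.OLS(c.df["suvr_7"], X).fit()
        assert res.params["thickness"] == pytest.approx(ref.params["thickness_7"], rel=1e-12)


class TestPartialCorrelation:
    def test_equals_simple_r_when_covariates_constant(self):
        rng = np.random.default_rng(5)
        n = 40
        thick = rng.normal(2.4, 0.3, n)
        suvr = 2 - 0.4 * thick + rng.normal(0, 0.1, n)
        c = _cohort({"thickness_7": thick, "suvr_7": suvr}, n, seed=5)
        c.df["age"] = 74.0
        c.df["education"] = 15.0
        c.df["sex"] = 1
        c.df["moca"] = 20
        c.df["moca_group"] = "20-30"
        r, _ = partial_correlation(c, 7)
        assert r == pytest.approx(simple_regression(thick, suvr).r, abs=1e-9)

    def test_zero_when_outcome_is_function_of_covariates(self):
        rng = np.random.default_rng(6)
        n = 50
        c = _cohort({"thickness_7": rng.normal(2.4, 0.3, n)}, n, seed=6)
        c.df["suvr_7"] = (
            1 + 0.01 * c.df["age"] - 0.02 * c.df["education"] + 0.1 * c.df["sex"]
        )
        r, _ = partial_correlation(c, 7)
        assert abs(r) < 1e-9

    def test_matrix_inversion_oracle_six_subjects(self):
        # partial r of (x, y) given z from the precision matrix
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([0.5, 1.0, 0.2, 1.5, 0.8, 1.1])
        corr = np.corrcoef([x, y, z])
        prec = np.linalg.inv(corr)
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        c = _cohort({"thickness_7": x, "suvr_7": y, "zcov": z}, 6, seed=7)
        r, p = partial_correlation(c, 7, covariates=("zcov",))
        assert r == pytest.approx(oracle, abs=1e-9)
        assert 0 <= p <= 1

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        n = 60
        thick = rng.normal(2.4, 0.3, n)
        suvr = 2 - 0.4 * thick + rng.normal(0, 0.15, n)
        c = _cohort({"thickness_7": thick, "suvr_7": suvr}, n, seed=11)
        r, p = partial_correlation(c, 7)
        ref = pingouin.partial_corr(
            data=c.df.assign(
                age=c.df["age"].astype(float), sex=c.df["sex"].astype(float),
                education=c.df["education"].astype(float), moca=c.df["moca"].astype(float),
            ),
            x="thickness_7", y="suvr_7",
            covar=["age", "education", "sex", "moca"],
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


class TestBHFDR:
    def test_worked_example(self):
        res = bh_fdr([0.01, 0.02, 0.5], q=0.1)
        assert res.threshold == pytest.approx(0.02)
        assert res.n_rejected == 2
        assert list(res.reject) == [True, True, False]

    def test_all_ones_no_rejections(self):
        res = bh_fdr(np.ones(8), q=0.1)
        assert res.n_rejected == 0 and res.threshold == 0.0

    def test_single_test_reduces_to_q(self):
        assert bh_fdr([0.05], q=0.1).n_rejected == 1
        assert bh_fdr([0.2], q=0.1).n_rejected == 0

    @settings(max_examples=100, deadline=None)
    @given(
        ps=st.lists(st.floats(0, 1), min_size=1, max_size=10),
        q=st.floats(0.01, 0.5),
    )
    def test_agrees_with_brute_force_step_up(self, ps, q):
        res = bh_fdr(ps, q=q)
        m = len(ps)
        sorted_p = np.sort(ps)
        # brute force: largest k such that the k smallest p all fit p(k) <= k q / m
        best_k = 0
        for k in range(1, m + 1):
            if sorted_p[k - 1] <= k * q / m:
                best_k = k
        expected = np.zeros(m, dtype=bool)
        if best_k:
            expected = np.asarray(ps) <= sorted_p[best_k - 1]
        np.testing.assert_array_equal(res.reject, expected)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        ps = rng.uniform(size=40) ** 2
        res = bh_fdr(ps, q=0.1)
        ref_reject, *_ = multipletests(ps, alpha=0.1, method="fdr_bh")
        np.testing.assert_array_equal(res.reject, ref_reject)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_fdr([], q=0.1)
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], q=0.1)


class TestRThreshold:
    def test_p_of_one_gives_zero(self):
        assert r_threshold_from_p(1.0, 75, 4) == pytest.approx(0.0)

    def test_round_trip_identity(self):
        for p in (0.001, 0.037, 0.2):
            r = r_threshold_from_p(p, 75, 4)
            assert p_from_r(r, 75, 4) == pytest.approx(p, abs=1e-9)

    def test_matches_t_quantile_oracle(self):
        p, df = 0.037, 69
        t = sps.t.ppf(1 - p / 2, df)
        assert r_threshold_from_p(p, df + 6, 4) == pytest.approx(
            t / np.sqrt(t**2 + df), abs=1e-12
        )

    def test_df_guard(self):
        with pytest.raises(ValueError):
            r_threshold_from_p(0.05, 5, 4)


class TestGroupSummaries:
    def _cohort_three_groups(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "age": [70.0, 71, 72, 73],
                "sex": [0, 1, 0, 1],
                "education": [12.0, 14, 16, 18],
                "moca": [5, 15, 25, 25],
                "moca_group": ["0-10", "11-19", "20-30", "20-30"],
                "thickness_7": [2.0, 2.2, 2.4, 2.6],
                "suvr_7": [2.0, 1.6, 1.2, 1.4],
            }
        )
        return CohortTable(df)

    def test_single_subject_group_sd_flagged_zero(self):
        summary, per_parcel = group_summaries(self._cohort_three_groups())
        row = summary[(summary["moca_group"] == "0-10")].iloc[0]
        assert row["sd"] == 0.0 and row["sd_undefined"]

    def test_matches_direct_mean_sd(self):
        summary, per_parcel = group_summaries(self._cohort_three_groups())
        row = summary[
            (summary["moca_group"] == "20-30")
            & (summary["measure"] == "amyloid_suvr")
        ].iloc[0]
        assert row["mean"] == pytest.approx(1.3)
        assert row["sd"] == pytest.approx(np.std([1.2, 1.4], ddof=1))

    def test_empty_group_raises(self):
        c = self._cohort_three_groups()
        c.df.loc[c.df["moca_group"] == "0-10", ["moca", "moca_group"]] = [15, "11-19"]
        with pytest.raises(ValueError, match="0-10"):
            group_summaries(c)


class TestCompareGroups:
    def test_fisher_matches_hypergeometric_enumeration(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "age": 70.0,
                "sex": [0] * 10 + [1] * 10,
                "education": 15.0,
                "moca": [5] * 10 + [25] * 10,
                "moca_group": ["0-10"] * 10 + ["20-30"] * 10,
                "thickness_7": 2.0 + np.arange(20) * 0.01,
                "suvr_7": 1.0 + np.arange(20) * 0.01,
            }
        )
        c = CohortTable(df)
        _, p = compare_groups(c, "sex", kind="categorical")
        # table (10,0;0,10): two-sided Fisher p = 2 / C(20,10)
        from math import comb

        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_separated_means_tiny_p(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(40)],
                "age": np.r_[rng.normal(60, 0.01, 20), rng.normal(80, 0.01, 20)],
                "sex": 1,
                "education": 15.0,
                "moca": [5] * 20 + [25] * 20,
                "moca_group": ["0-10"] * 20 + ["20-30"] * 20,
                "thickness_7": 2.0,
                "suvr_7": 1.0,
            }
        )
        _, p = compare_groups(CohortTable(df), "age", kind="continuous")
        assert p < 1e-6


class TestTrajectories:
    def _means(self):
        return pd.DataFrame(
            [
                {"label": 1, "moca_group": "0-10", "thickness_mean": 2.0, "suvr_mean": 2.0},
                {"label": 1, "moca_group": "11-19", "thickness_mean": 2.2, "suvr_mean": 1.6},
                {"label": 1, "moca_group": "20-30", "thickness_mean": 2.4, "suvr_mean": 1.2},
                {"label": 2, "moca_group": "0-10", "thickness_mean": 2.3, "suvr_mean": 1.8},
                {"label": 2, "moca_group": "11-19", "thickness_mean": 2.5, "suvr_mean": 1.5},
                {"label": 2, "moca_group": "20-30", "thickness_mean": 2.5, "suvr_mean": 1.0},
            ]
        )

    def test_high_moca_anchor_maps_to_unit_point(self):
        out = normalize_parcel_trajectories(self._means())
        anchor = out[(out["moca_group"] == "20-30")]
        np.testing.assert_allclose(anchor["norm_suvr"], 1.0)
        np.testing.assert_allclose(anchor["delta_thickness"], 0.0)

    def test_arithmetic_and_tie_convention(self):
        out = normalize_parcel_trajectories(self._means()).set_index(["label", "moca_group"])
        assert out.loc[(1, "0-10"), "norm_suvr"] == pytest.approx(2.0 / 1.2)
        assert out.loc[(1, "0-10"), "delta_thickness"] == pytest.approx(-0.4)
        # parcel 1: middle 2.2 < high 2.4 -> thinner; parcel 2: tie -> thinner
        assert (out["category"] == "thinner").all()

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="three group"):
            normalize_parcel_trajectories(self._means().iloc[:-1])
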
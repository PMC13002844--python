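"""Demographics tests, ANCOVA, FDR, factor scores and correlation CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mstates import (
    FactorMap,
    ancova_group,
    bh_fdr,
    chi2_2x2,
    hamd24_factor_scores,
    pearson_ci,
    pearson_ci_from_summary,
    run_group_analysis,
    summary_ttest,
    ttest_from_data,
)


class TestFactorScores:
    def test_all_zero_items(self):
        scores = hamd24_factor_scores(np.zeros((3, 24)))
        assert (scores.to_numpy() == 0).all()

    def test_duplicate_item_rejected(self):
        with pytest.raises(ValueError):
            FactorMap({"a": (1, 2), "b": (2, 3)})
        with pytest.raises(ValueError):
            FactorMap({"a": (0,)})

    def test_sums_match_oracle(self, rng):
        items = rng.integers(0, 5, (10, 24)).astype(float)
        scores = hamd24_factor_scores(items)
        fm = FactorMap.default()
        for name, idx in fm.factors.items():
            expect = items[:, [i - 1 for i in idx]].sum(axis=1)
            np.testing.assert_allclose(scores[name], expect)
        np.testing.assert_allclose(scores["hamd_total"], items.sum(axis=1))

    def test_missing_item_flags_factor(self):
        items = np.zeros((2, 24))
        items[0, 9] = np.nan  # item 10: anxiety/somatization
        scores = hamd24_factor_scores(items)
        assert np.isnan(scores.loc[0, "anxiety_somatization"])
        assert scores.loc[0, "weight"] == 0.0


class TestSummaryTTest:
    # published two-arm demographic rows: (m1, sd1, n1, m2, sd2, n2, t, d);
    # t is matched at the precision attainable from 2-dp summary moments
    @pytest.mark.parametrize(
        "m1,sd1,n1,m2,sd2,n2,t_ref,d_ref",
        [
            (26.40, 7.36, 30, 24.10, 5.99, 40, 1.442, 0.35),
            (14.30, 3.53, 30, 15.85, 2.55, 40, -2.133, 0.52),
        ],
    )
    def test_published_rows(self, m1, sd1, n1, m2, sd2, n2, t_ref, d_ref):
        res = summary_ttest(m1, sd1, n1, m2, sd2, n2)
        assert res.t == pytest.approx(t_ref, abs=5e-3)
        assert abs(round(res.cohen_d, 2)) == d_ref
        assert res.df == n1 + n2 - 2

    def test_equal_means(self):
        res = summary_ttest(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.t == 0.0 and res.cohen_d == 0.0

    def test_zero_variance_convention(self):
        assert summary_ttest(3.0, 0.0, 5, 3.0, 0.0, 5).t == 0.0

    def test_consistency_with_raw_data(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1.2, 30)
        a = ttest_from_data(x, y)
        b = summary_ttest(x.mean(), x.std(ddof=1), 25, y.mean(), y.std(ddof=1), 30)
        assert a.t == pytest.approx(b.t)
        assert a.p == pytest.approx(b.p)


class TestChi2:
    def test_published_sex_table(self):
        res = chi2_2x2(np.array([[8, 22], [16, 24]]), yates=True)
        assert round(res.chi2, 3) == 0.826
        assert res.df == 1

    def test_proportional_table_zero(self):
        assert chi2_2x2(np.array([[10, 20], [20, 40]]), yates=True).chi2 == 0.0

    def test_uncorrected_matches_brute_force(self, rng):
        obs = rng.integers(5, 40, (2, 2)).astype(float)
        res = chi2_2x2(obs, yates=False)
        n = obs.sum()
        expect = 0.0
        for i in range(2):
            for j in range(2):
                e = obs[i].sum() * obs[:, j].sum() / n
                expect += (obs[i, j] - e) ** 2 / e
        assert res.chi2 == pytest.approx(expect)

    def test_zero_marginal_signaled(self):
        with pytest.raises(ValueError):
            chi2_2x2(np.array([[0, 0], [5, 8]]))


class TestAncova:
    def test_denominator_df_at_study_size(self, rng):
        y = rng.normal(size=70)
        arm = np.array(["patient"] * 30 + ["control"] * 40)
        edu = rng.normal(15, 3, 70)
        res = ancova_group(y, arm, edu)
        assert (res.df_num, res.df_denom) == (1, 67)

    def test_null_effect_f_small(self, rng):
        fs = []
        for _ in range(20):
            n = 400
            arm = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
            edu = rng.normal(0, 1, n)
            y = 0.5 * edu + rng.normal(0, 1, n)  # covariate effect, no arm effect
            fs.append(ancova_group(y, arm, edu).f)
        assert np.median(fs) < 1.5

    def test_matches_two_model_rss_oracle(self, rng):
        n = 24
        arm = rng.choice(["a", "b"], n)
        while len(set(arm)) < 2 or min((arm == "a").sum(), (arm == "b").sum()) < 3:
            arm = rng.choice(["a", "b"], n)
        edu = rng.normal(12, 2, n)
        y = rng.normal(0, 1, n) + (arm == "b") * 0.8 + 0.3 * edu
        res = ancova_group(y, arm, edu)
        # independent oracle: two lstsq fits, F from residual sums of squares
        g = (arm == np.unique(arm)[1]).astype(float)
        xf = np.column_stack([np.ones(n), edu, g])
        xr = np.column_stack([np.ones(n), edu])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        f_oracle = (rss(xr) - rss(xf)) / (rss(xf) / (n - 3))
        assert res.f == pytest.approx(f_oracle, rel=1e-9)
        assert res.partial_eta_sq == pytest.approx(
            (rss(xr) - rss(xf)) / rss(xr), rel=1e-9
        )

    def test_eta_f_identity(self, rng):
        n = 40
        arm = np.array(["a"] * 20 + ["b"] * 20)
        y = rng.normal(0, 1, n) + (arm == "b") * 0.7
        edu = rng.normal(0, 1, n)
        res = ancova_group(y, arm, edu)
        assert res.partial_eta_sq == pytest.approx(res.f / (res.f + res.df_denom), rel=1e-9)

    def test_constant_covariate_warns(self, rng):
        y = rng.normal(size=20)
        arm = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.warns(UserWarning):
            res = ancova_group(y, arm, np.full(20, 12.0))
        assert res.df_denom == 18  # one-way ANOVA df


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, pvals):
        adj = bh_fdr(pvals)
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        expect = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expect[i] = running
        np.testing.assert_allclose(adj, expect, atol=1e-12)
        assert np.all(adj >= p - 1e-15)  # adjustment never decreases p
        assert np.all(adj <= 1.0)


class TestPearsonCI:
    # published correlation captions: r, n, CI bounds
    @pytest.mark.parametrize(
        "r,n,lo,hi",
        [
            (-0.403, 30, -0.666, -0.050),
            (-0.423, 30, -0.680, -0.074),
            (0.380, 30, 0.023, 0.651),
        ],
    )
    def test_published_cis(self, r, n, lo, hi):
        res = pearson_ci_from_summary(r, n)
        assert res.ci_low == pytest.approx(lo, abs=1e-3)
        assert res.ci_high == pytest.approx(hi, abs=1e-3)
        assert res.ci_low < r < res.ci_high

    def test_perfectly_linear(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == 1.0 and res.p == 0.0

    def test_data_vs_summary_consistency(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        a = pearson_ci(x, y)
        b = pearson_ci_from_summary(a.r, 50)
        assert a.ci_low == pytest.approx(b.ci_low)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))


def _toy_tables(rng, n_pat=12, n_ctl=14):
    n = n_pat + n_ctl
    subjects = [f"S{i:03d}" for i in range(n)]
    params = []
    trans = []
    for sid in subjects:
        for c in "ABCD":
            params.append(
                {"subject": sid, "class": c, "duration_ms": rng.normal(70, 8),
                 "occurrence_hz": rng.normal(3, 0.4), "coverage_pct": rng.uniform(15, 35)}
            )
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    trans.append({"subject": sid, "from": a, "to": b, "probability": rng.uniform(0.1, 0.5)})
    clinical = pd.DataFrame(
        {
            "subject": subjects,
            "arm": ["patient"] * n_pat + ["control"] * n_ctl,
            "age": rng.normal(25, 6, n).round(),
            "sex": rng.choice(["male", "female"], n),
            "education_years": rng.normal(15, 3, n).round(),
            "hama": np.where([a == "patient" for a in ["patient"] * n_pat + ["control"] * n_ctl],
                              rng.normal(18, 7, n), np.nan),
            "madrs": np.nan,
        }
    )
    for i in range(1, 25):
        clinical[f"hamd{i:02d}"] = np.where(
            clinical["arm"] == "patient", rng.integers(0, 4, n).astype(float), np.nan
        )
    return pd.DataFrame(params), pd.DataFrame(trans), clinical


class TestGroupAnalysis:
    def test_report_bookkeeping(self, rng):
        params, trans, clinical = _toy_tables(rng)
        out = run_group_analysis(params, trans, clinical)
        assert len(out["ancova"]) == 12 + 12  # 4 classes x 3 parameters + 12 transitions
        assert set(out["ancova"]["family"]) == {"duration_ms", "occurrence_hz", "coverage_pct", "transition"}
        assert len(out["demographics"]) == 3
        assert out["ancova"]["df_denom"].eq(12 + 14 - 3).all()

    def test_fdr_within_families(self, rng):
        params, trans, clinical = _toy_tables(rng)
        out = run_group_analysis(params, trans, clinical)
        anc = out["ancova"]
        for fam, grp in anc.groupby("family"):
            np.testing.assert_allclose(
                grp["p_fdr"].to_numpy(), bh_fdr(grp["p"].to_numpy()), atol=1e-12
            )

    def test_unmatched_subjects_dropped(self, rng):
        params, trans, clinical = _toy_tables(rng)
        params = params[params["subject"] != "S000"]
        with pytest.warns(UserWarning, match="dropping"):
            out = run_group_analysis(params, trans, clinical)
        assert out["ancova"]["df_denom"].eq(25 - 3).all()

    def test_correlations_restricted_to_patients(self, rng):
        params, trans, clinical = _toy_tables(rng)
        out = run_group_analysis(params, trans, clinical, correlate_all=True)
        corr = out["correlations"]
        assert (corr["n"] <= 12).all()
        assert set(corr["score"]).issubset({"anxiety_somatization", "hamd_total", "hama", "madrs"})
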
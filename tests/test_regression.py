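import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidlens.regression import (
    TRAIT_TRANSFORMS,
    bh_fdr,
    bonferroni,
    cohort_summary,
    fame_crossref,
    fit_single_lipid,
    run_all_regressions,
    transform_trait,
    venn_overlaps,
)


def _toy_covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(48, 65, n),
            "smoking": pd.Categorical(rng.choice(["ever", "never", "unknown"], n)),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestFitSingleLipid:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 40
        cov = _toy_covariates(n, seed=1)
        lipid = pd.Series(rng.normal(size=n), index=cov.index, name="lip")
        y = pd.Series(
            1.0 + 0.05 * cov["age"].to_numpy() + 0.7 * lipid.to_numpy() + rng.normal(size=n),
            index=cov.index, name="y",
        )
        rec = fit_single_lipid(y, cov, lipid)
        s = cov["smoking"].astype(str)
        X = sm.add_constant(
            np.column_stack([cov["age"], (s == "ever").astype(float),
                             (s == "unknown").astype(float), lipid])
        )
        fit = sm.OLS(y.to_numpy(), X).fit()
        assert rec.effect == pytest.approx(fit.params[-1], abs=1e-10)
        assert rec.se == pytest.approx(fit.bse[-1], abs=1e-10)
        assert rec.p_raw == pytest.approx(fit.pvalues[-1], abs=1e-10)
        assert rec.df_resid == int(fit.df_resid)

    def test_perfect_association(self):
        cov = _toy_covariates(30, seed=2)
        rng = np.random.default_rng(2)
        lipid = pd.Series(rng.normal(size=30), index=cov.index)
        y = 3.0 * lipid + 0.5
        rec = fit_single_lipid(y, cov, lipid)
        assert rec.effect == pytest.approx(3.0, abs=1e-8)
        assert rec.p_raw < 1e-30

    def test_constant_lipid_flagged(self):
        cov = _toy_covariates(20, seed=3)
        lipid = pd.Series(np.ones(20), index=cov.index)
        y = pd.Series(np.random.default_rng(0).normal(size=20), index=cov.index)
        rec = fit_single_lipid(y, cov, lipid)
        assert not rec.ok
        assert np.isnan(rec.p_raw)

    def test_missing_rejected(self):
        cov = _toy_covariates(10)
        lipid = pd.Series(np.r_[np.nan, np.ones(9)], index=cov.index)
        with pytest.raises(ValueError, match="missing"):
            fit_single_lipid(pd.Series(np.ones(10), index=cov.index), cov, lipid)


class TestRunAllRegressions:
    def test_batch_matches_single_fits(self, processed_small, cohort126):
        from lipidlens.simulate import TraitGenSpec, generate_traits

        table = processed_small[0]
        frame, _ = generate_traits(TraitGenSpec(variance_fraction=0.3, seed=2), table, cohort126)
        records, effects = run_all_regressions(frame, table, trait_names=["trait"],
                                               transforms={"trait": "identity"})
        sub = table.analyte_matrix().loc[frame.index]
        for ion in list(sub.columns[:5]):
            rec = fit_single_lipid(frame["trait"], frame, sub[ion])
            row = records[records["ion"] == ion].iloc[0]
            assert row["effect"] == pytest.approx(rec.effect, abs=1e-10)
            assert row["p_raw"] == pytest.approx(rec.p_raw, abs=1e-10)
        assert effects.shape == (sub.shape[1], 1)

    @pytest.fixture()
    def independent_panel(self, cohort126):
        """Factor-free panel: lipids mutually independent (power/null configuration)."""
        from lipidlens.preprocess import preprocess
        from lipidlens.simulate import FeaturePanelSpec, generate_feature_table

        spec = FeaturePanelSpec(
            n_ions=500, n_internal_standards=3, missing_fraction_high=0.0,
            max_low_missing_rate=0.0, rmd_in_range_fraction=1.0,
            n_latent_factors=0, seed=21,
        )
        return preprocess(generate_feature_table(spec, cohort126))[0]

    def test_causal_lipids_rank_first(self, independent_panel, cohort126):
        from lipidlens.simulate import TraitGenSpec, generate_traits

        table = independent_panel
        spec = TraitGenSpec(variance_fraction=0.9, n_causal_lipids=5, effect_size=3.0, seed=6)
        frame, truth = generate_traits(spec, table, cohort126)
        records, _ = run_all_regressions(frame, table, trait_names=["trait"],
                                         transforms={"trait": "identity"})
        causal = set(truth["alpha"].abs().nlargest(5).index)
        top5 = set(records.nsmallest(5, "p_raw")["ion"])
        assert top5 == causal

    def test_null_type_one_error(self, independent_panel, cohort126):
        table = independent_panel
        rng = np.random.default_rng(9)
        rates = []
        for _ in range(4):
            frame = cohort126.copy()
            frame["null"] = rng.normal(size=len(frame))
            records, _ = run_all_regressions(frame, table, trait_names=["null"],
                                             transforms={"null": "identity"})
            rates.append((records["p_raw"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_permuted_trait_rarely_passes_bh(self, processed_small, cohort126):
        table = processed_small[0]
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(10):
            frame = cohort126.copy()
            frame["perm"] = rng.permutation(rng.normal(size=len(frame)))
            records, _ = run_all_regressions(frame, table, trait_names=["perm"],
                                             transforms={"perm": "identity"})
            hits += int((records["p_bh"] < 0.05).sum() > 0)
        assert hits <= 2


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.42]), [0.42])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_invariance(self, pvals):
        p = np.array(pvals)
        perm = np.random.default_rng(0).permutation(len(p))
        adjusted = bh_fdr(p)
        adjusted_perm = bh_fdr(p[perm])
        np.testing.assert_allclose(adjusted_perm, adjusted[perm], atol=1e-12)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bonferroni([-0.1])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bonferroni_significant_subset_of_bh(self, pvals):
        p = np.array(pvals)
        bh = bh_fdr(p)
        bf = bonferroni(p)
        assert np.all(bh <= bf + 1e-12)  # hence Bonferroni hits are BH hits


class TestVennOverlaps:
    @staticmethod
    def _records(sets):
        rows = []
        for trait, ions in sets.items():
            for ion in range(20):
                rows.append({"ion": f"i{ion}", "trait": trait,
                             "p_bh": 0.01 if ion in ions else 0.5})
        return pd.DataFrame(rows)

    def test_disjoint(self):
        rec = self._records({"a": {0, 1}, "b": {2, 3}})
        out = venn_overlaps(rec, ["a", "b"])
        assert out.intersections[("a", "b")] == 0

    def test_identical(self):
        rec = self._records({"a": {0, 1, 2}, "b": {0, 1, 2}})
        out = venn_overlaps(rec, ["a", "b"])
        assert out.intersections[("a", "b")] == 3

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(5)
        sets = {t: set(rng.choice(20, size=rng.integers(0, 15), replace=False).tolist())
                for t in "abcd"}
        rec = self._records(sets)
        out = venn_overlaps(rec, list("abcd"))
        named = {t: {f"i{i}" for i in s} for t, s in sets.items()}
        from itertools import combinations
        universe = set().union(*named.values())
        for r in range(1, 5):
            for subset in combinations("abcd", r):
                inter = set.intersection(*(named[t] for t in subset))
                assert out.intersections[subset] == len(inter)
                exclusive = {
                    e for e in universe
                    if all(e in named[t] for t in subset)
                    and all(e not in named[t] for t in "abcd" if t not in subset)
                }
                assert out.exclusive_regions[subset] == len(exclusive)
        # inclusion-exclusion: exclusive regions partition each trait's set
        for t in "abcd":
            total = sum(v for k, v in out.exclusive_regions.items() if t in k)
            assert total == len(named[t])

    def test_unknown_trait(self):
        rec = self._records({"a": {0}})
        with pytest.raises(ValueError, match="not present"):
            venn_overlaps(rec, ["a", "zz"])


class TestCohortSummary:
    @staticmethod
    def _traits(shift):
        rng = np.random.default_rng(0)
        bmi = np.r_[rng.uniform(20, 24.5, 30), rng.uniform(25.5, 29.5, 30), rng.uniform(30.5, 40, 30)]
        marker = np.r_[rng.normal(0, 1, 30), rng.normal(shift, 1, 30), rng.normal(2 * shift, 1, 30)]
        return pd.DataFrame({"bmi": bmi, "marker": marker})

    def test_identical_groups_null(self):
        t = self._traits(0.0)
        t["marker"] = np.tile(np.arange(30.0), 3)  # same values in every group
        summary, _ = cohort_summary(t, parameters=["marker"])
        assert summary.loc[0, "kw_p_raw"] > 0.95

    def test_large_shift_all_pairs_significant(self):
        summary, pairwise = cohort_summary(self._traits(8.0), parameters=["marker"])
        row = summary.iloc[0]
        assert row["kw_p_raw"] < 1e-10
        letters = {row["lean_letter"], row["overweight_letter"], row["obese_letter"]}
        assert letters == {"A", "B", "C"}
        assert (pairwise["p_bh"] < 0.05).all()

    def test_kw_statistic_matches_scipy_oracle(self):
        from scipy.stats import kruskal

        t = self._traits(1.0)
        summary, _ = cohort_summary(t, parameters=["marker"])
        groups = [
            t.loc[t["bmi"] < 25, "marker"],
            t.loc[(t["bmi"] >= 25) & (t["bmi"] < 30), "marker"],
            t.loc[t["bmi"] >= 30, "marker"],
        ]
        stat, p = kruskal(*groups)
        assert summary.loc[0, "kw_statistic"] == pytest.approx(stat, abs=1e-10)
        assert summary.loc[0, "kw_p_raw"] == pytest.approx(p, abs=1e-12)

    def test_kw_statistic_matches_rank_oracle(self):
        # brute-force rank computation on a small hand dataset (no ties)
        data = pd.DataFrame({
            "bmi": [20, 21, 22, 26, 27, 28, 31, 32, 33],
            "m": [1.0, 3.0, 5.0, 2.0, 4.0, 8.0, 6.0, 7.0, 9.0],
        })
        summary, _ = cohort_summary(data, parameters=["m"])
        ranks = data["m"].rank()
        n = len(data)
        groups = [ranks[:3], ranks[3:6], ranks[6:]]
        h = 12.0 / (n * (n + 1)) * sum(len(g) * g.mean() ** 2 for g in groups) - 3 * (n + 1)
        assert summary.loc[0, "kw_statistic"] == pytest.approx(h, abs=1e-10)

    def test_missing_bmi_column(self):
        with pytest.raises(ValueError):
            cohort_summary(pd.DataFrame({"x": [1.0]}))


class TestFameCrossref:
    def test_proportional_gives_unit_loglog_effect(self):
        rng = np.random.default_rng(1)
        fa = pd.Series(rng.uniform(1, 10, 50))
        pl = 3.7 * fa
        bmi = pd.Series(rng.uniform(20, 35, 50))
        out = fame_crossref(pl, fa, bmi)
        assert out["effect"] == pytest.approx(1.0, abs=1e-10)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        pvals = [
            fame_crossref(
                pd.Series(rng.lognormal(size=60)),
                pd.Series(rng.lognormal(size=60)),
                pd.Series(rng.uniform(20, 35, 60)),
            )["p"]
            for _ in range(400)
        ]
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.035)

    def test_spearman_matches_rank_formula(self):
        fa = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        pl = pd.Series([2.0, 1.0, 4.0, 3.0, 5.0])
        bmi = pd.Series([22.0, 25.0, 28.0, 31.0, 34.0])
        out = fame_crossref(pl, fa, bmi)
        d = fa.rank() - pl.rank()
        rho = 1 - 6 * (d**2).sum() / (5 * 24)
        assert out["spearman_rho"] == pytest.approx(rho, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fame_crossref(pd.Series([1.0, -1.0]), pd.Series([1.0, 2.0]), pd.Series([20.0, 30.0]))


class TestTransforms:
    def test_declared_scheme(self):
        assert TRAIT_TRANSFORMS["leptin"] == "log"
        assert TRAIT_TRANSFORMS["bmi"] == "identity"
        assert TRAIT_TRANSFORMS["mcp1"] == "identity"

    def test_log_with_zero_offset(self):
        v = pd.Series([0.0, 1.0, 4.0], name="il6")
        out = transform_trait(v, "log")
        np.testing.assert_allclose(out, np.log([1.0, 2.0, 5.0]))

    def test_plain_log_when_positive(self):
        v = pd.Series([1.0, 2.0], name="leptin")
        np.testing.assert_allclose(transform_trait(v, "log"), np.log([1.0, 2.0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_trait(pd.Series([-1.0, 2.0], name="x"), "log")


def test_smoking_saturated_group_means():
    # with zero age effect the model reproduces a saturated group-means fit
    rng = np.random.default_rng(4)
    n = 60
    cov = pd.DataFrame({
        "age": rng.uniform(48, 65, n),
        "smoking": pd.Categorical(rng.choice(["ever", "never", "unknown"], n)),
    }, index=[f"s{i}" for i in range(n)])
    means = {"ever": 1.0, "never": 3.0, "unknown": 5.0}
    y = pd.Series([means[str(s)] for s in cov["smoking"]], index=cov.index, dtype=float)
    lipid = pd.Series(rng.normal(size=n), index=cov.index)
    rec = fit_single_lipid(y, cov, lipid)
    # residual from group means is exactly zero apart from the lipid column
    assert abs(rec.effect) < 1e-10
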
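"""Association engine: regressions, LRTs, FDR, confounding, AIC comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from commtype.association import (
    _representation_design,
    adjusted_disease_test,
    associate_factor,
    bh_fdr,
    compare_representations,
    drug_confounding_scan,
    screen_factors,
    subdiagnosis_test,
)
from commtype.tables import PhenotypeTable


def _labels(rng, n, probs=(0.45, 0.25, 0.30)):
    return pd.Series(rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs))


class TestAssociateFactor:
    def test_balanced_table_gives_zero_statistic(self):
        factor = pd.Series([0] * 30 + [1] * 30, name="f")
        clusters = pd.Series(([1] * 10 + [2] * 10 + [3] * 10) * 2)
        res = associate_factor(factor, "categorical", clusters)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_hand_statistic(self):
        # [[20,10],[10,20]]: Pearson chi2 = 100/15
        factor = pd.Series([0] * 30 + [1] * 30, name="f")
        clusters = pd.Series([1] * 20 + [2] * 10 + [1] * 10 + [2] * 20)
        res = associate_factor(factor, "categorical", clusters)
        assert res.statistic == pytest.approx(100 / 15)
        assert res.df == 1

    def test_constant_factor_reports_reason(self):
        factor = pd.Series([1.0] * 50, name="f")
        res = associate_factor(factor, "binary", pd.Series([1, 2] * 25))
        assert res.p_value is None
        assert "constant" in res.reason

    def test_covariates_rejected_for_categorical(self):
        factor = pd.Series([0, 1, 2, 0], name="f")
        with pytest.raises(ValueError, match="covariates"):
            associate_factor(
                factor, "categorical", pd.Series([1, 1, 2, 2]),
                covariates=pd.DataFrame({"age": [1, 2, 3, 4]}),
            )

    def test_reference_level_is_largest_cluster(self):
        rng = np.random.default_rng(0)
        labels = _labels(rng, 300)
        cols, df, kind = _representation_design(labels)
        assert kind == "cluster"
        assert df == 2
        assert "cluster_1" not in cols.columns  # cluster 1 has p=0.45

    def test_lrt_matches_independent_refits(self):
        rng = np.random.default_rng(1)
        n = 400
        labels = _labels(rng, n)
        y = pd.Series(
            rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.8 * (labels == 2))))),
            name="d",
        )
        covs = pd.DataFrame({"age": rng.normal(50, 10, n)})
        res = adjusted_disease_test(y, labels, covs)

        frame = pd.DataFrame({"y": y, "age": covs["age"]})
        for lv in (2, 3):
            frame[f"c{lv}"] = (labels == lv).astype(float)
        full = sm.GLM(
            frame["y"], sm.add_constant(frame[["age", "c2", "c3"]]),
            family=sm.families.Binomial(),
        ).fit()
        red = sm.GLM(
            frame["y"], sm.add_constant(frame[["age"]]),
            family=sm.families.Binomial(),
        ).fit()
        assert res.statistic == pytest.approx(2 * (full.llf - red.llf), abs=1e-6)
        assert res.df == 2

    def test_constant_cluster_column_gives_null_result(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.binomial(1, 0.3, 100).astype(float), name="d")
        res = adjusted_disease_test(
            y, pd.Series(np.ones(100, dtype=int)),
            pd.DataFrame({"age": rng.normal(size=100)}),
        )
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)


class TestBHFDR:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_nan_excluded_from_family(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_brute_force_definition(self, ps):
        q = bh_fdr(ps)
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        for rank, idx in enumerate(order, start=1):
            brute = min(
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            )
            assert q[idx] == pytest.approx(min(brute, 1.0), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40)
    )
    def test_monotone_in_p(self, ps):
        q = bh_fdr(ps)
        p = np.asarray(ps)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTypeICalibration:
    def test_null_continuous_factor_rejects_near_nominal(self):
        rng = np.random.default_rng(10)
        R, n = 400, 300
        rej = 0
        for _ in range(R):
            labels = _labels(rng, n)
            y = pd.Series(rng.normal(size=n), name="f")
            res = associate_factor(y, "continuous", labels)
            rej += res.p_value <= 0.05
        # binomial 99% envelope around 0.05 for 400 replicates
        assert 0.02 <= rej / R <= 0.085

    def test_adjusted_model_removes_covariate_confounding(self):
        rng = np.random.default_rng(22)
        R, n = 120, 500
        rej_adj = rej_unadj = 0
        for _ in range(R):
            labels = _labels(rng, n)
            age = rng.normal(50, 10, n) + 4.0 * (labels == 3)  # cluster-age link
            y = pd.Series(
                rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.06 * (age - 50))))),
                name="d",
            )
            covs = pd.DataFrame({"age": age})
            adj = adjusted_disease_test(y, labels, covs)
            unadj = associate_factor(y, "binary", labels)
            rej_adj += adj.p_value <= 0.05
            rej_unadj += unadj.p_value <= 0.05
        assert rej_unadj > rej_adj
        assert rej_adj / R <= 0.12


class TestScreenFactors:
    def _null_panel(self, rng, n=200, n_factors=100):
        labels = _labels(rng, n)
        data = pd.DataFrame(
            rng.normal(size=(n, n_factors)),
            columns=[f"f{j}" for j in range(n_factors)],
        )
        kinds = {c: "continuous" for c in data.columns}
        return PhenotypeTable(data, kinds), labels

    def test_null_panel_yields_no_fdr_hits(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            pheno, labels = self._null_panel(rng)
            summary = screen_factors(pheno, {"CT": labels})
            assert len(summary.fdr_significant["CT"]) <= 2

    def test_shared_and_specific_sets_partition_each_family(self):
        rng = np.random.default_rng(5)
        n = 400
        ct = _labels(rng, n)
        et = ct.where(ct <= 2, 3)
        data = pd.DataFrame(
            {
                "hit": 1.0 * (ct == 2) + rng.normal(0, 0.5, n),
                "null1": rng.normal(size=n),
                "null2": rng.normal(size=n),
            }
        )
        pheno = PhenotypeTable(data, {c: "continuous" for c in data.columns})
        summary = screen_factors(pheno, {"ET": et, "CT": ct})
        for rep in ("ET", "CT"):
            # with two families: significant = shared ∪ family-specific
            assert summary.fdr_significant[rep] == (
                summary.shared_fdr | summary.specific_fdr[rep]
            )
            assert "hit" in summary.fdr_significant[rep]


class TestDrugConfounding:
    def test_no_drugs_means_not_confounded(self):
        rng = np.random.default_rng(3)
        n = 300
        labels = _labels(rng, n)
        y = pd.Series(rng.binomial(1, 0.3, n).astype(float), name="d")
        covs = pd.DataFrame({"age": rng.normal(size=n)})
        report = drug_confounding_scan(y, labels, covs, pd.DataFrame(index=y.index))
        assert report.confounded is False
        assert report.confounding_drugs == {}

    def test_full_mediation_is_flagged(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 600
            labels = _labels(rng, n)
            drug = rng.binomial(1, np.where(labels == 1, 0.55, 0.08))
            y = pd.Series(
                rng.binomial(1, 1 / (1 + np.exp(-(-2.0 + 1.8 * drug)))), name="d"
            )
            covs = pd.DataFrame({"age": rng.normal(size=n)})
            report = drug_confounding_scan(
                y, labels, covs, pd.DataFrame({"drugA": drug}, index=y.index)
            )
            flagged += report.confounded
        assert flagged >= 16

    def test_independent_drug_rarely_flagged(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n = 600
            labels = _labels(rng, n)
            y = pd.Series(
                rng.binomial(1, 1 / (1 + np.exp(-(-1.8 + 1.5 * (labels == 1))))),
                name="d",
            )
            drug = rng.binomial(1, 0.2, n)
            covs = pd.DataFrame({"age": rng.normal(size=n)})
            report = drug_confounding_scan(
                y, labels, covs, pd.DataFrame({"drugB": drug}, index=y.index)
            )
            flagged += report.confounded
        assert flagged <= 3

    def test_collinear_drug_skipped(self):
        rng = np.random.default_rng(4)
        n = 200
        labels = _labels(rng, n)
        y = pd.Series(rng.binomial(1, 0.4, n).astype(float), name="d")
        covs = pd.DataFrame({"age": rng.normal(size=n)})
        report = drug_confounding_scan(
            y, labels, covs, pd.DataFrame({"same": y.to_numpy()}, index=y.index)
        )
        assert "same" in report.skipped_drugs


class TestCompareRepresentations:
    def test_cluster_specific_effect_prefers_ct(self, three_component_cohort):
        # single strong instance; the replicated rates live in the
        # acceptance suite
        rng = np.random.default_rng(7)
        n = 1000
        ct = _labels(rng, n, probs=(0.18, 0.26, 0.24, 0.20, 0.12))
        et = ct.map({1: 1, 2: 1, 3: 3, 4: 2, 5: 2})
        grad = pd.Series(
            {1: -8.0, 2: -6.5, 3: 0.5, 4: 6.5, 5: 8.0}
        )[ct].set_axis(ct.index) + rng.normal(0, 1.5, n)
        y = pd.Series(
            rng.binomial(1, 1 / (1 + np.exp(-(-1.5 + 1.5 * (ct == 2))))), name="f"
        )
        comp = compare_representations(y, "binary", et, ct, grad)
        assert comp.best == "CT"

    def test_gradient_effect_prefers_gradient(self):
        rng = np.random.default_rng(8)
        n = 1000
        ct = _labels(rng, n, probs=(0.18, 0.26, 0.24, 0.20, 0.12))
        et = ct.map({1: 1, 2: 1, 3: 3, 4: 2, 5: 2})
        grad = pd.Series(
            {1: -8.0, 2: -6.5, 3: 0.5, 4: 6.5, 5: 8.0}
        )[ct].set_axis(ct.index) + rng.normal(0, 1.5, n)
        y = pd.Series(grad * 0.4 + rng.normal(0, 1, n), name="f")
        comp = compare_representations(y, "continuous", et, ct, grad)
        assert comp.best == "gradient"

    def test_aic_formula_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        n = 300
        ct = _labels(rng, n)
        et = ct
        grad = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.normal(size=n), name="f")
        comp = compare_representations(y, "continuous", et, ct, grad)
        X = sm.add_constant(pd.DataFrame({"gradient": grad}))
        fit = sm.OLS(y, X).fit()
        assert comp.aic_gradient == pytest.approx(fit.aic)
        assert comp.best == min(
            {"ET": comp.aic_ET, "CT": comp.aic_CT, "gradient": comp.aic_gradient},
            key=lambda k: {"ET": comp.aic_ET, "CT": comp.aic_CT,
                           "gradient": comp.aic_gradient}[k],
        )


class TestSubdiagnosis:
    def test_balanced_distribution_gives_zero(self):
        sub = pd.Series((["K29.3"] * 10 + ["K29.7"] * 10) * 2, name="sub")
        clusters = pd.Series([1] * 20 + [2] * 20)
        res = subdiagnosis_test(sub, clusters)
        assert res.statistic == pytest.approx(0.0)

    def test_single_subcode_gives_na(self):
        sub = pd.Series(["K29.3"] * 20, name="sub")
        res = subdiagnosis_test(sub, pd.Series([1, 2] * 10))
        assert res.p_value is None
        assert "single subcode" in res.reason

    def test_statistic_matches_hand_formula(self):
        rng = np.random.default_rng(12)
        sub = pd.Series(rng.choice(["a", "b", "c"], size=120), name="sub")
        clusters = pd.Series(rng.choice([1, 2, 3], size=120))
        res = subdiagnosis_test(sub, clusters)
        tab = pd.crosstab(sub, clusters).to_numpy(float)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        hand = ((tab - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand)

    def test_concentrated_subcode_detected(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            n = 200
            clusters = pd.Series(rng.choice([1, 2, 3], size=n))
            probs = np.where(clusters == 1, 0.7, 0.2)
            sub = pd.Series(
                np.where(rng.random(n) < probs, "K29.3", "K29.7"), name="sub"
            )
            res = subdiagnosis_test(sub, clusters)
            detected += res.p_value <= 0.05
        assert detected >= 18
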
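import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metalith.diffstats import (
    DiffStatsError,
    anova_from_summary,
    anova_oneway,
    covariate_screen,
    differential_table,
    fold_change,
    percent_change,
    ratio_statistic,
)
from metalith.synthetic import (
    PlantedEffect,
    SyntheticTruth,
    generate_study,
)

from conftest import build_matrix


class TestAnovaOneway:
    def test_identical_groups(self):
        F, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert F == 0.0 and p == 1.0

    def test_zero_within_variance_floors_p(self):
        F, p = anova_oneway([[0, 0], [1, 1]])
        assert math.isinf(F) and 0 < p < 1e-15

    def test_small_group_rejected(self):
        with pytest.raises(DiffStatsError):
            anova_oneway([[1.0], [1, 2]])

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 12))
            F, p = anova_oneway([a, b])
            t = stats.ttest_ind(a, b, equal_var=True)
            assert F == pytest.approx(t.statistic**2, abs=1e-12, rel=1e-12)
            assert p == pytest.approx(t.pvalue, abs=1e-12, rel=1e-12)

    def test_multi_group_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=7), rng.normal(1, 1, 5), rng.normal(0, 2, 9)]
        F, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_type_one_error_calibration(self):
        # 1000 null 2-group datasets at the study's cerebellar control sizes
        rng = np.random.default_rng(12)
        n_sim, alpha = 1000, 0.05
        hits = 0
        for _ in range(n_sim):
            F, p = anova_oneway([rng.normal(size=10), rng.normal(size=16)])
            hits += p < alpha
        rate = hits / n_sim
        se3 = 3 * math.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) <= se3


class TestAnovaFromSummary:
    def test_published_summary_reproduces_published_p(self):
        # cerebellar 2-monopalmitin: SCA1 ctrl 0.7±0.2 (n=16) vs WT ctrl
        # 1.0±0.3 (n=10) reconstructs the printed p = 0.005
        F, p = anova_from_summary(1.0, 0.3, 10, 0.7, 0.2, 16)
        assert round(p, 3) == 0.005

    def test_identical_summaries(self):
        F, p = anova_from_summary(1.0, 0.2, 10, 1.0, 0.2, 16)
        assert F == 0.0 and p == 1.0

    def test_equivalent_to_raw_anova(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(0.5, 1.3, rng.integers(3, 15))
            F1, p1 = anova_oneway([a, b])
            F2, p2 = anova_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            assert F1 == pytest.approx(F2, rel=1e-12, abs=1e-12)
            assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-12)

    def test_bad_n_rejected(self):
        with pytest.raises(DiffStatsError):
            anova_from_summary(1.0, 0.1, 1, 1.0, 0.1, 5)


class TestFoldChange:
    def test_hand_values(self):
        assert fold_change([2, 2], [1, 1]) == 2.0

    def test_identity(self):
        vals = [1.5, 2.5, 3.0]
        assert fold_change(vals, vals) == 1.0

    def test_reciprocal_product_is_one(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(size=6)
        b = rng.lognormal(size=9)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-12)

    def test_published_group_means(self):
        # hypoxanthine, WT cerebellum: lithium 2.2 vs control 1.0 -> 2.2
        assert round(fold_change([2.2], [1.0]), 1) == 2.2
        # inosine, cerebellum control: SCA1 0.8 vs WT 1.0 -> 0.8
        assert round(fold_change([0.8], [1.0]), 1) == 0.8

    def test_missing_excluded(self):
        assert fold_change([2.0, math.nan, 2.0], [1.0, 1.0]) == 2.0


def planted_truth(seed, effects, n_met=40, n_ident=30, sigma=0.3):
    return SyntheticTruth(
        n_metabolites=n_met,
        n_identified=n_ident,
        effects=tuple(effects),
        sigma_range=(sigma, sigma),
        dropout=None,
        seed=seed,
    )


WT_CEREB_LI = {"tissue": "cerebellum", "genotype": "WT", "treatment": "lithium"}


class TestDifferentialTable:
    def test_planted_effects_all_flagged(self):
        effects = [
            PlantedEffect.make(f"M{i + 1:04d}", WT_CEREB_LI, 4.0) for i in range(5)
        ]
        m, _ = generate_study(planted_truth(21, effects))
        res = differential_table(
            m,
            {"tissue": "cerebellum", "genotype": "WT"},
            ({"treatment": "lithium"}, {"treatment": "control"}),
        )
        flagged = {r.metabolite_id for r in res if r.significant}
        assert {e.metabolite_id for e in effects} <= flagged

    def test_null_flag_count_in_binomial_band(self):
        m, _ = generate_study(planted_truth(22, [], n_met=400, n_ident=130))
        res = differential_table(
            m,
            {"tissue": "cerebellum", "genotype": "WT"},
            ({"treatment": "lithium"}, {"treatment": "control"}),
        )
        n_sig = sum(r.significant for r in res)
        lo, hi = stats.binom.ppf([0.005, 0.995], 400, 0.05)
        assert lo <= n_sig <= hi

    def test_self_contrast_ratio_centered_at_one(self):
        m, _ = generate_study(planted_truth(23, []))
        # split one group in half by sex (assigned alternately at generation)
        res = differential_table(
            m,
            {"tissue": "cerebellum", "genotype": "WT", "treatment": "control"},
            ({"sex": "F"}, {"sex": "M"}),
        )
        ratios = np.array([r.ratio for r in res])
        assert np.median(np.log(ratios)) == pytest.approx(0.0, abs=0.1)

    def test_empty_stratum_rejected(self, two_group_matrix):
        with pytest.raises(DiffStatsError, match="stratum"):
            differential_table(
                two_group_matrix,
                {"tissue": "plasma"},
                ({"treatment": "lithium"}, {"treatment": "control"}),
            )

    def test_invariant_to_column_order_and_global_scale(self):
        m, _ = generate_study(planted_truth(24, []))
        res1 = {
            r.metabolite_id: (r.ratio, r.p)
            for r in differential_table(
                m, {"tissue": "cerebellum", "genotype": "WT"},
                ({"treatment": "lithium"}, {"treatment": "control"}))
        }
        m2 = m.copy()
        cols = list(reversed(m2.values.columns))
        m2 = m2.subset(metabolite_ids=cols)
        m2.values = m2.values * 3.0
        res2 = {
            r.metabolite_id: (r.ratio, r.p)
            for r in differential_table(
                m2, {"tissue": "cerebellum", "genotype": "WT"},
                ({"treatment": "lithium"}, {"treatment": "control"}))
        }
        for mid, (ratio, p) in res1.items():
            assert res2[mid][0] == pytest.approx(ratio, rel=1e-12)
            assert res2[mid][1] == pytest.approx(p, rel=1e-12)


class TestCovariateScreen:
    def test_constant_covariate_rejected(self, two_group_matrix):
        with pytest.raises(DiffStatsError, match="genotype"):
            covariate_screen(two_group_matrix, ["genotype", "treatment"])

    def test_planted_sex_effect_dominates(self):
        rng = np.random.default_rng(31)
        n = 40
        vals = pd.DataFrame(
            rng.lognormal(3, 0.3, size=(n, 12)),
            columns=[f"m{i}" for i in range(12)],
        )
        sex = ["F", "M"] * (n // 2)
        for c in ("m0", "m1", "m2"):  # planted sex effect on 3 metabolites
            vals[c] = vals[c] * np.where(np.array(sex) == "F", 2.5, 1.0)
        m = build_matrix(
            vals,
            sample_meta={
                "sex": sex,
                "treatment": ["control"] * (n // 2) + ["lithium"] * (n // 2),
                "age": rng.uniform(13, 15, n),
                "weight": rng.normal(25, 2, n),
            },
        )
        table, n_sig = covariate_screen(m, ["treatment", "sex", "age", "weight"])
        sex_p = table[table["covariate"] == "sex"].set_index("metabolite_id")["p"]
        assert set(sex_p.nsmallest(3).index) == {"m0", "m1", "m2"}
        assert (sex_p[["m0", "m1", "m2"]] < 0.05).all()

    def test_permuted_covariates_fall_to_null(self):
        rng = np.random.default_rng(32)
        n = 40
        vals = pd.DataFrame(
            rng.lognormal(3, 0.3, size=(n, 40)),
            columns=[f"m{i}" for i in range(40)],
        )
        m = build_matrix(
            vals,
            sample_meta={
                "sex": list(rng.permutation(["F", "M"] * (n // 2))),
                "treatment": list(rng.permutation(["control", "lithium"] * (n // 2))),
            },
        )
        table, n_sig = covariate_screen(m, ["treatment", "sex"])
        # 40 metabolites x 2 covariates at alpha=.05 -> ~4 expected flags
        assert n_sig <= stats.binom.ppf(0.999, 80, 0.05)


class TestRatioStatistic:
    def test_published_percent_change(self):
        # WT hypoxanthine/inosine: 0.55 (control) -> 0.86 (lithium) = +56%
        assert percent_change(0.55, 0.86) == 56

    def test_identical_groups_zero_change(self):
        m = build_matrix(
            pd.DataFrame({"num": [2.0] * 4, "den": [4.0] * 4}),
            sample_meta={"treatment": ["control"] * 2 + ["lithium"] * 2},
        )
        r = ratio_statistic(m, "num", "den",
                            {"treatment": "control"}, {"treatment": "lithium"})
        assert r.percent_change == 0
        assert r.mean_a == pytest.approx(0.5)

    def test_zero_denominator_sample_excluded(self):
        m = build_matrix(
            pd.DataFrame({"num": [2.0, 2.0, 3.0], "den": [1.0, 0.0, 1.0]}),
            sample_meta={"treatment": ["control", "control", "lithium"]},
        )
        r = ratio_statistic(m, "num", "den",
                            {"treatment": "control"}, {"treatment": "lithium"})
        assert r.n_a == 1 and r.n_excluded == 1

    def test_planted_shift_recovered(self):
        changes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 16
            den = rng.lognormal(2, 0.2, 2 * n)
            shift = np.r_[np.ones(n), 1.5 * np.ones(n)]
            num = den * rng.lognormal(-0.7, 0.15, 2 * n) * shift
            m = build_matrix(
                pd.DataFrame({"num": num, "den": den}),
                sample_meta={"treatment": ["control"] * n + ["lithium"] * n},
            )
            r = ratio_statistic(m, "num", "den", {"treatment": "control"},
                                {"treatment": "lithium"})
            changes.append(r.percent_change)
        assert np.median(changes) == pytest.approx(50, abs=10)
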
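"""Correlation screens, repeated-measures ANOVA and the stability summary.

pingouin serves as the independent oracle for the RM-ANOVA / sphericity /
Greenhouse-Geisser implementation.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import batkit as bk
from batkit.sessions import FeatureTable, KEY_COLS
from batkit.stats import (explore_correlations, multiple_comparison_ledger,
                          rm_anova, rm_anova_by_feature, spearman,
                          stability_summary)


def long_format(y):
    n, k = y.shape
    return pd.DataFrame({"subj": np.repeat(np.arange(n), k),
                         "cond": np.tile(np.arange(k), n),
                         "y": y.ravel()})


def table_with_sets(y_by_set, feature="hrv_sdnn", theme=7):
    rows = []
    for set_id, vals in y_by_set.items():
        for i, v in enumerate(vals):
            rows.append(dict(participant=f"p{i}", set=set_id, theme=theme,
                             phase="whole", variant="raw", feature=feature,
                             value=float(v)))
    return FeatureTable(pd.DataFrame(rows)[KEY_COLS + ["value"]])


class TestSpearman:
    def test_exact_small_n_perfect_rank(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rho, p = spearman(x, x ** 3)  # monotone -> rho = 1
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120, abs=1e-12)

    def test_matches_scipy_at_larger_n(self):
        from scipy import stats as st
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = spearman(x, y)
        ref_rho, ref_p = st.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho) and p == pytest.approx(ref_p)


class TestRmAnova:
    def test_epsilon_is_one_for_two_conditions(self):
        rng = np.random.default_rng(2)
        res = rm_anova(rng.normal(size=(12, 2)))
        assert res.epsilon_gg == 1.0 and not res.corrected

    def test_identical_conditions_give_zero_f(self):
        y = np.tile(np.arange(8, dtype=float)[:, None], (1, 3))
        res = rm_anova(y)
        assert res.f == 0.0 and res.p == 1.0

    def test_matches_pingouin_on_random_tables(self):
        rng = np.random.default_rng(3)
        for i in range(12):
            n = int(rng.integers(6, 15))
            k = int(rng.integers(2, 5))
            y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = rm_anova(y)
            long = long_format(y)
            aov = pg.rm_anova(data=long, dv="y", within="cond",
                              subject="subj", correction=True).iloc[0]
            # uncorrected F statistic is shared by both routes
            f_ref = float(aov["F"])
            assert res.f == pytest.approx(f_ref, abs=1e-6 * max(1, abs(f_ref)))
            eps_ref = float(pg.epsilon(data=long, dv="y", within="cond",
                                       subject="subj", correction="gg"))
            assert res.epsilon_gg == pytest.approx(eps_ref, abs=1e-6)
            if k > 2:
                sph = pg.sphericity(data=long, dv="y", within="cond",
                                    subject="subj")
                assert res.mauchly_w == pytest.approx(sph.W, abs=1e-6)
                assert res.mauchly_p == pytest.approx(sph.pval, abs=1e-6)
                p_ref = float(aov["p_GG_corr"] if res.corrected
                              else aov["p_unc"])
                assert res.p == pytest.approx(p_ref, abs=1e-6)
            else:
                assert res.p == pytest.approx(float(aov["p_unc"]), abs=1e-6)

    def test_by_feature_uses_complete_cases(self):
        rng = np.random.default_rng(4)
        t = table_with_sets({1: rng.normal(size=10),
                             2: rng.normal(size=10),
                             3: rng.normal(size=10)})
        # remove one participant's set-3 value -> complete cases drop to 9
        data = t.data.drop(t.data[(t.data.participant == "p0")
                                  & (t.data.set == 3)].index)
        t = FeatureTable(data)
        res = rm_anova_by_feature(t, [("whole", "raw", "hrv_sdnn")],
                                  themes=(7,))
        assert len(res) == 1 and res[0].n == 9 and res[0].k == 3


class TestStability:
    def test_counts(self):
        mk = lambda p: bk.AnovaResult(feature="f", k=3, n=10, f=1.0,
                                      df_num=2, df_den=18, p=p,
                                      mauchly_w=1, mauchly_p=1,
                                      epsilon_gg=1, corrected=False)
        all_one = [mk(1.0)] * 5
        assert stability_summary(all_one) == (0, 5, 0.0)
        all_zero = [mk(0.0)] * 5
        assert stability_summary(all_zero) == (5, 5, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stability_summary([])


class TestLedger:
    def test_arithmetic(self):
        led = multiple_comparison_ledger()
        assert led["n_tests"] == 138
        assert led["bonferroni_alpha"] == pytest.approx(0.05 / 138)


class TestExploreCorrelations:
    def test_feature_equal_to_measure(self, small_cohort):
        _, _, _, gt = small_cohort
        rows = [dict(participant=p, set=1, theme=7, phase="whole",
                     variant="raw", feature="mirror",
                     value=gt.loc[p, "aaq_security"])
                for p in gt.index]
        t = FeatureTable(pd.DataFrame(rows)[KEY_COLS + ["value"]])
        rep = explore_correlations(t, gt, scopes={"aaq_security": (7,)})
        row = rep.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-6 or row["method"] == "spearman"

    def test_spearman_rank_invariance_under_monotone_transform(self, small_cohort):
        _, _, _, gt = small_cohort
        rows = [dict(participant=p, set=1, theme=7, phase="whole",
                     variant="raw", feature="cubed",
                     value=float(gt.loc[p, "aaq_security"]) ** 3)
                for p in gt.index]
        t = FeatureTable(pd.DataFrame(rows)[KEY_COLS + ["value"]])
        spear = explore_correlations(t, gt, scopes={"aaq_security": (7,)},
                                     small_n_threshold=100).iloc[0]
        pears = explore_correlations(t, gt, scopes={"aaq_security": (7,)},
                                     small_n_threshold=1).iloc[0]
        assert spear["method"] == "spearman"
        assert spear["r"] == pytest.approx(1.0)
        assert pears["method"] == "pearson" and pears["r"] < 1.0

    def test_expected_sign_tagging(self, small_cohort):
        _, _, _, gt = small_cohort
        rows = [dict(participant=p, set=1, theme=7, phase="whole",
                     variant="raw", feature="mirror",
                     value=gt.loc[p, "aaq_security"])
                for p in gt.index]
        t = FeatureTable(pd.DataFrame(rows)[KEY_COLS + ["value"]])
        rep = explore_correlations(t, gt, scopes={"aaq_security": (7,)},
                                   expected_signs={"mirror": -1})
        row = rep.iloc[0]
        if row["significant"]:
            assert row["theory_consistent"] is np.False_ \
                or row["theory_consistent"] == False  # noqa: E712

    def test_sign_recovery_on_planted_cohort(self):
        """Most planted-effect features correlate with the trait in the
        planted direction (exercised at moderate size here)."""
        cfg = bk.CohortConfig(n_participants=80, n_sets=1, seed=17,
                              effect_size=0.6)
        sessions, traits, gt = bk.generate_cohort(cfg)
        table = bk.extract_cohort_features(sessions, treatments=False)
        schema = bk.feature_schema()
        signs = {f: (1 if m["desirability"] == "desirable" else -1)
                 for f, m in schema.items()
                 if m["desirability"] in ("desirable", "undesirable")}
        rep = explore_correlations(
            table, gt, scopes={"latent_security": (4, 7, 13)},
            expected_signs=signs, small_n_threshold=5)
        rep = rep[(rep.variant == "raw") & rep.feature.isin(signs)]
        match = np.sign(rep["r"]) == rep["feature"].map(signs)
        assert match.mean() >= 0.9

    def test_bonferroni_mode_shrinks_significance(self, small_table,
                                                  small_cohort):
        _, _, _, gt = small_cohort
        plain = explore_correlations(small_table, gt,
                                     scopes={"latent_security": (4, 7, 13)})
        bonf = explore_correlations(small_table, gt,
                                    scopes={"latent_security": (4, 7, 13)},
                                    correction="bonferroni")
        assert bonf["significant"].sum() <= plain["significant"].sum()
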
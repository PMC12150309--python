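"""Mixed-model screening: elementary tests, REML engine, calibration, trends."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_balanced_metadata
from septomics import screen, simulate
from septomics.screen import (
    CONTRASTS,
    RandomInterceptLMM,
    anova_three_group,
    bh_adjust,
    classify_trend,
    directed_pvalue,
    fisher_exact_2x2,
    fit_contrast_lmm,
    fold_change,
    identify_confounders,
    run_screen,
    stratified_screen,
    welch_t,
)
from septomics.simulate import CohortSpec, ConfigurationError, EffectSpec


class TestElementaryTests:
    def test_welch_identical_arms(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_welch_known_value(self):
        t, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.0213, abs=2e-3)

    def test_welch_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, p1 = welch_t(x, y)
        t2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_fisher_table1_sex_by_pathogen(self):
        # gram-positive 22M/7F vs gram-negative 11M/3F: no sex bias
        _, p = fisher_exact_2x2([[22, 7], [11, 3]])
        assert p == 1.0

    def test_fisher_extreme_table(self):
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(1.0825088e-05, rel=1e-5)

    def test_fisher_symmetric_table(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == 1.0

    def test_fisher_zero_margin(self):
        with pytest.warns(UserWarning, match="margin"):
            _, p = fisher_exact_2x2([[0, 0], [5, 3]])
        assert p == 1.0

    def test_anova_identical_groups_and_shift_invariance(self, rng):
        y = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["control", "SINS", "sepsis"], 3)
        F, p = anova_three_group(y, g)
        assert F == pytest.approx(0.0) and p == pytest.approx(1.0)
        y2 = rng.normal(size=90)
        g2 = np.repeat(["control", "SINS", "sepsis"], 30)
        F1, p1 = anova_three_group(y2, g2)
        F2, p2 = anova_three_group(y2 + 7.5, g2)
        assert F1 == pytest.approx(F2) and p1 == pytest.approx(p2)

    def test_anova_power_on_shifted_group(self, rng):
        g = np.repeat(["control", "SINS", "sepsis"], 30)
        y = rng.normal(size=90)
        y[g == "sepsis"] += 10.0
        _, p = anova_three_group(y, g)
        assert p < 1e-6


class TestBH:
    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_monotone_and_nan_excluded(self, rng):
        p = rng.uniform(size=30)
        p[5] = np.nan
        q = bh_adjust(p)
        assert np.isnan(q[5])
        ok = ~np.isnan(p)
        order = np.argsort(p[ok])
        assert (np.diff(q[ok][order]) >= -1e-12).all()
        assert (q[ok] >= p[ok] - 1e-12).all()


class TestDirectedP:
    @pytest.mark.parametrize(
        "p,est,expected",
        [(0.001, -0.5, -3.0), (1.0, 2.0, 0.0), (0.01, 2.0, 2.0), (0.5, 0.0, 0.0)],
    )
    def test_formula(self, p, est, expected):
        assert directed_pvalue(p, est) == pytest.approx(expected)

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError):
            directed_pvalue(0.0, 1.0)


class TestFoldChange:
    def test_identity_and_doubling(self):
        tab = pd.DataFrame(
            {"f": [1.0, 1.0, 2.0, 2.0]}, index=[f"s{i}" for i in range(4)]
        )
        groups = pd.Series(
            ["control", "control", "sepsis", "sepsis"], index=tab.index
        )
        fc = fold_change(tab, groups, ("control", "sepsis"))
        assert fc["f"] == pytest.approx(2.0)  # +1 on log2 scale doubles
        fc_same = fold_change(tab, groups, ("control", "control"))
        assert fc_same["f"] == pytest.approx(1.0)

    def test_planted_shift_recovered(self):
        meta = make_balanced_metadata(500, seed=3)
        es = EffectSpec.planted(
            2, {0: "progressive"}, {0: -0.6}, subject_icc=0.0, seed=4
        )
        _, truth = simulate.generate_abundances(meta, es)
        groups = meta.set_index("sample_id")["group"]
        fc = fold_change(truth.uncensored_log2, groups, ("control", "sepsis"))
        assert fc.iloc[0] == pytest.approx(2 ** (-0.6), rel=0.1)


class TestRandomInterceptLMM:
    def test_matches_mixedlm_oracle(self, rng):
        import statsmodels.formula.api as smf

        rows = []
        for i in range(60):
            u = rng.normal(0, 0.8)
            g = float(rng.random() < 0.4)
            for _ in range(int(rng.integers(1, 3))):
                x = rng.normal()
                rows.append({"subject": f"s{i}", "g": g, "x": x, "u": u})
        df = pd.DataFrame(rows)
        df["y"] = 0.5 * df.g + 0.3 * df.x + df.u + rng.normal(0, 1, len(df))
        X = np.column_stack([np.ones(len(df)), df.g, df.x])
        fit = RandomInterceptLMM(X, df.subject.to_numpy()).fit(df.y.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm("y ~ g + x", df, groups=df.subject).fit(reml=True)
        assert np.allclose(fit["beta"], m.fe_params.to_numpy(), atol=1e-4)
        assert fit["se"][1] == pytest.approx(m.bse_fe.iloc[1], rel=2e-2)
        assert fit["tau2"] == pytest.approx(float(m.cov_re.iloc[0, 0]), abs=1e-3)

    def test_reduces_to_ols_with_single_samples(self, rng):
        import statsmodels.api as sm

        n = 80
        X = np.column_stack([np.ones(n), rng.random(n) < 0.5, rng.normal(size=n)])
        y = X @ [1.0, 0.4, 0.2] + rng.normal(size=n)
        fit = RandomInterceptLMM(X, [f"s{i}" for i in range(n)]).fit(y)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit["beta"], ols.params, rtol=1e-6, atol=1e-9)
        assert np.allclose(fit["se"], ols.bse, rtol=1e-6)
        assert np.allclose(fit["p"], ols.pvalues, rtol=1e-6, atol=1e-12)

    def test_duplicated_rows_absorbed_by_random_intercept(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.5).astype(float)])
        subj = np.array([f"s{i}" for i in range(n)])
        y = X @ [0.5, 0.6] + rng.normal(size=n)
        base = RandomInterceptLMM(X, subj).fit(y)
        X2 = np.vstack([X, X])
        fit2 = RandomInterceptLMM(X2, np.r_[subj, subj]).fit(np.r_[y, y])
        assert fit2["beta"][1] == pytest.approx(base["beta"][1], abs=0.02)


class TestFitContrastLMM:
    def test_null_p_values_uniform(self):
        meta = make_balanced_metadata(70, seed=10)
        es = EffectSpec.null(296, subject_icc=0.3, seed=11)
        _, truth = simulate.generate_abundances(meta, es)
        ps = []
        for j in range(296):
            r = fit_contrast_lmm(
                truth.uncensored_log2.iloc[:, j].to_numpy(), meta, "Sepsis"
            )
            ps.append(r["p"])
        stat, pks = stats.kstest(ps, "uniform")
        assert pks > 0.01

    def test_planted_effect_recovery_band(self):
        ests = []
        for rep in range(30):
            cohort = CohortSpec(n_subjects=200, seed=500 + rep)
            meta = simulate.generate_cohort(cohort)
            es = EffectSpec.planted(
                1, {0: "sepsis_specific"}, {0: 0.8}, subject_icc=0.3, seed=600 + rep
            )
            _, truth = simulate.generate_abundances(meta, es)
            r = fit_contrast_lmm(
                truth.uncensored_log2.iloc[:, 0].to_numpy(), meta, "Sepsis"
            )
            ests.append(r["estimate"])
        assert 0.72 <= np.mean(ests) <= 0.88


class TestRunScreen:
    def test_single_feature_q_equals_p(self):
        meta = make_balanced_metadata(30, seed=20)
        es = EffectSpec.null(1, seed=21)
        _, truth = simulate.generate_abundances(meta, es)
        scaled = (truth.uncensored_log2 - truth.uncensored_log2.mean()) / truth.uncensored_log2.std(ddof=1)
        res = run_screen(scaled, meta, "Sepsis")
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_planted_features_found_at_q10(self):
        meta = make_balanced_metadata(70, seed=22)
        classes = {i: "sepsis_specific" for i in range(20)}
        effects = {i: 0.8 for i in range(20)}
        es = EffectSpec.planted(120, classes, effects, subject_icc=0.3, seed=23)
        _, truth = simulate.generate_abundances(meta, es)
        y = truth.uncensored_log2
        scaled = (y - y.mean()) / y.std(ddof=1)
        res = run_screen(scaled, meta, "Sepsis")
        hits = res.index[res["q"] < 0.1]
        planted = set(es.feature_names()[:20])
        assert len(planted & set(hits)) >= 16

    def test_estimate_sign_consistency_for_monotone_effect(self):
        agree = 0
        reps = 20
        for rep in range(reps):
            meta = make_balanced_metadata(70, seed=800 + rep)
            es = EffectSpec.planted(
                1, {0: "progressive"}, {0: 0.8}, subject_icc=0.3, seed=900 + rep
            )
            _, truth = simulate.generate_abundances(meta, es)
            y = truth.uncensored_log2.iloc[:, 0].to_numpy()
            signs = {
                name: np.sign(fit_contrast_lmm(y, meta, name)["estimate"])
                for name in ("Sepsis", "C_S", "SINS_S")
            }
            agree += len(set(signs.values())) == 1
        assert agree / reps >= 0.95


class TestConfounders:
    def _study(self, seed, loading=0.0):
        cohort = CohortSpec(n_subjects=200, seed=seed)
        meta = simulate.generate_cohort(cohort)
        loadings = {"gestational_age": np.full(50, loading)} if loading else None
        es = EffectSpec.null(50, confounder_loadings=loadings, seed=seed + 1)
        _, truth = simulate.generate_abundances(meta, es)
        y = truth.uncensored_log2
        scaled = (y - y.mean()) / y.std(ddof=1)
        return meta, scaled

    def test_outcome_identical_covariate_detected(self):
        meta, scaled = self._study(30)
        meta = meta.copy()
        meta["mechanical_ventilation"] = (meta["group"] == "sepsis").astype(int)
        conf = identify_confounders(meta, scaled)
        assert "mechanical_ventilation" in conf.outcome_associated

    def test_planted_metabolome_confounder_detected(self):
        meta, scaled = self._study(31, loading=0.5)
        conf = identify_confounders(meta, scaled)
        assert "gestational_age" in conf.metabolome_associated

    def test_independent_covariate_usually_excluded(self):
        excluded = 0
        for seed in range(15):
            meta, scaled = self._study(100 + 2 * seed)
            rng = np.random.default_rng(seed)
            meta = meta.copy()
            meta["antibiotics_24h"] = (rng.random(len(meta)) < 0.5).astype(int)
            conf = identify_confounders(meta, scaled)
            excluded += "antibiotics_24h" not in conf.union
        assert excluded >= 9  # level ~0.05 per family of tests

    def test_adjustment_restores_nominal_level(self):
        # a covariate that both shifts the metabolome and tracks sepsis
        # inflates null rejections unless included as a fixed effect
        rej_unadj = rej_adj = 0
        n_feat = 40
        for seed in range(10):
            cohort = CohortSpec(n_subjects=150, seed=40 + seed)
            meta = simulate.generate_cohort(cohort)
            meta["oxygen_pct"] = meta["oxygen_pct"] + 10.0 * (meta["group"] == "sepsis")
            loadings = {"oxygen_pct": np.full(n_feat, 0.6)}
            es = EffectSpec.null(n_feat, confounder_loadings=loadings, seed=41 + seed)
            _, truth = simulate.generate_abundances(meta, es)
            y = truth.uncensored_log2
            scaled = (y - y.mean()) / y.std(ddof=1)
            res_u = run_screen(scaled, meta, "Sepsis")
            res_a = run_screen(scaled, meta, "Sepsis", ["oxygen_pct"])
            rej_unadj += (res_u["p"] < 0.05).mean()
            rej_adj += (res_a["p"] < 0.05).mean()
        assert rej_unadj / 10 > 0.15          # inflated without adjustment
        assert rej_adj / 10 < 0.10            # near nominal with adjustment


class TestStratifiedScreen:
    def _sex_specific_study(self, seed):
        cohort = CohortSpec(n_subjects=260, seed=seed)
        meta = simulate.generate_cohort(cohort)
        es = EffectSpec.planted(
            30, {0: "sex_specific"}, {0: 1.0}, subject_icc=0.2, seed=seed + 1
        )
        _, truth = simulate.generate_abundances(meta, es)
        assert truth.target_sex[0] == "male"
        y = truth.uncensored_log2
        scaled = (y - y.mean()) / y.std(ddof=1)
        return meta, scaled

    def test_male_screen_recovers_male_only_effect(self):
        meta, scaled = self._sex_specific_study(50)
        male = stratified_screen(scaled, meta, "sex", "male")
        female = stratified_screen(scaled, meta, "sex", "female")
        assert male["q"].iloc[0] < 0.1
        assert female["p"].iloc[0] > 0.05

    def test_stratum_variable_dropped_from_confounders(self):
        meta, scaled = self._sex_specific_study(52)
        res = stratified_screen(scaled, meta, "sex", "male", confounders=["sex", "oxygen_pct"])
        assert res.attrs["stratum"] == "sex=male"

    def test_single_class_stratum_rejected(self):
        meta, scaled = self._sex_specific_study(54)
        meta2 = meta.loc[meta["group"] != "sepsis"]
        with pytest.raises(ConfigurationError, match="single class"):
            stratified_screen(scaled.loc[scaled.index.isin(meta2["sample_id"])], meta2, "sex", "male")

    def test_pathogen_stratum_composition(self):
        meta, scaled = self._sex_specific_study(56)
        res = stratified_screen(scaled, meta, "pathogen_type", "gram_positive")
        n_gp = ((meta["group"] == "sepsis") & (meta["pathogen_type"] == "gram_positive")).sum()
        n_nonsepsis = (meta["group"] != "sepsis").sum()
        assert res.attrs["n_samples"] == n_gp + n_nonsepsis


class TestClassifyTrend:
    @staticmethod
    def _row(p, est):
        return {"p": p, "estimate": est}

    def test_all_null_unclassified(self):
        means = {"control": 0.0, "SINS": 0.0, "sepsis": 0.0}
        assert classify_trend(self._row(1, 0), self._row(1, 0), self._row(1, 0), means) == "unclassified"

    def test_archetypes(self):
        means_up = {"control": 0.0, "SINS": 0.5, "sepsis": 1.0}
        assert (
            classify_trend(self._row(0.01, 1), self._row(0.001, 1), self._row(0.5, 0.1), means_up)
            == "shared_inflammation"
        )
        assert (
            classify_trend(self._row(0.01, 1), self._row(0.001, 1), self._row(0.01, 1), means_up)
            == "progressive_up"
        )
        assert (
            classify_trend(self._row(0.5, 0.1), self._row(0.01, 1), self._row(0.01, 1), means_up)
            == "sepsis_specific"
        )
        means_sins = {"control": 0.0, "SINS": 0.6, "sepsis": 0.1}
        assert (
            classify_trend(self._row(0.01, 1), self._row(0.3, 0.2), self._row(0.2, -0.4), means_sins)
            == "sins_specific"
        )

    def test_planted_classes_recovered_at_scale(self):
        # 4 planted features per class; classification is stochastic per
        # feature, so require a high aggregate recovery rate
        meta = make_balanced_metadata(100, seed=60)
        layout = ["shared_inflammation", "progressive", "sepsis_specific", "sins_specific"]
        classes = {4 * k + r: cls for k, cls in enumerate(layout) for r in range(4)}
        effects = {i: 1.0 for i in classes}
        es = EffectSpec.planted(24, classes, effects, subject_icc=0.2, seed=61)
        _, truth = simulate.generate_abundances(meta, es)
        y = truth.uncensored_log2
        scaled = (y - y.mean()) / y.std(ddof=1)
        res = {
            name: run_screen(scaled, meta, name) for name in ("C_SINS", "C_S", "SINS_S")
        }
        groups = meta.set_index("sample_id")["group"]
        gm = y.groupby(groups.to_numpy()).mean()
        want_by_class = {
            "shared_inflammation": {"shared_inflammation"},
            "progressive": {"progressive_up", "progressive_down"},
            "sepsis_specific": {"sepsis_specific"},
            "sins_specific": {"sins_specific"},
        }
        correct = 0
        for j, cls in classes.items():
            f = es.feature_names()[j]
            got = classify_trend(
                res["C_SINS"].loc[f].to_dict(),
                res["C_S"].loc[f].to_dict(),
                res["SINS_S"].loc[f].to_dict(),
                {g: float(gm.loc[g, f]) for g in ("control", "SINS", "sepsis")},
            )
            correct += got in want_by_class[cls]
        assert correct >= 13  # >= 80% of 16 planted features
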
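"""Preprocessing: QC arithmetic, filtering rules, Rosner test, QRILC, scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from septomics import preprocess, simulate
from septomics.preprocess import (
    FeatureRecipe,
    QCThresholds,
    autoscale,
    compute_feature_qc,
    derive_features,
    detect_outlier_samples,
    filter_features,
    log2_transform,
    qrilc_impute,
)
from septomics.simulate import CohortSpec, ConfigurationError, EffectSpec


def _tables(qc_values: dict, blank_values: dict, sample_values: dict):
    """Build aligned sample/qc/blank tables from per-feature value lists."""
    def frame(d, prefix):
        n = len(next(iter(d.values())))
        return pd.DataFrame(d, index=[f"{prefix}{i}" for i in range(n)])

    return frame(sample_values, "s"), frame(qc_values, "q"), frame(blank_values, "b")


class TestFeatureQC:
    def test_rsd_direct_arithmetic(self):
        s, q, b = _tables(
            {"f": [1.0, 1.0, 1.0, 2.0]}, {"f": [0.1, 0.1]}, {"f": [5.0, 5.0, 5.0]}
        )
        rep = compute_feature_qc(s, q, b)
        assert rep.features.loc["f", "rsd_pct"] == pytest.approx(40.0)

    def test_equal_replicates_zero_rsd_and_full_blank(self):
        s, q, b = _tables({"f": [3.0] * 4}, {"f": [3.0, 3.0]}, {"f": [5.0] * 3})
        rep = compute_feature_qc(s, q, b)
        assert rep.features.loc["f", "rsd_pct"] == 0.0
        assert rep.features.loc["f", "blank_pct"] == pytest.approx(100.0)

    def test_missingness_percentage(self):
        samples = pd.DataFrame({"f": [1.0, np.nan, 1.0, 1.0]}, index=list("wxyz"))
        qc = pd.DataFrame({"f": [2.0, 2.0, 2.0]}, index=list("abc"))
        blanks = pd.DataFrame({"f": [1.0, 1.0]}, index=list("de"))
        rep = compute_feature_qc(samples, qc, blanks)  # 1 of 4 samples missing
        assert rep.features.loc["f", "missing_pct"] == pytest.approx(25.0)

    def test_zero_qc_mean_auto_fails(self):
        samples = pd.DataFrame({"f": [1.0, 1.0, 1.0]}, index=list("xyz"))
        qc = pd.DataFrame({"f": [0.0, 0.0, 0.0]}, index=list("abc"))
        blanks = pd.DataFrame({"f": [1.0, 1.0]}, index=list("de"))
        rep = compute_feature_qc(samples, qc, blanks)
        filter_features(rep, QCThresholds())
        assert rep.features.loc["f", "rsd_undefined"]
        assert not rep.features.loc["f", "pass_all"]


class TestFilterFeatures:
    @pytest.mark.parametrize(
        "rsd,blank,miss,kept",
        [
            (29.99, 39.99, 19.99, True),   # all strictly below: retained
            (30.0, 10.0, 5.0, False),      # boundary is exclusive
            (10.0, 40.0, 5.0, False),
            (10.0, 10.0, 20.0, False),
        ],
    )
    def test_strict_inequality_boundaries(self, rsd, blank, miss, kept):
        feats = pd.DataFrame(
            {"rsd_pct": [rsd], "blank_pct": [blank], "missing_pct": [miss],
             "rsd_undefined": [False]},
            index=["f"],
        )
        rep = preprocess.QCReport(features=feats)
        retained = filter_features(rep, QCThresholds())
        assert (["f"] == retained) is kept

    def test_planted_violators_are_exactly_removed(self):
        meta = simulate.generate_cohort(CohortSpec(n_subjects=200, seed=1))
        n_feat = 60
        cv = np.full(n_feat, 0.05)
        bf = np.full(n_feat, 0.02)
        cq = np.full(n_feat, 0.02)
        cv[:10] = 0.8     # RSD violators
        bf[10:20] = 0.9   # blank violators
        cq[20:30] = 0.45  # missingness violators
        es = EffectSpec.null(n_feat, technical_cv=cv, blank_fraction=bf,
                             censor_quantile=cq, seed=2)
        tab, truth = simulate.generate_abundances(meta, es)
        censored = simulate.apply_left_censoring(tab, es, truth)
        qc, blanks = simulate.generate_qc_materials(tab, es, n_qc=30, n_blank=10, seed=3)
        rep = compute_feature_qc(censored, qc, blanks)
        retained = filter_features(rep, QCThresholds())
        removed = set(rep.removed)
        expected = {es.feature_names()[i] for i in range(30)}
        assert removed == expected
        assert len(retained) == n_feat - 30


class TestRosner:
    def test_gross_outlier_flagged(self):
        s = pd.Series([1.0, 2.0, 3.0, 100.0], index=list("abcd"))
        assert detect_outlier_samples(s, alpha=0.05, kmax=1) == ["d"]

    def test_reduces_to_grubbs_for_k1(self):
        # independent oracle: Grubbs' critical value at alpha, n
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        x[0] = 6.0
        s = pd.Series(x, index=[f"s{i}" for i in range(30)])
        n = 30
        t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        flagged = detect_outlier_samples(s, alpha=0.05, kmax=1)
        assert (g > g_crit) == (flagged == ["s0"])
        assert flagged == ["s0"]

    def test_null_level(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = pd.Series(rng.normal(size=200), index=[f"s{i}" for i in range(200)])
            hits += len(detect_outlier_samples(s, alpha=0.05, kmax=5)) > 0
        assert hits <= 2  # 0 flagged in >= 90% of replicates

    def test_constant_statistic_warns_and_flags_none(self):
        s = pd.Series([2.0] * 20, index=[f"s{i}" for i in range(20)])
        with pytest.warns(UserWarning, match="constant"):
            assert detect_outlier_samples(s) == []


class TestDeriveFeatures:
    raw = pd.DataFrame(
        {"A": [2.0, 4.0, np.nan], "B": [2.0, 2.0, 1.0], "C": [1.0, 2.0, 3.0]},
        index=["s1", "s2", "s3"],
    )

    def test_ratio_sum_mean(self):
        out = derive_features(
            self.raw,
            [
                FeatureRecipe("A_B", "ratio", ("A", "B")),
                FeatureRecipe("BplusC", "sum", ("B", "C")),
                FeatureRecipe("BCmean", "mean", ("B", "C")),
            ],
        )
        assert out.loc["s1", "A_B"] == 1.0
        assert out.loc["s2", "A_B"] == 2.0
        assert np.isnan(out.loc["s3", "A_B"])  # missing operand -> missing
        assert out.loc["s1", "BplusC"] == 3.0
        assert out.loc["s1", "BCmean"] == 1.5

    def test_zero_denominator_is_missing(self):
        raw = pd.DataFrame({"A": [1.0], "B": [0.0]}, index=["s1"])
        out = derive_features(raw, [FeatureRecipe("A_B", "ratio", ("A", "B"))])
        assert np.isnan(out.loc["s1", "A_B"])

    def test_unknown_operand_names_the_recipe(self):
        with pytest.raises(ConfigurationError, match="bad_recipe"):
            derive_features(self.raw, [FeatureRecipe("bad_recipe", "ratio", ("A", "Z"))])

    def test_bad_arity_rejected(self):
        with pytest.raises(ConfigurationError, match="ratio"):
            FeatureRecipe("x", "ratio", ("A",))


class TestLog2:
    def test_values(self):
        raw = pd.DataFrame({"f": [8.0, 1.0, np.nan]})
        out = log2_transform(raw)
        assert out["f"].tolist()[:2] == [3.0, 0.0]
        assert np.isnan(out["f"].iloc[2])

    def test_nonpositive_rejected_with_coordinates(self):
        raw = pd.DataFrame({"f": [1.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            log2_transform(raw)


class TestQRILC:
    def _censored_normal(self, seed, n=300, mu=10.0, sigma=2.0, q=0.2, n_samples=4):
        rng = np.random.default_rng(seed)
        truth = pd.DataFrame(
            rng.normal(mu, sigma, size=(n_samples, n)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"m{j}" for j in range(n)],
        )
        thr = truth.quantile(q, axis=1)
        censored = truth.where(truth.ge(thr, axis=0))
        return truth, censored

    def test_no_missing_is_identity(self):
        truth, _ = self._censored_normal(1)
        out, _ = qrilc_impute(truth, seed=0)
        pd.testing.assert_frame_equal(out, truth)

    def test_censored_normal_parameter_recovery(self):
        truth, censored = self._censored_normal(2)
        out, params = qrilc_impute(censored, seed=3)
        # per-unit estimates are noisy; their mean is tightly centered
        assert np.all(np.abs(params["mu_hat"] - 10.0) < 0.3)
        assert np.all(np.abs(params["sigma_hat"] - 2.0) < 0.3)
        assert abs(params["mu_hat"].mean() - 10.0) < 0.15

    def test_observed_preserved_and_truncation_respected(self):
        truth, censored = self._censored_normal(4)
        out, params = qrilc_impute(censored, tune=1.0, seed=5)
        obs = censored.notna()
        assert out.where(obs).equals(censored.where(obs))
        for sid in censored.index:
            miss = censored.loc[sid].isna()
            if not miss.any():
                continue
            m = miss.mean()
            bound = params.loc[sid, "mu_hat"] + params.loc[sid, "sigma_hat"] * stats.norm.ppf(m)
            assert out.loc[sid, miss].max() <= bound + 1e-9

    def test_qrilc_beats_minimum_imputation(self):
        wins = 0
        for seed in range(50):
            truth, censored = self._censored_normal(100 + seed, n=200, n_samples=3)
            out, _ = qrilc_impute(censored, seed=seed)
            miss = censored.isna()
            err_q = (out - truth)[miss].abs().mean(axis=1).mean()
            min_imp = censored.apply(lambda r: r.fillna(r.min()), axis=1)
            err_m = (min_imp - truth)[miss].abs().mean(axis=1).mean()
            wins += err_q < err_m
        assert wins >= 45

    def test_determinism(self):
        _, censored = self._censored_normal(6)
        a, _ = qrilc_impute(censored, seed=9)
        b, _ = qrilc_impute(censored, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_sparse_unit_rejected(self):
        df = pd.DataFrame(np.nan, index=["s1", "s2"], columns=[f"m{i}" for i in range(10)])
        df.iloc[:, :2] = 1.0
        with pytest.raises(ConfigurationError, match="30%"):
            qrilc_impute(df)


class TestAutoscale:
    def test_moments_and_two_point_column(self):
        tab = pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 5.0]})
        scaled, params = autoscale(tab)
        assert np.allclose(scaled["a"], [-np.sqrt(0.5), np.sqrt(0.5)])
        assert abs(scaled.mean()).max() < 1e-9
        assert abs(scaled.std(ddof=1) - 1).max() < 1e-9

    def test_idempotence(self, rng):
        tab = pd.DataFrame(rng.normal(size=(50, 4)))
        scaled, _ = autoscale(tab)
        rescaled, _ = autoscale(scaled)
        assert np.allclose(scaled, rescaled, atol=1e-9)

    def test_constant_feature_named(self):
        tab = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError, match="flat"):
            autoscale(tab)


class TestPipeline:
    def test_stage_contracts_hold_end_to_end(self, small_processed):
        ds = small_processed
        # autoscaled moments
        assert abs(ds.scaled.mean()).max() < 1e-9
        assert abs(ds.scaled.std(ddof=1) - 1).max() < 1e-9
        # imputation preserves observations bitwise on the log2 table
        obs = ds.log2.notna()
        assert ds.imputed.where(obs).equals(ds.log2.where(obs))
        # derived features present, shared indexing
        assert set(ds.derived_features) == {"r1", "s1", "m1"}
        for t in (ds.raw, ds.log2, ds.imputed, ds.scaled):
            assert t.index.equals(ds.scaled.index)
            assert t.columns.equals(ds.scaled.columns)
        # QC accounting sums
        rep = ds.qc_report
        assert len(rep.retained) + len(rep.removed) == len(rep.features)
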
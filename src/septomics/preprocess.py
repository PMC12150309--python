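"""Preprocessing: QC filtering, outliers, derived features, log2, QRILC, autoscaling.

The pipeline order is fixed and mirrors standard targeted-metabolomics
practice: feature QC filter -> sample-outlier removal -> derived-feature
construction (linear scale) -> log2 transform -> QRILC imputation of
left-censored missing values -> per-feature autoscaling.  RSD and blank
percentages are computed on the linear (untransformed) scale, where these
assay-level metrics are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ConfigurationError

__all__ = [
    "QCThresholds",
    "QCReport",
    "FeatureRecipe",
    "ProcessedDataset",
    "compute_feature_qc",
    "filter_features",
    "detect_outlier_samples",
    "derive_features",
    "log2_transform",
    "qrilc_impute",
    "autoscale",
    "preprocess_pipeline",
]


@dataclass
class QCThresholds:
    """Acceptance thresholds for feature QC and the sample outlier screen.

    Features are retained only with RSD over pooled-QC replicates < 30%,
    blank signal < 40% of the QC mean, and missingness < 20% (all strict
    inequalities).
    """

    max_rsd_pct: float = 30.0
    max_blank_pct: float = 40.0
    max_missing_pct: float = 20.0
    rosner_alpha: float = 0.05
    rosner_kmax: int = 5

    def validate(self) -> None:
        for name in ("max_rsd_pct", "max_blank_pct", "max_missing_pct"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ConfigurationError(f"{name} must be in (0, 100], got {v}")
        if self.rosner_kmax < 1:
            raise ConfigurationError("rosner_kmax must be >= 1")
        if not 0 < self.rosner_alpha < 1:
            raise ConfigurationError("rosner_alpha must be in (0, 1)")


@dataclass
class QCReport:
    """Per-feature QC metrics and pass flags plus per-sample outlier flags."""

    features: pd.DataFrame
    samples: pd.DataFrame | None = None

    @property
    def retained(self) -> list[str]:
        return list(self.features.index[self.features["pass_all"]])

    @property
    def removed(self) -> list[str]:
        return list(self.features.index[~self.features["pass_all"]])

    @property
    def outlier_samples(self) -> list[str]:
        if self.samples is None:
            return []
        return list(self.samples.index[self.samples["outlier"]])


@dataclass(frozen=True)
class FeatureRecipe:
    """A derived feature: a ratio of 2 operands, or a sum/mean of >= 2."""

    name: str
    kind: str  # ratio | sum | mean
    operands: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in ("ratio", "sum", "mean"):
            raise ConfigurationError(f"recipe {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "ratio" and len(self.operands) != 2:
            raise ConfigurationError(f"recipe {self.name!r}: ratio needs exactly 2 operands")
        if self.kind in ("sum", "mean") and len(self.operands) < 2:
            raise ConfigurationError(f"recipe {self.name!r}: {self.kind} needs >= 2 operands")


# ---------------------------------------------------------------------------
# Feature QC
# ---------------------------------------------------------------------------

def compute_feature_qc(
    samples: pd.DataFrame, qc: pd.DataFrame, blanks: pd.DataFrame
) -> QCReport:
    """Per-feature RSD, blank percentage and missingness on the linear scale.

    * ``rsd_pct``    = 100 * sd / mean over pooled-QC replicates (n-1 sd)
    * ``blank_pct``  = 100 * mean(blanks) / mean(QC pool)
    * ``missing_pct``= 100 * #missing / #study samples

    A feature whose QC mean is zero has undefined RSD and auto-fails with a
    flagged reason.
    """
    if len(qc) < 3:
        raise ConfigurationError("need >= 3 pooled-QC replicates for RSD")
    if len(blanks) < 2:
        raise ConfigurationError("need >= 2 blank replicates")
    common = samples.columns
    if not (qc.columns.equals(common) and blanks.columns.equals(common)):
        qc = qc.reindex(columns=common)
        blanks = blanks.reindex(columns=common)

    qc_mean = qc.mean(axis=0)
    qc_sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * qc_sd / qc_mean
        blank = 100.0 * blanks.mean(axis=0) / qc_mean
    missing = 100.0 * samples.isna().mean(axis=0)
    undefined = (qc_mean == 0) | qc_mean.isna()
    feats = pd.DataFrame(
        {
            "rsd_pct": rsd,
            "blank_pct": blank,
            "missing_pct": missing,
            "rsd_undefined": undefined,
        },
        index=common,
    )
    feats.index.name = "feature"
    return QCReport(features=feats)


def filter_features(report: QCReport, thr: QCThresholds) -> list[str]:
    """Apply the three acceptance rules (strict <) and return retained features."""
    thr.validate()
    f = report.features
    pass_rsd = (f["rsd_pct"] < thr.max_rsd_pct) & ~f["rsd_undefined"]
    pass_blank = f["blank_pct"] < thr.max_blank_pct
    pass_missing = f["missing_pct"] < thr.max_missing_pct
    f["pass_rsd"] = pass_rsd.fillna(False)
    f["pass_blank"] = pass_blank.fillna(False)
    f["pass_missing"] = pass_missing.fillna(False)
    f["pass_all"] = f["pass_rsd"] & f["pass_blank"] & f["pass_missing"]
    return report.retained


# ---------------------------------------------------------------------------
# Sample outliers: generalized ESD (Rosner) test
# ---------------------------------------------------------------------------

def detect_outlier_samples(
    is_summary: pd.Series, alpha: float = 0.05, kmax: int = 5
) -> list[str]:
    """Rosner's generalized extreme studentized deviate test.

    ``is_summary`` is a per-sample scalar (here: the mean log
    internal-standard response).  Iteratively removes the most extreme value,
    computes R_i = max|x - mean| / sd, compares each against the lambda_i
    critical value at level ``alpha``, and flags the samples up to the
    largest i with R_i > lambda_i.
    """
    x = is_summary.dropna()
    n = len(x)
    if n < kmax + 3:
        raise ConfigurationError(f"need >= kmax+3={kmax + 3} samples, got {n}")
    if x.std(ddof=1) == 0:
        warnings.warn("constant internal-standard statistic; no outliers flagged")
        return []
    values = x.copy()
    candidates: list[str] = []
    R = np.empty(kmax)
    lam = np.empty(kmax)
    for i in range(1, kmax + 1):
        mu, sd = values.mean(), values.std(ddof=1)
        if sd == 0:
            R[i - 1 :] = 0.0
            lam[i - 1 :] = np.inf
            break
        dev = (values - mu).abs()
        idx = dev.idxmax()
        R[i - 1] = dev.loc[idx] / sd
        ni = n - i + 1  # sample size at this iteration
        pcrit = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(pcrit, ni - 2)
        lam[i - 1] = (ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni)
        candidates.append(idx)
        values = values.drop(idx)
    flagged = 0
    for i in range(kmax, 0, -1):
        if R[i - 1] > lam[i - 1]:
            flagged = i
            break
    return candidates[:flagged]


# ---------------------------------------------------------------------------
# Derived features, log2, imputation, scaling
# ---------------------------------------------------------------------------

def derive_features(raw: pd.DataFrame, recipes: Iterable[FeatureRecipe]) -> pd.DataFrame:
    """Compute ratio/sum/mean features per sample on the linear scale.

    A derived value is missing whenever any operand is missing; a ratio with
    a zero denominator is missing for that sample.  Recipes referencing
    features absent from ``raw`` (e.g. removed by QC) raise a configuration
    error naming the recipe.
    """
    out = {}
    for r in recipes:
        missing_ops = [o for o in r.operands if o not in raw.columns]
        if missing_ops:
            raise ConfigurationError(
                f"recipe {r.name!r} references unavailable features {missing_ops}"
            )
        if r.name in raw.columns or r.name in out:
            raise ConfigurationError(f"derived feature name {r.name!r} is not unique")
        ops = raw[list(r.operands)]
        if r.kind == "ratio":
            a, b = ops.iloc[:, 0], ops.iloc[:, 1]
            vals = a / b.replace(0.0, np.nan)
        elif r.kind == "sum":
            vals = ops.sum(axis=1, skipna=False)
        else:  # mean
            vals = ops.mean(axis=1, skipna=False)
        out[r.name] = vals
    derived = pd.DataFrame(out, index=raw.index)
    return derived


def log2_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing stays missing; nonpositive values are errors."""
    vals = raw.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"nonpositive abundance at sample {raw.index[i]!r}, feature {raw.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(vals), index=raw.index, columns=raw.columns)


def qrilc_impute(
    logtab: pd.DataFrame,
    tune: float = 1.0,
    seed: int = 0,
    per_feature: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantile regression imputation of left-censored data (QRILC).

    Per sample (or per feature with ``per_feature=True``): with missing
    fraction m, the sorted observed values are assigned plotting positions
    ``p_k = m + (1 - m) (k - 0.5) / n_obs`` and regressed on the standard
    normal quantiles ``Phi^{-1}(p_k)``; the intercept and slope estimate the
    censored-normal mean mu and sd sigma.  Missing entries are drawn from
    ``Normal(mu, tune * sigma)`` truncated above at
    ``mu + tune * sigma * Phi^{-1}(m)``, i.e. from the left tail the
    censoring removed.  Observed entries are returned unchanged.

    Returns the imputed table and a per-unit (mu_hat, sigma_hat) frame.
    If the fitted slope is nonpositive the unit falls back to half-minimum
    imputation (observed minimum minus 1 on the log2 scale) with a warning.
    """
    if tune <= 0:
        raise ConfigurationError("tune must be > 0")
    work = logtab if per_feature else logtab.T  # columns = imputation units
    n_items = work.shape[0]
    obs_frac = work.notna().mean(axis=0)
    low = obs_frac[obs_frac < 0.3]
    if len(low):
        raise ConfigurationError(
            f"QRILC requires >= 30% observed values per unit; worst offenders: "
            f"{dict(low.sort_values().head(3).round(3))}"
        )
    rng = np.random.default_rng(seed)
    imputed = work.to_numpy(dtype=float).copy()
    params = pd.DataFrame(
        np.nan, index=work.columns, columns=["mu_hat", "sigma_hat"]
    )
    for c in range(work.shape[1]):
        col = imputed[:, c]
        miss = np.isnan(col)
        n_miss = int(miss.sum())
        obs = np.sort(col[~miss])
        n_obs = len(obs)
        m = n_miss / n_items
        # censored-normal fit from the observed upper part of the distribution
        p_k = m + (1.0 - m) * (np.arange(1, n_obs + 1) - 0.5) / n_obs
        z = stats.norm.ppf(p_k)
        slope, intercept = np.polyfit(z, obs, 1)
        params.iloc[c] = [intercept, slope]
        if n_miss == 0:
            continue
        if slope <= 0:
            warnings.warn(
                f"QRILC: nonpositive sigma for {work.columns[c]!r}; "
                "falling back to half-minimum imputation"
            )
            col[miss] = obs[0] - 1.0  # half of the minimum on the linear scale
            continue
        upper_z = stats.norm.ppf(m)  # truncation point in z units
        draws = stats.truncnorm.rvs(
            -np.inf, upper_z, loc=intercept, scale=tune * slope,
            size=n_miss, random_state=rng,
        )
        col[miss] = draws
    out = pd.DataFrame(imputed, index=work.index, columns=work.columns)
    if not per_feature:
        out = out.T
    params.index.name = "feature" if per_feature else "sample_id"
    return out, params


def autoscale(tab: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature standardization to mean 0, sd 1 (n-1 sd)."""
    if tab.isna().any().any():
        raise ConfigurationError("autoscale requires a complete (imputed) table")
    mean = tab.mean(axis=0)
    sd = tab.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ConfigurationError(
            f"cannot autoscale constant feature(s): {list(constant.index)[:5]}"
        )
    scaled = (tab - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    params.index.name = "feature"
    return scaled, params


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def default_recipes(feature_names: Sequence[str], n_derived: int = 42) -> list[FeatureRecipe]:
    """Deterministic ratio/sum/mean recipes over available measured features.

    Used to fill the derived-feature slots of a synthetic study (42 by
    default, giving the 254 measured + 42 derived = 296 layout).  Recipes
    cycle through ratio, sum and mean over consecutive feature pairs/triples
    so they are reproducible and reference only retained features.
    """
    names = list(feature_names)
    if len(names) < 3:
        raise ConfigurationError("need >= 3 features to build derived recipes")
    recipes = []
    kinds = ("ratio", "sum", "mean")
    i = 0
    for d in range(n_derived):
        kind = kinds[d % 3]
        arity = 2 if kind == "ratio" else 3
        ops = tuple(names[(i + k) % len(names)] for k in range(arity))
        recipes.append(FeatureRecipe(name=f"dr_{kind}_{d + 1:02d}", kind=kind, operands=ops))
        i = (i + arity) % len(names)
    return recipes


@dataclass
class ProcessedDataset:
    """All preprocessing outputs sharing one sample/feature index."""

    raw: pd.DataFrame        # retained measured + derived, linear scale
    log2: pd.DataFrame       # with missing values
    imputed: pd.DataFrame    # log2, complete
    scaled: pd.DataFrame     # autoscaled
    qc_report: QCReport
    scale_params: pd.DataFrame
    impute_params: pd.DataFrame
    derived_features: tuple[str, ...] = field(default_factory=tuple)


def preprocess_pipeline(
    features: pd.DataFrame,
    qc: pd.DataFrame,
    blanks: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    recipes: Sequence[FeatureRecipe] = (),
    thresholds: QCThresholds | None = None,
    tune: float = 1.0,
    seed: int = 0,
) -> ProcessedDataset:
    """Run the fixed preprocessing order and return a :class:`ProcessedDataset`.

    When ``metadata`` carries an ``is_log_mean`` column (per-sample internal
    standard summary), the Rosner test is used to drop outlier samples before
    any feature computation.
    """
    thresholds = thresholds or QCThresholds()
    report = compute_feature_qc(features, qc, blanks)
    retained = filter_features(report, thresholds)
    if not retained:
        raise ConfigurationError("no features survive QC filtering")
    kept = features[retained]

    if metadata is not None and "is_log_mean" in metadata.columns:
        stat = metadata.set_index("sample_id")["is_log_mean"].reindex(kept.index)
        outliers = detect_outlier_samples(
            stat, alpha=thresholds.rosner_alpha, kmax=thresholds.rosner_kmax
        )
        report.samples = pd.DataFrame(
            {"is_log_mean": stat, "outlier": stat.index.isin(outliers)}
        )
        report.samples.index.name = "sample_id"
        kept = kept.drop(index=outliers)
    # recompute missingness on the retained sample set for bookkeeping
    derived = derive_features(kept, recipes)
    raw = pd.concat([kept, derived], axis=1)
    logtab = log2_transform(raw)
    imputed, impute_params = qrilc_impute(logtab, tune=tune, seed=seed)
    scaled, scale_params = autoscale(imputed)
    return ProcessedDataset(
        raw=raw,
        log2=logtab,
        imputed=imputed,
        scaled=scaled,
        qc_report=report,
        scale_params=scale_params,
        impute_params=impute_params,
        derived_features=tuple(derived.columns),
    )
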
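"""Linear mixed-effects metabolome-wide screening over five group contrasts.

Each feature is modelled as

    y = b0 + b * contrast + sum_k g_k * confounder_k + u_subject + eps

with a per-subject random intercept, fitted by REML.  Two primary models
compare inflamed (SINS + sepsis) vs control ("Inflamed") and sepsis vs
non-sepsis ("Sepsis"); three pairwise models (C_SINS, C_S, SINS_S) aid
interpretation.  Screens report the estimate in autoscaled-log2 SD units,
Wald p, BH q over all features, the directed p-value
(-log10 p * sign(estimate)) and the fold change (ratio of group geometric
means on the pre-scaling data).

The random-intercept REML fit is profiled analytically: rotating each
subject's rows onto its mean/within-contrast basis diagonalizes the
marginal covariance, so the restricted likelihood reduces to a scalar
optimization over the variance ratio tau^2/sigma^2 with O(p^2) cost per
evaluation.  This keeps metabolome-wide screens (hundreds of features,
hundreds of replicates) fast while agreeing with a general mixed-model
fitter to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .preprocess import ProcessedDataset
from .simulate import (
    BINARY_CONFOUNDERS,
    CONFOUNDERS,
    CONTINUOUS_CONFOUNDERS,
    ConfigurationError,
)

__all__ = [
    "CONTRASTS",
    "ContrastSpec",
    "ConfounderSet",
    "RandomInterceptLMM",
    "identify_confounders",
    "welch_t",
    "fisher_exact_2x2",
    "fit_contrast_lmm",
    "run_screen",
    "bh_adjust",
    "directed_pvalue",
    "fold_change",
    "anova_three_group",
    "stratified_screen",
    "classify_trend",
    "TREND_CATEGORIES",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A binary group contrast: which samples enter, which groups code 1."""

    name: str
    included_groups: tuple[str, ...]
    case_groups: tuple[str, ...]  # groups coded 1; the rest code 0 (reference)

    def mask(self, metadata: pd.DataFrame) -> pd.Series:
        return metadata["group"].isin(self.included_groups)

    def code(self, metadata: pd.DataFrame) -> pd.Series:
        return metadata["group"].isin(self.case_groups).astype(float)


CONTRASTS: dict[str, ContrastSpec] = {
    "Inflamed": ContrastSpec("Inflamed", ("control", "SINS", "sepsis"), ("SINS", "sepsis")),
    "Sepsis": ContrastSpec("Sepsis", ("control", "SINS", "sepsis"), ("sepsis",)),
    "C_SINS": ContrastSpec("C_SINS", ("control", "SINS"), ("SINS",)),
    "C_S": ContrastSpec("C_S", ("control", "sepsis"), ("sepsis",)),
    "SINS_S": ContrastSpec("SINS_S", ("SINS", "sepsis"), ("sepsis",)),
}

TREND_CATEGORIES = (
    "shared_inflammation",
    "progressive_up",
    "progressive_down",
    "sepsis_specific",
    "sins_specific",
    "unclassified",
)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("welch_t needs n >= 2 per arm")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns the conditional odds ratio and the two-sided p summing
    hypergeometric probabilities <= the observed table's.  A zero row or
    column margin gives p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(int)
        if t.shape != (2, 2) or np.any(t < 0):
            raise ConfigurationError("fisher_exact_2x2 needs a nonnegative 2x2 integer table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return np.nan, 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def anova_three_group(y: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """One-way ANOVA F and p across the three study groups."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    arms = [y[groups == g] for g in np.unique(groups)]
    if len(arms) != 3 or any(len(a) < 2 for a in arms):
        raise ConfigurationError("anova_three_group needs 3 groups with n >= 2 each")
    if all(np.ptp(a) == 0 for a in arms) and len({a[0] for a in arms}) == 1:
        return 0.0, 1.0
    F, p = stats.f_oneway(*arms)
    if np.isnan(F):
        warnings.warn("ANOVA F undefined (zero within-group variance)")
    return float(F), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p excluded from m, NaN out."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    from statsmodels.stats.multitest import multipletests

    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def directed_pvalue(p: float, estimate: float) -> float:
    """-log10(p) times the sign of the estimate (0 when the estimate is 0)."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return float(-np.log10(p) * np.sign(estimate))


def fold_change(
    log2tab: pd.DataFrame,
    groups: pd.Series,
    pair: tuple[str | Sequence[str], str | Sequence[str]],
) -> pd.Series:
    """Ratio of group geometric means, pair = (reference, case).

    Computed on imputed log2 data prior to autoscaling:
    FC = 2 ** (mean_log2(case) - mean_log2(reference)).  Either side of the
    pair may be a single group label or a collection of labels.
    """
    ref, case = pair
    ref = (ref,) if isinstance(ref, str) else tuple(ref)
    case = (case,) if isinstance(case, str) else tuple(case)
    g = groups.reindex(log2tab.index)
    mref = g.isin(ref).to_numpy()
    mcase = g.isin(case).to_numpy()
    if mref.sum() == 0 or mcase.sum() == 0:
        raise ConfigurationError(f"empty group in fold_change pair {pair}")
    diff = log2tab.loc[mcase].mean(axis=0) - log2tab.loc[mref].mean(axis=0)
    return np.exp2(diff)


# ---------------------------------------------------------------------------
# Confounder identification
# ---------------------------------------------------------------------------

@dataclass
class ConfounderSet:
    """Covariates associated with the sepsis outcome or with the metabolome."""

    outcome_associated: list[str] = field(default_factory=list)
    metabolome_associated: list[str] = field(default_factory=list)
    pvalues: pd.DataFrame | None = None

    @property
    def union(self) -> list[str]:
        seen: list[str] = []
        for c in self.outcome_associated + self.metabolome_associated:
            if c not in seen:
                seen.append(c)
        return seen


def identify_confounders(
    metadata: pd.DataFrame,
    scaled: pd.DataFrame,
    alpha: float = 0.05,
    n_pcs: int = 5,
    covariates: Sequence[str] = CONFOUNDERS,
) -> ConfounderSet:
    """Screen candidate covariates for outcome and metabolome association.

    Outcome association (vs sepsis status): Fisher exact for categorical
    covariates, Welch t for continuous ones.  Metabolome association: each
    covariate is tested against the top ``n_pcs`` principal-component scores
    of the autoscaled table (Spearman for continuous covariates; Welch t /
    one-way ANOVA for categorical), flagged if any PC association has
    p < alpha.
    """
    meta = metadata.set_index("sample_id").reindex(scaled.index)
    sepsis = (meta["group"] == "sepsis").to_numpy()

    # principal-component scores of the metabolome
    vals = scaled.to_numpy(dtype=float)
    k = min(n_pcs, min(vals.shape) - 1)
    u, s, _ = np.linalg.svd(vals - vals.mean(axis=0), full_matrices=False)
    scores = u[:, :k] * s[:k]

    rows = []
    out_assoc, met_assoc = [], []
    for cov in covariates:
        v = meta[cov]
        continuous = cov in CONTINUOUS_CONFOUNDERS or (
            v.dtype.kind in "if" and v.nunique() > 2
        )
        levels = v.dropna().unique()
        if len(levels) < 2:
            warnings.warn(f"covariate {cov!r} has a single level; skipped")
            continue
        if sepsis.sum() < 2 or (~sepsis).sum() < 2:
            p_out = np.nan  # outcome association untestable without both arms
        elif continuous:
            _, p_out = welch_t(v[sepsis], v[~sepsis])
        else:
            tab = pd.crosstab(v, sepsis)
            if tab.shape == (2, 2):
                _, p_out = fisher_exact_2x2(tab.to_numpy())
            else:  # rare multi-level categorical: chi2
                p_out = float(stats.chi2_contingency(tab.to_numpy())[1])
        p_mets = []
        for j in range(k):
            pc = scores[:, j]
            if continuous:
                rho_p = stats.spearmanr(v, pc)
                p_mets.append(float(rho_p.pvalue))
            elif len(levels) == 2:
                m = v == sorted(levels)[-1]
                p_mets.append(welch_t(pc[m.to_numpy()], pc[~m.to_numpy()])[1])
            else:
                arms = [pc[(v == lv).to_numpy()] for lv in levels]
                p_mets.append(float(stats.f_oneway(*arms)[1]))
        p_met = min(p_mets)
        rows.append({"covariate": cov, "p_outcome": p_out, "p_metabolome": p_met})
        if p_out < alpha:
            out_assoc.append(cov)
        if p_met < alpha:
            met_assoc.append(cov)
    return ConfounderSet(
        outcome_associated=out_assoc,
        metabolome_associated=met_assoc,
        pvalues=pd.DataFrame(rows).set_index("covariate") if rows else None,
    )


# ---------------------------------------------------------------------------
# Random-intercept REML engine
# ---------------------------------------------------------------------------

class RandomInterceptLMM:
    """Profiled-REML fitter for y = X beta + u_subject + eps, shared X.

    Rotating each subject's rows onto an orthonormal basis whose first
    vector is the subject mean turns the marginal covariance
    ``sigma^2 (I + lambda Z Z')`` into a diagonal with entries
    ``1 + lambda * k_i`` (k_i = subject size) on the mean rows and 1 on the
    within rows.  The restricted likelihood then profiles to a 1-D search
    over lambda = tau^2 / sigma^2; sufficient statistics per eigenvalue
    class make each evaluation O(p^2).  Wald inference uses a t reference
    with n - p degrees of freedom, which reduces exactly to OLS when every
    subject has one sample or when lambda collapses to zero.
    """

    def __init__(self, X: np.ndarray, subjects: Sequence) -> None:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n <= p:
            raise ConfigurationError(f"need n > p, got n={n}, p={p}")
        self.n, self.p = n, p
        subjects = np.asarray(subjects)
        blocks = []
        evals = []
        order = []
        for subj in pd.unique(subjects):
            idx = np.flatnonzero(subjects == subj)
            kk = len(idx)
            Q = np.linalg.qr(np.ones((kk, 1)), mode="complete")[0]  # col 0 = 1/sqrt(k)
            blocks.append(Q.T)
            evals.extend([kk] + [0] * (kk - 1))
            order.extend(idx)
        self._R = sparse.block_diag(blocks, format="csr")
        self._order = np.asarray(order)
        self.evals = np.asarray(evals, dtype=float)
        self.Xrot = self._R @ X[self._order]
        # sufficient statistics per distinct eigenvalue
        self._eclasses = []
        for e in np.unique(self.evals):
            rows = self.evals == e
            Xe = self.Xrot[rows]
            self._eclasses.append((float(e), rows, Xe.T @ Xe, int(rows.sum())))

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self._R @ np.asarray(y, dtype=float)[self._order]

    def fit(self, y: np.ndarray) -> dict:
        yrot = self.rotate(y)
        n, p = self.n, self.p
        stats_e = []
        for e, rows, A, m in self._eclasses:
            ye = yrot[rows]
            stats_e.append((e, A, self.Xrot[rows].T @ ye, float(ye @ ye), m))

        def assemble(lam: float):
            XtX = np.zeros((p, p))
            Xty = np.zeros(p)
            yty = 0.0
            logdet = 0.0
            for e, A, b, q, m in stats_e:
                w = 1.0 / (1.0 + lam * e)
                XtX += w * A
                Xty += w * b
                yty += w * q
                logdet += m * np.log1p(lam * e)
            return XtX, Xty, yty, logdet

        def neg2reml(loglam: float) -> float:
            lam = np.exp(loglam)
            XtX, Xty, yty, logdet = assemble(lam)
            try:
                beta = np.linalg.solve(XtX, Xty)
            except np.linalg.LinAlgError:
                return np.inf
            rss = max(yty - Xty @ beta, 1e-300)
            sign, ld_xtx = np.linalg.slogdet(XtX)
            if sign <= 0:
                return np.inf
            return (n - p) * np.log(rss) + logdet + ld_xtx

        res = optimize.minimize_scalar(
            neg2reml, bounds=(-10.0, 10.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(np.exp(res.x))
        # compare against the tau^2 = 0 boundary
        XtX0, Xty0, yty0, _ = assemble(0.0)
        beta0 = np.linalg.solve(XtX0, Xty0)
        rss0 = max(yty0 - Xty0 @ beta0, 1e-300)
        f_zero = (n - p) * np.log(rss0) + np.linalg.slogdet(XtX0)[1]
        boundary = f_zero <= res.fun + 1e-10
        if boundary:
            lam_hat = 0.0
        XtX, Xty, yty, _ = assemble(lam_hat)
        beta = np.linalg.solve(XtX, Xty)
        rss = max(yty - Xty @ beta, 1e-300)
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
        return {
            "beta": beta,
            "se": se,
            "t": tvals,
            "p": pvals,
            "df": n - p,
            "sigma2": sigma2,
            "lambda": lam_hat,
            "tau2": lam_hat * sigma2,
            "converged": bool(res.success or boundary),
            "boundary": bool(boundary),
        }


def _design_matrix(
    meta: pd.DataFrame, contrast_code: pd.Series, confounders: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + contrast + confounder columns (continuous standardized)."""
    cols = [np.ones(len(meta)), contrast_code.to_numpy(dtype=float)]
    names = ["intercept", "contrast"]
    for cov in confounders:
        v = meta[cov]
        if cov in CONTINUOUS_CONFOUNDERS or v.dtype.kind in "if":
            x = v.to_numpy(dtype=float)
            sd = x.std()
            cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
            names.append(cov)
        else:
            levels = sorted(v.dropna().unique())
            for lv in levels[1:]:
                cols.append((v == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
    return np.column_stack(cols), names


def fit_contrast_lmm(
    y: pd.Series | np.ndarray,
    metadata: pd.DataFrame,
    contrast: str | ContrastSpec,
    confounders: Sequence[str] | ConfounderSet = (),
) -> dict:
    """Fit one feature's random-intercept LMM for one contrast.

    ``metadata`` rows must align with ``y``.  Samples outside the contrast's
    groups are dropped.  Returns estimate / se / p for the contrast
    coefficient plus variance components and convergence flags; a failed fit
    returns NaNs with ``converged=False`` rather than raising.
    """
    spec = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    conf = confounders.union if isinstance(confounders, ConfounderSet) else list(confounders)
    mask = spec.mask(metadata).to_numpy()
    meta = metadata.loc[mask]
    yv = np.asarray(y, dtype=float)[mask]
    X, names = _design_matrix(meta, spec.code(meta), conf)
    try:
        engine = RandomInterceptLMM(X, meta["subject_id"].to_numpy())
        fit = engine.fit(yv)
    except (np.linalg.LinAlgError, ConfigurationError) as exc:
        warnings.warn(f"LMM fit failed for contrast {spec.name}: {exc}")
        return {
            "contrast": spec.name, "estimate": np.nan, "se": np.nan, "p": np.nan,
            "converged": False, "boundary": False, "tau2": np.nan, "sigma2": np.nan,
        }
    j = names.index("contrast")
    return {
        "contrast": spec.name,
        "estimate": float(fit["beta"][j]),
        "se": float(fit["se"][j]),
        "p": float(fit["p"][j]),
        "df": fit["df"],
        "tau2": fit["tau2"],
        "sigma2": fit["sigma2"],
        "converged": fit["converged"],
        "boundary": fit["boundary"],
    }


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def run_screen(
    ds: ProcessedDataset | pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: str | ContrastSpec,
    confounders: Sequence[str] | ConfounderSet = (),
    log2tab: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Screen every feature under one contrast; BH q over all features.

    ``ds`` is a :class:`ProcessedDataset` (screen runs on its autoscaled
    table, fold changes on its imputed log2 table) or a bare autoscaled
    DataFrame (then ``log2tab`` supplies the fold-change data, optional).
    """
    if isinstance(ds, ProcessedDataset):
        scaled, log2tab = ds.scaled, ds.imputed
    else:
        scaled = ds
    spec = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    meta = metadata.set_index("sample_id").reindex(scaled.index).reset_index()
    mask = spec.mask(meta).to_numpy()
    meta_sub = meta.loc[mask]
    conf = confounders.union if isinstance(confounders, ConfounderSet) else list(confounders)
    X, names = _design_matrix(meta_sub, spec.code(meta_sub), conf)
    engine = RandomInterceptLMM(X, meta_sub["subject_id"].to_numpy())
    j = names.index("contrast")
    n, p = engine.n, engine.p

    rows = []
    vals = scaled.to_numpy(dtype=float)[mask]
    for f_idx, feature in enumerate(scaled.columns):
        try:
            fit = engine.fit(vals[:, f_idx])
            rows.append(
                {
                    "feature": feature,
                    "estimate": float(fit["beta"][j]),
                    "se": float(fit["se"][j]),
                    "p": float(fit["p"][j]),
                    "converged": fit["converged"],
                    "boundary": fit["boundary"],
                }
            )
        except np.linalg.LinAlgError:
            rows.append(
                {"feature": feature, "estimate": np.nan, "se": np.nan, "p": np.nan,
                 "converged": False, "boundary": False}
            )
    res = pd.DataFrame(rows).set_index("feature")
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["directed_p"] = [
        directed_pvalue(pv, est) if pv > 0 and not np.isnan(pv) else np.nan
        for pv, est in zip(res["p"], res["estimate"])
    ]
    if log2tab is not None:
        ref = tuple(g for g in spec.included_groups if g not in spec.case_groups)
        groups = meta.set_index("sample_id")["group"]
        fc = fold_change(log2tab.loc[scaled.index[mask]], groups, (ref, spec.case_groups))
        res["fc"] = fc
    res.attrs["contrast"] = spec.name
    res.attrs["n_samples"] = int(mask.sum())
    return res


def stratified_screen(
    ds: ProcessedDataset | pd.DataFrame,
    metadata: pd.DataFrame,
    stratum: str,
    level: str,
    confounders: Sequence[str] | ConfounderSet = (),
    contrast: str = "Sepsis",
    log2tab: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sepsis-model screen on a stratified subset.

    * ``sex``: all samples of the given sex.
    * ``pathogen_type``: sepsis samples of the given pathogen vs all
      non-sepsis samples.
    * ``culture_outcome``: sepsis samples with the given culture outcome vs
      all non-sepsis samples.

    The stratum variable is removed from the confounder set automatically.
    """
    if stratum not in ("sex", "pathogen_type", "culture_outcome"):
        raise ConfigurationError(f"unsupported stratum {stratum!r}")
    meta = metadata.copy()
    if stratum == "sex":
        keep = meta["sex"] == level
    else:
        is_sepsis = meta["group"] == "sepsis"
        keep = ~is_sepsis | (meta[stratum] == level)
    meta = meta.loc[keep]
    spec = CONTRASTS[contrast]
    codes = spec.code(meta)
    if codes.nunique() < 2:
        raise ConfigurationError(
            f"stratum {stratum}={level!r} leaves a single class for contrast {contrast}"
        )
    conf = confounders.union if isinstance(confounders, ConfounderSet) else list(confounders)
    conf = [c for c in conf if c != stratum]
    scaled = ds.scaled if isinstance(ds, ProcessedDataset) else ds
    sub_ids = scaled.index.intersection(meta["sample_id"])
    sub = scaled.loc[sub_ids]
    if isinstance(ds, ProcessedDataset):
        log2tab = ds.imputed
    res = run_screen(
        sub, meta, contrast, conf,
        log2tab=log2tab.loc[sub_ids] if log2tab is not None else None,
    )
    res.attrs["stratum"] = f"{stratum}={level}"
    return res


def classify_trend(
    c_sins: Mapping[str, float],
    c_s: Mapping[str, float],
    sins_s: Mapping[str, float],
    means: Mapping[str, float],
    alpha: float = 0.05,
) -> str:
    """Assign a feature to a trend category from its three pairwise models.

    Uses the compact-letter convention on uncorrected p < alpha:

    * ``shared_inflammation``: control differs from both SINS and sepsis in
      the same direction, SINS and sepsis indistinguishable;
    * ``progressive_up``/``_down``: control-vs-SINS and SINS-vs-sepsis both
      significant with the same sign and monotone group means;
    * ``sepsis_specific``: sepsis differs from both others, control and SINS
      indistinguishable;
    * ``sins_specific``: SINS differs from control, sepsis does not, and
      SINS-vs-sepsis is either non-significant (small samples) or significant
      in the direction opposite to control-vs-SINS (the compact-letter
      pattern a/b/a at large samples);
    * otherwise ``unclassified``.
    """
    for r in (c_sins, c_s, sins_s):
        if r is None or np.isnan(r.get("p", np.nan)):
            return "unclassified"
    sig = {
        "C_SINS": c_sins["p"] < alpha,
        "C_S": c_s["p"] < alpha,
        "SINS_S": sins_s["p"] < alpha,
    }
    sgn = {
        "C_SINS": np.sign(c_sins["estimate"]),
        "C_S": np.sign(c_s["estimate"]),
        "SINS_S": np.sign(sins_s["estimate"]),
    }
    if sig["C_SINS"] and sig["C_S"] and sgn["C_SINS"] == sgn["C_S"] and not sig["SINS_S"]:
        return "shared_inflammation"
    if sig["C_SINS"] and sig["SINS_S"] and sgn["C_SINS"] == sgn["SINS_S"]:
        mono_up = means["control"] <= means["SINS"] <= means["sepsis"]
        mono_dn = means["control"] >= means["SINS"] >= means["sepsis"]
        if mono_up and sgn["C_SINS"] > 0:
            return "progressive_up"
        if mono_dn and sgn["C_SINS"] < 0:
            return "progressive_down"
    if sig["SINS_S"] and sig["C_S"] and not sig["C_SINS"]:
        return "sepsis_specific"
    if sig["C_SINS"] and not sig["C_S"] and (
        not sig["SINS_S"] or sgn["SINS_S"] == -sgn["C_SINS"]
    ):
        return "sins_specific"
    return "unclassified"
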
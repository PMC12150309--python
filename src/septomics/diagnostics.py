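"""Diagnostic modelling: STP curation, bootstrap LASSO, LOOCV, McNemar.

Works on the single-time-point (STP) data set — one sample per subject at
the moment of clinical suspicion — and asks how well metabolites separate
SINS from sepsis.  The framework: univariate logistic screening,
bootstrap-aggregated L1-penalized logistic regression with stability
selection (features chosen in over 45% of 100 bootstrap fits form the
panel), leave-one-out cross-validated panel evaluation, integration with
the routine inflammatory markers (IL-6, CRP, PCT), and paired model
comparison by McNemar's test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .preprocess import ProcessedDataset
from .simulate import MARKERS, ConfigurationError

__all__ = [
    "BootstrapResult",
    "PanelModel",
    "ModelComparison",
    "DiagnosticReport",
    "curate_stp",
    "univariate_logistic",
    "bootstrap_lasso",
    "select_panel",
    "loocv_evaluate",
    "mcnemar_exact_p",
    "compare_models_mcnemar",
    "run_diagnostics",
]


# ---------------------------------------------------------------------------
# STP curation
# ---------------------------------------------------------------------------

def curate_stp(metadata: pd.DataFrame) -> list[str]:
    """Select the single-time-point sample set: one sample per subject.

    Priority per subject: the first sepsis episode's suspected sample, else
    the first SINS episode's suspected sample.  Controls are eligible only
    for subjects with no SINS/sepsis occurrence anywhere in the study.
    Follow-up samples are never selected.
    """
    selected: list[str] = []
    sort_cols = [c for c in ("episode_index", "postnatal_age", "sample_id") if c in metadata.columns]
    for subject, sub in metadata.groupby("subject_id", sort=True):
        suspected = sub.loc[~sub["is_followup"].astype(bool)].sort_values(sort_cols)
        has_episode = sub["group"].isin(["SINS", "sepsis"]).any()
        if has_episode:
            for target in ("sepsis", "SINS"):
                hits = suspected.loc[suspected["group"] == target]
                if len(hits):
                    selected.append(str(hits.iloc[0]["sample_id"]))
                    break
            else:
                warnings.warn(
                    f"subject {subject!r} has episodes but no suspected sample; excluded"
                )
        else:
            if len(suspected):
                selected.append(str(suspected.iloc[0]["sample_id"]))
    return selected


# ---------------------------------------------------------------------------
# Univariate logistic screening
# ---------------------------------------------------------------------------

def _logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic fit; returns (beta, se, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + ridge * np.eye(p)
        g = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    H = X.T @ (X * W[:, None]) + ridge * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se, converged


def univariate_logistic(x: Sequence[float], y: Sequence[int]) -> dict:
    """Single-feature logistic regression with Wald p for the slope.

    On (quasi-)separation the maximum-likelihood slope diverges; the fit is
    then ridge-stabilized and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("both classes must be present")
    if len(y) < 10:
        raise ConfigurationError("univariate_logistic needs n >= 10")
    X = np.column_stack([np.ones_like(x), x])
    beta, se, converged = _logistic_irls(X, y)
    separated = (not converged) or np.abs(beta[1]) > 50 or not np.isfinite(se[1])
    if separated:
        beta, se, _ = _logistic_irls(X, y, ridge=1e-2)
    z = beta[1] / se[1]
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "estimate": float(beta[1]),
        "se": float(se[1]),
        "p": float(p),
        "separation": bool(separated),
    }


# ---------------------------------------------------------------------------
# Bootstrap-aggregated LASSO
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Aggregate of B bootstrap LASSO fits."""

    B: int
    seed: int
    oob_auc: np.ndarray
    oob_sensitivity: np.ndarray
    oob_specificity: np.ndarray
    selection_freq: pd.Series

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.oob_auc))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.oob_sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.oob_specificity))


_C_GRID = np.logspace(-2.0, 0.5, 6)


def _lasso_cv_fit(
    Xb: np.ndarray, yb: np.ndarray, rng: np.random.Generator
) -> LogisticRegression:
    """L1 logistic fit with the penalty chosen by 5-fold CV deviance.

    Uses the one-standard-error rule: the strongest penalty whose mean CV
    deviance lies within one SE of the minimum.  At these sample sizes the
    raw CV minimum admits many noise features; the 1-SE rule is the
    standard sparser choice and is what makes selection frequencies
    informative for stability selection.
    """
    kf = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(rng.integers(2**31)))
    dev = []  # per fold, per C mean deviance
    for tr, va in kf.split(Xb, yb):
        if len(np.unique(yb[va])) < 2 or len(np.unique(yb[tr])) < 2:
            continue
        fold = []
        for C in _C_GRID:
            clf = LogisticRegression(l1_ratio=1, C=C, solver="liblinear", max_iter=200)
            clf.fit(Xb[tr], yb[tr])
            fold.append(log_loss(yb[va], clf.predict_proba(Xb[va])[:, 1], labels=[0, 1]))
        dev.append(fold)
    dev = np.asarray(dev)
    mean = dev.mean(axis=0)
    best = int(np.argmin(mean))
    se = dev[:, best].std(ddof=1) / np.sqrt(len(dev))
    within = np.flatnonzero(mean <= mean[best] + se)
    C_best = _C_GRID[int(within[0])]  # grid ascends in C: first = strongest penalty
    clf = LogisticRegression(l1_ratio=1, C=C_best, solver="liblinear", max_iter=500)
    clf.fit(Xb, yb)
    return clf


def bootstrap_lasso(
    X: pd.DataFrame, y: Sequence[int], B: int = 100, seed: int = 0
) -> BootstrapResult:
    """Class-stratified bootstrap of L1-penalized logistic regression.

    For each of ``B`` iterations: resample each class with replacement at
    its observed size, pick the L1 penalty by 5-fold cross-validated
    deviance on the bootstrap sample, record the nonzero-coefficient
    features, and score AUC / sensitivity / specificity (threshold 0.5) on
    the out-of-bag samples.  Iterations whose out-of-bag set lacks a class
    contribute no metrics.
    """
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    cls0 = np.flatnonzero(y == 0)
    cls1 = np.flatnonzero(y == 1)
    if len(cls0) < 5 or len(cls1) < 5:
        raise ConfigurationError("need >= 5 members per class for bootstrap_lasso")
    rng = np.random.default_rng(seed)
    sel_counts = np.zeros(X.shape[1])
    auc = np.full(B, np.nan)
    sens = np.full(B, np.nan)
    spec = np.full(B, np.nan)
    for b in range(B):
        idx = np.concatenate([
            rng.choice(cls0, size=len(cls0), replace=True),
            rng.choice(cls1, size=len(cls1), replace=True),
        ])
        oob = np.setdiff1d(np.arange(n), np.unique(idx))
        clf = _lasso_cv_fit(Xv[idx], y[idx], rng)
        coefs = clf.coef_.ravel()
        sel_counts += coefs != 0
        if len(oob) and len(np.unique(y[oob])) == 2:
            prob = clf.predict_proba(Xv[oob])[:, 1]
            yo = y[oob]
            if len(np.unique(prob)) > 1:
                auc[b] = roc_auc_score(yo, prob)
            else:
                auc[b] = 0.5
            pred = prob >= 0.5
            sens[b] = (pred & (yo == 1)).sum() / max((yo == 1).sum(), 1)
            spec[b] = (~pred & (yo == 0)).sum() / max((yo == 0).sum(), 1)
    return BootstrapResult(
        B=B,
        seed=seed,
        oob_auc=auc,
        oob_sensitivity=sens,
        oob_specificity=spec,
        selection_freq=pd.Series(sel_counts / B, index=X.columns, name="selection_freq"),
    )


def select_panel(freqs: pd.Series | Mapping[str, float], threshold: float = 0.45) -> list[str]:
    """Features selected in strictly more than ``threshold`` of bootstrap fits."""
    if not 0 <= threshold < 1:
        raise ConfigurationError("threshold must be in [0, 1)")
    s = pd.Series(freqs, dtype=float)
    panel = s[s > threshold].sort_values(ascending=False)
    if panel.empty:
        warnings.warn(f"no feature exceeds selection frequency {threshold}")
    return list(panel.index)


# ---------------------------------------------------------------------------
# LOOCV evaluation
# ---------------------------------------------------------------------------

@dataclass
class PanelModel:
    """LOOCV-evaluated logistic model on a feature panel (plus markers)."""

    features: tuple[str, ...]
    markers: tuple[str, ...]
    probs: pd.Series
    roc: pd.DataFrame
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    f1: float
    threshold: float
    n_separation_flags: int = 0

    @property
    def name(self) -> str:
        parts = []
        if self.features:
            parts.append("panel")
        parts.extend(self.markers)
        return "+".join(parts) if parts else "null"


def loocv_evaluate(
    X_panel: pd.DataFrame | None,
    y: Sequence[int],
    markers: pd.DataFrame | None = None,
) -> PanelModel:
    """Leave-one-out cross-validated logistic model.

    For each sample, an unpenalized logistic regression is fitted on the
    remaining samples and the held-out probability recorded.  The ROC/AUC is
    computed on the out-of-fold probabilities; sensitivity, specificity, PPV
    and F1 are reported at the probability threshold maximizing Youden's J.
    A fold exhibiting separation is refitted with a small ridge penalty and
    counted in ``n_separation_flags``.
    """
    parts = [df for df in (X_panel, markers) if df is not None and df.shape[1]]
    if not parts:
        raise ConfigurationError("need at least one feature or marker column")
    Xdf = pd.concat(parts, axis=1)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 10:
        raise ConfigurationError("loocv_evaluate needs n >= 10")
    Xv = Xdf.to_numpy(dtype=float)
    Xv = np.column_stack([np.ones(n), Xv])
    probs = np.empty(n)
    flags = 0
    for i in range(n):
        keep = np.arange(n) != i
        beta, _, converged = _logistic_irls(Xv[keep], y[keep].astype(float))
        if not converged or np.abs(beta).max() > 50:
            flags += 1
            beta, _, _ = _logistic_irls(Xv[keep], y[keep].astype(float), ridge=1e-2)
        eta = np.clip(Xv[i] @ beta, -30, 30)
        probs[i] = 1.0 / (1.0 + np.exp(-eta))
    fpr, tpr, thr = roc_curve(y, probs)
    auc = float(roc_auc_score(y, probs)) if len(np.unique(probs)) > 1 else 0.5
    j = tpr - fpr
    best = int(np.argmax(j))
    cut = float(min(thr[best], 1.0))
    pred = probs >= cut
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    ppv = tp / max(tp + fp, 1)
    f1 = 2 * tp / max(2 * tp + fp + fn, 1)
    return PanelModel(
        features=tuple(X_panel.columns) if X_panel is not None else (),
        markers=tuple(markers.columns) if markers is not None else (),
        probs=pd.Series(probs, index=Xdf.index, name="loocv_prob"),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=auc,
        sensitivity=float(sens),
        specificity=float(spec),
        ppv=float(ppv),
        f1=float(f1),
        threshold=cut,
        n_separation_flags=flags,
    )


# ---------------------------------------------------------------------------
# McNemar comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    model_a: str
    model_b: str
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float | None
    exact: bool
    p: float


def mcnemar_exact_p(b: int, c: int) -> float:
    """Exact two-sided binomial McNemar p on the discordant pairs."""
    n = b + c
    if n == 0:
        return 1.0
    return float(stats.binomtest(b, n, 0.5).pvalue)


def compare_models_mcnemar(
    preds_a: Sequence[float],
    preds_b: Sequence[float],
    y: Sequence[int],
    threshold: float = 0.5,
    name_a: str = "A",
    name_b: str = "B",
) -> ModelComparison:
    """McNemar's test on paired classification outcomes of two models.

    Samples are classified correct/incorrect per model at ``threshold``.
    The exact binomial branch is used when the discordant count b + c < 25,
    else the chi-square with continuity correction ((|b-c|-1)^2 / (b+c)).
    """
    pa = np.asarray(preds_a, dtype=float)
    pb = np.asarray(preds_b, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (len(pa) == len(pb) == len(y)):
        raise ConfigurationError("predictions and labels must align")
    ca = (pa >= threshold).astype(int) == y
    cb = (pb >= threshold).astype(int) == y
    b = int((ca & ~cb).sum())
    c = int((~ca & cb).sum())
    if b + c < 25:
        return ModelComparison(name_a, name_b, b, c, None, True, mcnemar_exact_p(b, c))
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return ModelComparison(name_a, name_b, b, c, float(chi2), False, p)


# ---------------------------------------------------------------------------
# Consolidated diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """All outputs of the STP diagnostic framework."""

    stp_samples: list[str]
    univariate: pd.DataFrame
    bootstrap: BootstrapResult
    panel: list[str]
    models: dict[str, PanelModel] = field(default_factory=dict)
    comparisons: list[ModelComparison] = field(default_factory=list)
    seed: int = 0


def _marker_design(meta: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    """Markers log-transformed and autoscaled for use as model covariates."""
    logm = np.log(meta[list(markers)].astype(float))
    return (logm - logm.mean()) / logm.std(ddof=1)


def run_diagnostics(
    ds: ProcessedDataset,
    metadata: pd.DataFrame,
    B: int = 100,
    freq_threshold: float = 0.45,
    seed: int = 0,
    markers: Sequence[str] = MARKERS,
) -> DiagnosticReport:
    """Run the full SINS-vs-sepsis diagnostic framework on the STP data set.

    Fits and LOOCV-evaluates nine model variants: the stable metabolite
    panel alone, each inflammatory marker alone, all markers combined, the
    panel plus each marker, and the panel plus all markers; every variant is
    compared against the panel model with McNemar's test.
    """
    stp = curate_stp(metadata)
    meta = metadata.set_index("sample_id").loc[[s for s in stp if s in ds.scaled.index]]
    meta = meta.loc[meta["group"].isin(["SINS", "sepsis"])]
    if meta["group"].nunique() < 2:
        raise ConfigurationError("STP subset lacks one of SINS/sepsis")
    ids = meta.index
    X = ds.scaled.loc[ids]
    y = (meta["group"] == "sepsis").to_numpy(dtype=int)

    uni_rows = []
    for feature in X.columns:
        try:
            r = univariate_logistic(X[feature].to_numpy(), y)
        except ConfigurationError:
            r = {"estimate": np.nan, "se": np.nan, "p": np.nan, "separation": False}
        r["feature"] = feature
        uni_rows.append(r)
    uni = pd.DataFrame(uni_rows).set_index("feature")
    uni["q"] = np.nan
    ok = ~uni["p"].isna()
    from .screen import bh_adjust

    uni.loc[ok, "q"] = bh_adjust(uni.loc[ok, "p"].to_numpy())

    boot = bootstrap_lasso(X, y, B=B, seed=seed)
    panel = select_panel(boot.selection_freq, freq_threshold)

    mk = _marker_design(meta, markers)
    models: dict[str, PanelModel] = {}
    if panel:
        models["panel"] = loocv_evaluate(X[panel], y)
    for m in markers:
        models[m] = loocv_evaluate(None, y, markers=mk[[m]])
    models["markers_all"] = loocv_evaluate(None, y, markers=mk)
    if panel:
        for m in markers:
            models[f"panel+{m}"] = loocv_evaluate(X[panel], y, markers=mk[[m]])
        models["panel+markers_all"] = loocv_evaluate(X[panel], y, markers=mk)

    comparisons = []
    if panel:
        ref = models["panel"]
        for name, model in models.items():
            if name == "panel":
                continue
            comparisons.append(
                compare_models_mcnemar(
                    ref.probs.to_numpy(), model.probs.to_numpy(), y,
                    threshold=0.5, name_a="panel", name_b=name,
                )
            )
    return DiagnosticReport(
        stp_samples=list(ids),
        univariate=uni,
        bootstrap=boot,
        panel=panel,
        models=models,
        comparisons=comparisons,
        seed=seed,
    )
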
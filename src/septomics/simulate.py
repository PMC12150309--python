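"""Synthetic cohorts and abundance tables with known ground truth.

Generates preterm-neonate case-control cohorts (control / SINS / sepsis),
log2-scale metabolite abundances with planted group effects, confounder
loadings, subject-level random intercepts, left-censored missingness,
pooled-QC and blank replicates, and weakly discriminative inflammatory
markers (IL-6, CRP, PCT).  Every generator is a pure function of its spec
and seed, and each run returns a :class:`GroundTruth` recording the planted
parameters so downstream stages can be validated against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CohortSpec",
    "EffectSpec",
    "MarkerSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_abundances",
    "apply_left_censoring",
    "generate_qc_materials",
    "generate_markers",
    "simulate_study",
    "StudyBundle",
    "GROUPS",
    "CONTINUOUS_CONFOUNDERS",
    "BINARY_CONFOUNDERS",
    "CONFOUNDERS",
    "FEATURE_CLASSES",
]


class ConfigurationError(ValueError):
    """A spec field fails its validity constraints."""


GROUPS = ("control", "SINS", "sepsis")
PATHOGEN_TYPES = ("culture_negative", "gram_positive", "gram_negative")

#: The ten confounder covariates carried on every sample.
CONTINUOUS_CONFOUNDERS = (
    "gestational_age",
    "birthweight",
    "postnatal_age",
    "tpn_proportion",
    "oxygen_pct",
)
BINARY_CONFOUNDERS = (
    "sex",
    "sample_source",
    "mechanical_ventilation",
    "ivh",
    "antibiotics_24h",
)
CONFOUNDERS = CONTINUOUS_CONFOUNDERS + BINARY_CONFOUNDERS

FEATURE_CLASSES = (
    "null",
    "shared_inflammation",
    "progressive",
    "sepsis_specific",
    "sins_specific",
    "sex_specific",
    "pathogen_specific",
)

MARKERS = ("IL6", "CRP", "PCT")

# Cohort-level distribution parameters for the confounder covariates
# (continuous: mean/sd on the natural scale; binary: Bernoulli p).
# Mechanical ventilation and IVH additionally carry a log-odds shift for
# sepsis subjects, reflecting their association with sepsis outcome.
_DEFAULT_CONFOUNDER_DISTS: dict[str, dict[str, float]] = {
    "gestational_age": {"mean": 26.67, "sd": 2.07},
    "birthweight": {"mean": 891.9, "sd": 279.45},
    "postnatal_age": {"mean": 21.19, "sd": 18.45},
    "tpn_proportion": {"mean": 0.38, "sd": 0.38},
    "oxygen_pct": {"mean": 30.13, "sd": 14.33},
    "sample_source": {"p": 0.225},  # P(artery)
    "mechanical_ventilation": {"p": 0.41, "sepsis_log_or": 1.2},
    "ivh": {"p": 0.19, "sepsis_log_or": 1.2},
    "antibiotics_24h": {"p": 0.30, "sepsis_log_or": 1.0},
}


def _check_probs(name: str, probs: Sequence[float], k: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (k,):
        raise ConfigurationError(f"{name} must have length {k}, got shape {p.shape}")
    if np.any(p < 0):
        raise ConfigurationError(f"{name} has negative entries: {p}")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ConfigurationError(f"{name} must sum to 1 within 1e-12, sums to {p.sum()!r}")
    return p


def _check_prob(name: str, p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")
    return float(p)


@dataclass
class CohortSpec:
    """Cohort composition for the synthetic study.

    Defaults reproduce the scale of the study cohort: 180 subjects split so
    that, with a 50% follow-up rate for suspected episodes, expected sample
    counts are ~86 control, ~56 SINS and ~85 sepsis.  Confounder distribution
    parameters default to the cohort's demographic summary (gestational age
    26.67 +/- 2.07 weeks, birthweight 891.9 +/- 279.45 g, ...).
    """

    n_subjects: int = 180
    group_probs: tuple[float, float, float] = (86 / 180, 37 / 180, 57 / 180)
    followup_prob: float = 0.5
    male_prob: float = 0.599
    sepsis_culture_probs: tuple[float, float, float] = (42 / 85, 29 / 85, 14 / 85)
    confounder_dists: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CONFOUNDER_DISTS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError(f"n_subjects must be >= 3, got {self.n_subjects}")
        _check_probs("group_probs", self.group_probs, 3)
        _check_probs("sepsis_culture_probs", self.sepsis_culture_probs, 3)
        _check_prob("followup_prob", self.followup_prob)
        _check_prob("male_prob", self.male_prob)
        for cov, params in self.confounder_dists.items():
            if "sd" in params and params["sd"] <= 0:
                raise ConfigurationError(f"confounder_dists[{cov!r}] sd must be > 0")
            if "p" in params:
                _check_prob(f"confounder_dists[{cov!r}].p", params["p"])


def _as_feature_array(value, n_features: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_features,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite")
    return arr


@dataclass
class EffectSpec:
    """Planted feature effects and technical characteristics.

    Effect sizes are expressed in residual-SD units on the log2 scale so that
    magnitudes comparable to reported mixed-model estimates (~0.3-1.0) can be
    used directly.  ``technical_cv``, ``blank_fraction`` and
    ``censor_quantile`` accept a scalar or a per-feature array, which is how
    QC-rule violators are planted.
    """

    n_features: int = 254
    feature_classes: Sequence[str] | None = None
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "shared_inflammation": 20,
            "progressive": 12,
            "sepsis_specific": 12,
            "sins_specific": 4,
            "sex_specific": 8,
            "pathogen_specific": 8,
        }
    )
    effect_sizes: Sequence[float] | None = None
    effect_range: tuple[float, float] = (0.3, 1.0)
    confounder_loadings: np.ndarray | Mapping[str, Sequence[float]] | None = None
    subject_icc: float = 0.3
    residual_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    technical_cv: float | Sequence[float] = 0.10
    blank_fraction: float | Sequence[float] = 0.05
    censor_quantile: float | Sequence[float] = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not 0.0 <= self.subject_icc < 1.0:
            raise ConfigurationError(f"subject_icc must be in [0, 1), got {self.subject_icc}")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be > 0")
        cq = self.censor_quantiles()
        if np.any((cq < 0) | (cq > 0.5)):
            raise ConfigurationError("censor_quantile must lie in [0, 0.5]")
        if self.effect_sizes is not None:
            _as_feature_array(self.effect_sizes, self.n_features, "effect_sizes")
        classes = self.resolved_classes()
        unknown = set(classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown feature classes: {sorted(unknown)}")

    # -- resolved per-feature arrays -------------------------------------
    def feature_names(self) -> list[str]:
        width = max(3, len(str(self.n_features)))
        return [f"met_{i + 1:0{width}d}" for i in range(self.n_features)]

    def resolved_classes(self) -> np.ndarray:
        if self.feature_classes is not None:
            arr = np.asarray(self.feature_classes, dtype=object)
            if arr.shape != (self.n_features,):
                raise ConfigurationError(
                    f"feature_classes length {arr.shape} != n_features {self.n_features}"
                )
            return arr
        classes = np.array(["null"] * self.n_features, dtype=object)
        i = 0
        for cls, count in self.class_counts.items():
            take = min(count, self.n_features - i)
            classes[i : i + take] = cls
            i += take
        return classes

    def censor_quantiles(self) -> np.ndarray:
        return _as_feature_array(self.censor_quantile, self.n_features, "censor_quantile")

    def technical_cvs(self) -> np.ndarray:
        return _as_feature_array(self.technical_cv, self.n_features, "technical_cv")

    def blank_fractions(self) -> np.ndarray:
        return _as_feature_array(self.blank_fraction, self.n_features, "blank_fraction")

    def resolved_loadings(self) -> np.ndarray:
        """Per-feature coefficients on the confounders, (n_features, 10)."""
        if self.confounder_loadings is None:
            return np.zeros((self.n_features, len(CONFOUNDERS)))
        if isinstance(self.confounder_loadings, Mapping):
            out = np.zeros((self.n_features, len(CONFOUNDERS)))
            for cov, coefs in self.confounder_loadings.items():
                if cov not in CONFOUNDERS:
                    raise ConfigurationError(f"unknown confounder {cov!r} in loadings")
                out[:, CONFOUNDERS.index(cov)] = _as_feature_array(
                    coefs, self.n_features, f"confounder_loadings[{cov!r}]"
                )
            return out
        arr = np.asarray(self.confounder_loadings, dtype=float)
        if arr.shape != (self.n_features, len(CONFOUNDERS)):
            raise ConfigurationError(
                f"confounder_loadings must have shape ({self.n_features}, {len(CONFOUNDERS)})"
            )
        return arr

    # -- convenience constructors ----------------------------------------
    @classmethod
    def null(cls, n_features: int = 254, **kwargs) -> "EffectSpec":
        """All-null features: no group effects, no confounder loadings."""
        kwargs.setdefault("class_counts", {})
        return cls(n_features=n_features, **kwargs)

    @classmethod
    def planted(
        cls,
        n_features: int,
        classes: Mapping[int, str],
        effects: Mapping[int, float],
        **kwargs,
    ) -> "EffectSpec":
        """Explicitly place feature classes/effects at given feature indices."""
        cls_arr = np.array(["null"] * n_features, dtype=object)
        eff_arr = np.zeros(n_features)
        for i, c in classes.items():
            cls_arr[i] = c
        for i, e in effects.items():
            eff_arr[i] = e
        return cls(
            n_features=n_features,
            feature_classes=cls_arr,
            effect_sizes=eff_arr,
            **kwargs,
        )


@dataclass
class MarkerSpec:
    """Location shifts (in noise-SD units) of the log-scale inflammatory markers.

    Defaults give single-marker SINS-vs-sepsis AUCs of ~0.53-0.59
    (AUC = Phi(shift / sqrt(2)) under the binormal model), i.e. weakly
    discriminative markers.
    """

    inflamed_shift: Mapping[str, float] = field(
        default_factory=lambda: {"IL6": 0.8, "CRP": 0.8, "PCT": 0.8}
    )
    sepsis_shift: Mapping[str, float] = field(
        default_factory=lambda: {"IL6": 0.32, "CRP": 0.11, "PCT": 0.18}
    )
    noise_sd: float = 1.0
    seed: int = 0

    _LOCS = {"IL6": 3.0, "CRP": 2.0, "PCT": 0.5}

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """Planted parameters of one simulated study."""

    feature_names: list[str]
    feature_classes: np.ndarray
    effect_sizes: np.ndarray  # residual-SD units, signed
    #: per-contrast true shifts on the log2 scale, keyed by group
    sins_shift: np.ndarray
    sepsis_shift: np.ndarray
    #: target sex / pathogen of sex_specific / pathogen_specific features
    target_sex: dict[int, str]
    target_pathogen: dict[int, str]
    confounder_loadings: np.ndarray
    subject_icc: float
    residual_sd: float
    uncensored_log2: pd.DataFrame | None = None
    censor_thresholds: pd.Series | None = None


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort of subjects and emit one metadata row per sample.

    Control subjects contribute one sample.  SINS/sepsis subjects contribute
    one suspected-episode sample and, with probability ``followup_prob``, one
    follow-up sample carrying the same group label (follow-ups are
    consolidated into the episode's group).  Subject-level covariates
    (gestational age, birthweight, sex) are shared across a subject's
    samples; time-varying covariates are drawn per sample.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dists = {k: dict(_DEFAULT_CONFOUNDER_DISTS[k], **dict(spec.confounder_dists.get(k, {})))
             for k in _DEFAULT_CONFOUNDER_DISTS}

    groups = rng.choice(GROUPS, size=spec.n_subjects, p=_check_probs("group_probs", spec.group_probs, 3))
    sexes = np.where(rng.random(spec.n_subjects) < spec.male_prob, "male", "female")
    ga = rng.normal(dists["gestational_age"]["mean"], dists["gestational_age"]["sd"], spec.n_subjects)
    bw = rng.normal(dists["birthweight"]["mean"], dists["birthweight"]["sd"], spec.n_subjects)
    bw = np.clip(bw, 300.0, None)

    rows: list[dict] = []
    for i in range(spec.n_subjects):
        subject_id = f"N{i + 1:03d}"
        group = str(groups[i])
        if group == "sepsis":
            pathogen = str(rng.choice(PATHOGEN_TYPES, p=np.asarray(spec.sepsis_culture_probs)))
            culture = "negative" if pathogen == "culture_negative" else "positive"
        else:
            pathogen, culture = "none", "none"
        n_samples = 1
        followup_flags = [False]
        if group in ("SINS", "sepsis") and rng.random() < spec.followup_prob:
            n_samples = 2
            followup_flags = [False, True]
        base_pna = dists["postnatal_age"]["mean"] + dists["postnatal_age"]["sd"] * rng.standard_normal()
        base_pna = max(base_pna, 3.0)
        for k in range(n_samples):
            sepsis_bump = 1.0 if group == "sepsis" else 0.0
            row = {
                "sample_id": f"{subject_id}_s{k + 1}",
                "subject_id": subject_id,
                "group": group,
                "is_followup": followup_flags[k],
                "episode_index": 0 if group == "control" else 1,
                "sex": str(sexes[i]),
                "pathogen_type": pathogen,
                "culture_outcome": culture,
                "gestational_age": ga[i],
                "birthweight": bw[i],
                # follow-ups drawn 6-48 h after the suspected sample
                "postnatal_age": base_pna + (rng.uniform(0.25, 2.0) if k else 0.0),
                "tpn_proportion": float(np.clip(
                    rng.normal(dists["tpn_proportion"]["mean"], dists["tpn_proportion"]["sd"]), 0, 1)),
                "oxygen_pct": float(np.clip(
                    rng.normal(dists["oxygen_pct"]["mean"], dists["oxygen_pct"]["sd"]), 21, 100)),
                "sample_source": "artery" if rng.random() < dists["sample_source"]["p"] else "capillary",
                "mechanical_ventilation": int(rng.random() < _bump_p(
                    dists["mechanical_ventilation"], sepsis_bump)),
                "ivh": int(rng.random() < _bump_p(dists["ivh"], sepsis_bump)),
                "antibiotics_24h": int(rng.random() < dists["antibiotics_24h"]["p"]),
                # per-sample internal-standard summary (mean log response),
                # used by the Rosner outlier screen downstream
                "is_log_mean": rng.normal(0.0, 0.05),
            }
            rows.append(row)
    meta = pd.DataFrame(rows)
    for m in MARKERS:
        meta[m] = np.nan
    return meta


def _bump_p(params: Mapping[str, float], sepsis: float) -> float:
    """Bernoulli p with an optional log-odds shift for sepsis subjects."""
    logit = np.log(params["p"] / (1 - params["p"])) + sepsis * params.get("sepsis_log_or", 0.0)
    return float(1.0 / (1.0 + np.exp(-logit)))


# ---------------------------------------------------------------------------
# Abundance generation
# ---------------------------------------------------------------------------

def generate_abundances(
    metadata: pd.DataFrame, effects: EffectSpec
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a linear-scale feature table and its ground truth.

    The log2 abundance of feature *j* in sample *t* of subject *i* is

        y = baseline_j + shift_j(group, sex, pathogen) + x_t' L_j + u_i + eps

    with ``u_i ~ N(0, tau^2)``, ``eps ~ N(0, sigma^2)`` and
    ``tau^2 = icc / (1 - icc) * sigma^2``.  Planted shifts follow the feature
    class semantics: ``shared_inflammation`` shifts SINS and sepsis equally;
    ``progressive`` shifts SINS by half the sepsis shift; ``sepsis_specific``
    / ``sins_specific`` shift only the named group; ``sex_specific`` and
    ``pathogen_specific`` shift sepsis samples of the target sex / pathogen
    only.  The returned table is on the linear (peak-area-ratio) scale.
    """
    if metadata.empty:
        raise ConfigurationError("metadata is empty")
    effects.validate()
    rng = np.random.default_rng(effects.seed)

    n = len(metadata)
    p = effects.n_features
    classes = effects.resolved_classes()
    names = effects.feature_names()

    if effects.effect_sizes is not None:
        deltas = _as_feature_array(effects.effect_sizes, p, "effect_sizes")
    else:
        lo, hi = effects.effect_range
        deltas = rng.uniform(lo, hi, size=p) * rng.choice([-1.0, 1.0], size=p)
        deltas[classes == "null"] = 0.0

    target_sex: dict[int, str] = {}
    target_pathogen: dict[int, str] = {}
    sex_idx = np.flatnonzero(classes == "sex_specific")
    for k, j in enumerate(sex_idx):
        target_sex[int(j)] = "male" if k % 2 == 0 else "female"
    path_idx = np.flatnonzero(classes == "pathogen_specific")
    for k, j in enumerate(path_idx):
        target_pathogen[int(j)] = "gram_positive" if k % 2 == 0 else "gram_negative"

    sigma = effects.residual_sd
    tau = np.sqrt(effects.subject_icc / (1.0 - effects.subject_icc)) * sigma
    baselines = rng.normal(effects.baseline_mean, effects.baseline_sd, size=p)

    group = metadata["group"].to_numpy()
    sex = metadata["sex"].to_numpy()
    pathogen = metadata["pathogen_type"].to_numpy()
    is_sins = group == "SINS"
    is_sepsis = group == "sepsis"

    # per-feature group shift matrices (n,) built per class on the log2 scale
    shift = np.zeros((n, p))
    sins_shift = np.zeros(p)
    sepsis_shift = np.zeros(p)
    for j in range(p):
        d = deltas[j] * sigma
        cls = classes[j]
        if cls == "null" or d == 0.0:
            continue
        if cls == "shared_inflammation":
            sins_shift[j] = sepsis_shift[j] = d
            shift[:, j] = np.where(is_sins | is_sepsis, d, 0.0)
        elif cls == "progressive":
            sins_shift[j], sepsis_shift[j] = d / 2.0, d
            shift[:, j] = np.where(is_sepsis, d, np.where(is_sins, d / 2.0, 0.0))
        elif cls == "sepsis_specific":
            sepsis_shift[j] = d
            shift[:, j] = np.where(is_sepsis, d, 0.0)
        elif cls == "sins_specific":
            sins_shift[j] = d
            shift[:, j] = np.where(is_sins, d, 0.0)
        elif cls == "sex_specific":
            sepsis_shift[j] = d  # within the target sex
            shift[:, j] = np.where(is_sepsis & (sex == target_sex[j]), d, 0.0)
        elif cls == "pathogen_specific":
            sepsis_shift[j] = d  # within the target pathogen
            shift[:, j] = np.where(is_sepsis & (pathogen == target_pathogen[j]), d, 0.0)

    # confounder design: continuous covariates standardized, binaries centered
    loadings = effects.resolved_loadings()
    X = np.zeros((n, len(CONFOUNDERS)))
    for c, cov in enumerate(CONFOUNDERS):
        v = metadata[cov]
        if cov in CONTINUOUS_CONFOUNDERS:
            x = v.to_numpy(dtype=float)
            sd = x.std(ddof=1)
            X[:, c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
        else:
            x = _binary01(v)
            X[:, c] = x - x.mean()

    # per-feature, per-subject random intercepts (independent across features,
    # matching the screening model's assumption)
    subj_codes, subj_idx = np.unique(metadata["subject_id"].to_numpy(), return_inverse=True)
    u = rng.normal(0.0, tau, size=(len(subj_codes), p))[subj_idx, :]

    y = (
        baselines[None, :]
        + shift
        + X @ loadings.T
        + u
        + rng.normal(0.0, sigma, size=(n, p))
    )

    table = pd.DataFrame(np.exp2(y), index=metadata["sample_id"].to_numpy(), columns=names)
    table.index.name = "sample_id"
    truth = GroundTruth(
        feature_names=names,
        feature_classes=classes,
        effect_sizes=deltas,
        sins_shift=sins_shift,
        sepsis_shift=sepsis_shift,
        target_sex=target_sex,
        target_pathogen=target_pathogen,
        confounder_loadings=loadings,
        subject_icc=effects.subject_icc,
        residual_sd=sigma,
        uncensored_log2=pd.DataFrame(y, index=table.index, columns=names),
    )
    return table, truth


def apply_left_censoring(
    table: pd.DataFrame, effects: EffectSpec, truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Censor each feature below its empirical ``censor_quantile`` threshold.

    Missingness is strictly a threshold mechanism: for each feature the
    threshold is the stated quantile of the feature's marginal, and a value
    is missing iff it lies strictly below the threshold.  Thresholds are
    recorded on ``truth`` when given.  A quantile of 0 leaves the feature
    untouched.
    """
    q = effects.censor_quantiles()
    out = table.copy()
    thresholds = pd.Series(np.nan, index=table.columns, name="censor_threshold")
    vals = table.to_numpy(dtype=float)
    for j, col in enumerate(table.columns):
        if q[j] <= 0:
            continue
        thr = float(np.nanquantile(vals[:, j], q[j]))
        thresholds.iloc[j] = thr
        out.iloc[:, j] = np.where(vals[:, j] < thr, np.nan, vals[:, j])
    if truth is not None:
        truth.censor_thresholds = thresholds
    return out


def generate_qc_materials(
    table: pd.DataFrame,
    effects: EffectSpec,
    n_qc: int = 10,
    n_blank: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled-QC and method-blank replicate tables on the linear scale.

    A QC replicate is the per-feature grand mean of the study samples times
    mean-preserving lognormal technical noise with the feature's CV; a blank
    replicate is ``blank_fraction`` of the grand mean times the same noise
    model.  Rule violators are planted through per-feature ``technical_cv`` /
    ``blank_fraction`` arrays on the :class:`EffectSpec`.
    """
    if n_qc < 3:
        raise ConfigurationError("n_qc must be >= 3 (RSD undefined below that)")
    if n_blank < 2:
        raise ConfigurationError("n_blank must be >= 2")
    rng = np.random.default_rng(effects.seed + 1 if seed is None else seed)
    grand = np.nanmean(table.to_numpy(dtype=float), axis=0)
    cv = effects.technical_cvs()
    bf = effects.blank_fractions()

    def _noisy(base: np.ndarray, n_rep: int) -> np.ndarray:
        s2 = np.log1p(cv**2)
        ln = np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=(n_rep, len(base))))
        return base[None, :] * ln

    qc = pd.DataFrame(
        _noisy(grand, n_qc),
        index=[f"QC{i + 1:02d}" for i in range(n_qc)],
        columns=table.columns,
    )
    blanks = pd.DataFrame(
        _noisy(grand * bf, n_blank),
        index=[f"BLANK{i + 1:02d}" for i in range(n_blank)],
        columns=table.columns,
    )
    qc.index.name = blanks.index.name = "sample_id"
    return qc, blanks


def generate_markers(metadata: pd.DataFrame, mspec: MarkerSpec) -> pd.DataFrame:
    """Populate IL-6 / CRP / PCT with weakly discriminative lognormal values.

    The latent log-scale value is ``loc + inflamed_shift * [inflamed] +
    sepsis_shift * [sepsis] + noise``; single-marker SINS-vs-sepsis AUC is
    therefore Phi(sepsis_shift / (noise_sd * sqrt(2))).
    """
    mspec.validate()
    if "group" not in metadata.columns:
        raise ConfigurationError("metadata lacks a 'group' column")
    rng = np.random.default_rng(mspec.seed)
    out = metadata.copy()
    inflamed = out["group"].isin(["SINS", "sepsis"]).to_numpy(dtype=float)
    sepsis = (out["group"] == "sepsis").to_numpy(dtype=float)
    for m in MARKERS:
        latent = (
            MarkerSpec._LOCS[m]
            + mspec.inflamed_shift.get(m, 0.0) * mspec.noise_sd * inflamed
            + mspec.sepsis_shift.get(m, 0.0) * mspec.noise_sd * sepsis
            + rng.normal(0.0, mspec.noise_sd, size=len(out))
        )
        out[m] = np.exp(latent)
    return out


# ---------------------------------------------------------------------------
# One-call study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    metadata: pd.DataFrame
    features: pd.DataFrame  # censored, linear scale
    qc: pd.DataFrame
    blanks: pd.DataFrame
    truth: GroundTruth


def simulate_study(
    cohort: CohortSpec | None = None,
    effects: EffectSpec | None = None,
    markers: MarkerSpec | None = None,
    n_qc: int = 10,
    n_blank: int = 5,
    seed: int | None = None,
) -> StudyBundle:
    """Generate a complete study: cohort, markers, abundances, censoring, QC.

    When ``seed`` is given it overrides the seeds on all three specs
    (offset per generator so streams are independent).
    """
    cohort = cohort or CohortSpec()
    effects = effects or EffectSpec()
    markers = markers or MarkerSpec()
    if seed is not None:
        from dataclasses import replace

        cohort = replace(cohort, seed=seed)
        effects = replace(effects, seed=seed + 1)
        markers = replace(markers, seed=seed + 2)
    meta = generate_cohort(cohort)
    meta = generate_markers(meta, markers)
    features, truth = generate_abundances(meta, effects)
    censored = apply_left_censoring(features, effects, truth)
    qc, blanks = generate_qc_materials(features, effects, n_qc=n_qc, n_blank=n_blank)
    return StudyBundle(metadata=meta, features=censored, qc=qc, blanks=blanks, truth=truth)


def _binary01(v: pd.Series) -> np.ndarray:
    """Encode a two-level covariate as 0/1 (alphabetically larger level = 1)."""
    if v.dtype.kind in "ifb":
        return v.to_numpy(dtype=float)
    levels = sorted(v.unique())
    return (v.to_numpy() == levels[-1]).astype(float)
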
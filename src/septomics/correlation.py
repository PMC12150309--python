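"""Spearman and differential correlation of metabolites with inflammatory markers.

Within each condition (SINS, sepsis) metabolite-marker association is
summarized by Spearman's rank correlation; whether a metabolite-marker
relationship differs between the two conditions is tested by the Fisher
r-to-z two-sample comparison:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

with a two-sided normal p.  For Spearman correlations an optional variance
inflation of 1.06 (the Fieller adjustment) can be applied to each 1/(n-3)
term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ConfigurationError

__all__ = [
    "CorrelationResult",
    "DiffCorrelationResult",
    "spearman_group",
    "differential_correlation",
    "correlate_markers",
]


@dataclass
class CorrelationResult:
    feature: str
    marker: str
    group: str
    rho: float
    n: int
    p: float


@dataclass
class DiffCorrelationResult:
    feature: str
    marker: str
    rho_sins: float
    n_sins: int
    rho_sepsis: float
    n_sepsis: int
    z: float
    p: float


def spearman_group(
    x: Sequence[float], y: Sequence[float], feature: str = "", marker: str = "", group: str = ""
) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ConfigurationError("spearman_group needs n >= 4")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return CorrelationResult(feature, marker, group, np.nan, n, np.nan)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(feature, marker, group, float(rho), n, float(p))


def differential_correlation(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    feature: str = "",
    marker: str = "",
    spearman_adjust: bool = False,
) -> DiffCorrelationResult:
    """Fisher r-to-z test for a difference between two correlations.

    ``spearman_adjust=True`` multiplies each variance term 1/(n-3) by 1.06,
    the asymptotic inflation of the Fisher transform for Spearman's rho.
    """
    for r in (r1, r2):
        if not np.abs(r) < 1:
            raise ConfigurationError("|r| must be < 1 (Fisher transform diverges)")
    if n1 < 4 or n2 < 4:
        raise ConfigurationError("need n >= 4 per group")
    infl = 1.06 if spearman_adjust else 1.0
    var = infl / (n1 - 3) + infl / (n2 - 3)
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DiffCorrelationResult(feature, marker, float(r1), n1, float(r2), n2, float(z), float(p))


def correlate_markers(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    markers: Sequence[str] = ("IL6", "CRP", "PCT"),
    groups: Sequence[str] = ("SINS", "sepsis"),
    spearman_adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolite-marker Spearman correlations per group plus differential tests.

    ``features`` is a samples-by-features table (typically the imputed log2
    table restricted to the STP samples); metadata supplies group labels and
    marker values.  Returns (per-group correlations, differential results)
    as tidy DataFrames.
    """
    meta = metadata.set_index("sample_id").reindex(features.index)
    feature_names = list(feature_names) if feature_names is not None else list(features.columns)
    per_group = []
    diff = []
    g1, g2 = groups
    for feat in feature_names:
        for marker in markers:
            res = {}
            for g in groups:
                m = (meta["group"] == g).to_numpy()
                if m.sum() < 4:
                    continue
                r = spearman_group(
                    features.loc[m, feat], meta.loc[m, marker],
                    feature=feat, marker=marker, group=g,
                )
                per_group.append(r.__dict__)
                res[g] = r
            if g1 in res and g2 in res and all(
                np.isfinite(res[g].rho) and abs(res[g].rho) < 1 for g in groups
            ):
                d = differential_correlation(
                    res[g1].rho, res[g1].n, res[g2].rho, res[g2].n,
                    feature=feat, marker=marker, spearman_adjust=spearman_adjust,
                )
                diff.append(d.__dict__)
    return pd.DataFrame(per_group), pd.DataFrame(diff)
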
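"""File formats, validation and provenance-stamped CSV output.

All tabular outputs are plain CSV with ``#``-prefixed metadata header lines
(seed, config hash, package version) so runs are diff-able and
language-agnostic.  Missing values are serialized as empty cells — never as
sentinel numbers, which would collide with the left-censoring semantics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import FeatureRecipe
from .simulate import CONFOUNDERS, GROUPS, MARKERS, ConfigurationError

__all__ = [
    "read_feature_table",
    "write_table",
    "read_metadata",
    "read_recipes",
    "write_recipes",
    "read_metabolights_maf",
    "config_hash",
]

REQUIRED_METADATA = (
    ("sample_id", "subject_id", "group", "is_followup", "episode_index",
     "sex", "pathogen_type")
    + CONFOUNDERS
    + MARKERS
)
_VOCAB = {
    "group": set(GROUPS),
    "sex": {"male", "female"},
    "pathogen_type": {"none", "culture_negative", "gram_positive", "gram_negative"},
}


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=None)


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples-by-features CSV (first column ``sample_id``).

    Empty cells become missing values; duplicate sample IDs or feature names
    and non-numeric cells are rejected with coordinates.
    """
    df = _read_csv(path)
    if df.columns[0] != "sample_id":
        raise ConfigurationError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConfigurationError(f"{path}: duplicated sample_id values {dupes[:5]}")
    feats = df.columns[1:]
    if feats.duplicated().any():
        raise ConfigurationError(f"{path}: duplicated feature names")
    out = df.set_index("sample_id")
    for col in out.columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = out.index[bad.to_numpy().argmax()]
            raise ConfigurationError(
                f"{path}: non-numeric cell at sample {row!r}, feature {col!r}"
            )
        out[col] = coerced
    return out


def write_table(
    df: pd.DataFrame,
    path,
    seed: int | None = None,
    config: Mapping | None = None,
    index: bool = True,
) -> None:
    """Write a CSV with a ``#`` provenance header; NaN as empty cells."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# septomics {__version__}"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    if config is not None:
        header.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=index, na_rep="")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample metadata CSV.

    Checks required columns, normalizes stray whitespace/case in
    vocabulary-restricted columns (with a warning), and rejects unknown
    group labels.
    """
    df = _read_csv(path)
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing metadata column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ConfigurationError(f"{path}: duplicated sample_id values")
    for col, vocab in _VOCAB.items():
        vals = df[col].astype(str)
        stripped = vals.str.strip()
        fixes = {}
        for v in stripped.unique():
            if v in vocab:
                continue
            match = [w for w in vocab if w.lower() == v.lower()]
            if match:
                fixes[v] = match[0]
        if (stripped != vals).any() or fixes:
            warnings.warn(f"{path}: normalized {col!r} labels (whitespace/case)")
        norm = stripped.replace(fixes)
        unknown = sorted(set(norm.unique()) - vocab)
        if unknown:
            raise ConfigurationError(f"{path}: unknown {col} label(s) {unknown}")
        df[col] = norm
    df["is_followup"] = df["is_followup"].astype(bool)
    return df


def read_recipes(path) -> list[FeatureRecipe]:
    """Read derived-feature recipes: CSV columns name,kind,operands (';'-sep)."""
    df = _read_csv(path)
    need = {"name", "kind", "operands"}
    if not need.issubset(df.columns):
        raise ConfigurationError(f"{path}: recipe file needs columns {sorted(need)}")
    return [
        FeatureRecipe(
            name=str(r["name"]),
            kind=str(r["kind"]),
            operands=tuple(str(r["operands"]).split(";")),
        )
        for _, r in df.iterrows()
    ]


def write_recipes(recipes: Iterable[FeatureRecipe], path) -> None:
    rows = [
        {"name": r.name, "kind": r.kind, "operands": ";".join(r.operands)}
        for r in recipes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metabolights_maf(path, sample_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a MetaboLights metabolite-assignment TSV into a feature table.

    MAF files carry features as rows and samples as columns; the table is
    transposed on load so it matches the package's samples-by-features
    convention.  ``sample_columns`` restricts which columns are treated as
    samples; by default every column right of ``metabolite_identification``
    (or all purely numeric columns) is used.
    """
    df = pd.read_csv(path, sep="\t")
    name_col = next(
        (c for c in ("metabolite_identification", "database_identifier", "feature")
         if c in df.columns),
        df.columns[0],
    )
    if sample_columns is None:
        anchor = list(df.columns).index(name_col)
        candidates = df.columns[anchor + 1 :]
        sample_columns = [
            c for c in candidates if pd.to_numeric(df[c], errors="coerce").notna().any()
        ]
    out = df.set_index(name_col)[list(sample_columns)].apply(pd.to_numeric, errors="coerce").T
    out.index.name = "sample_id"
    out.columns.name = None
    return out


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
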
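import numpy as np
import pandas as pd
import pytest

from septomics import preprocess, simulate


@pytest.fixture(scope="session")
def small_study() -> simulate.StudyBundle:
    """A compact study with planted effects of every class."""
    cohort = simulate.CohortSpec(n_subjects=90, seed=11)
    effects = simulate.EffectSpec(
        n_features=40,
        class_counts={
            "shared_inflammation": 4,
            "progressive": 4,
            "sepsis_specific": 4,
            "sins_specific": 2,
            "sex_specific": 2,
            "pathogen_specific": 2,
        },
        censor_quantile=0.08,
        seed=12,
    )
    return simulate.simulate_study(cohort, effects, simulate.MarkerSpec(seed=13))


@pytest.fixture(scope="session")
def small_processed(small_study) -> preprocess.ProcessedDataset:
    b = small_study
    recipes = [
        preprocess.FeatureRecipe("r1", "ratio", ("met_001", "met_002")),
        preprocess.FeatureRecipe("s1", "sum", ("met_003", "met_004", "met_005")),
        preprocess.FeatureRecipe("m1", "mean", ("met_006", "met_007")),
    ]
    return preprocess.preprocess_pipeline(
        b.features, b.qc, b.blanks, metadata=b.metadata, recipes=recipes, seed=7
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def make_balanced_metadata(n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """One-sample-per-subject metadata with exactly n subjects per group."""
    cohort = simulate.CohortSpec(n_subjects=3 * n_per_group, followup_prob=0.0, seed=seed)
    meta = simulate.generate_cohort(cohort)
    groups = np.repeat(["control", "SINS", "sepsis"], n_per_group)
    meta = meta.iloc[: len(groups)].copy()
    meta["group"] = groups
    return meta
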
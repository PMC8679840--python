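import numpy as np
import pandas as pd
import pytest

from bloodstage import (
    CohortAnnotation,
    ExpressionMatrix,
    FeatureTable,
    SimulationConfig,
    generate_cohort,
    generate_signatures,
)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast, fully featured study: 5 cell types, 300 genes, 24 samples/cohort."""
    return SimulationConfig(
        n_genes=300,
        n_celltypes=5,
        genes_per_signature=8,
        group_sizes={"CON": 8, "MCI": 8, "AD": 8},
        n_de_genes=20,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_config):
    signatures = generate_signatures(small_config)
    X, ann, truth = generate_cohort(small_config, signatures, "cohortA")
    return signatures, X, ann, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_expression(values: np.ndarray, cohort: str = "c1", scale: str = "raw") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{cohort}_s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(frame, pd.Series(cohort, index=samples), scale=scale)


def make_features(values: np.ndarray, names=None, ftype: str = "mRNA") -> FeatureTable:
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"f{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=list(names), columns=samples)
    return FeatureTable(frame, pd.Series(ftype, index=frame.index))


def make_annotation(diagnoses, cohort="c1", prefix="s") -> CohortAnnotation:
    ids = [f"{prefix}{i}" for i in range(len(diagnoses))]
    return CohortAnnotation.from_lists(ids, list(diagnoses), cohort)
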
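"""Core in-memory containers shared across the pipeline.

Matrices follow the omics convention: genes (or features, or cell types) in
rows, samples in columns.  Sample metadata travels in a
:class:`CohortAnnotation` keyed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DIAGNOSES: tuple[str, ...] = ("CON", "MCI", "AD")
STAGE_CODE: dict[str, int] = {"CON": 0, "MCI": 1, "AD": 2}
LINEAGES: tuple[str, ...] = ("HSC", "Lymphoid", "Myeloid", "Epithelial", "Stroma")
HEMATOPOIETIC: frozenset[str] = frozenset({"HSC", "Lymphoid", "Myeloid"})

#: valid values of the ExpressionMatrix scale flag
SCALES = ("raw", "normalized", "log2")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with cohort tags and a scale flag.

    ``scale`` is ``raw`` for arbitrary intensity units, ``normalized`` after
    per-sample rescaling to a million-count total, and ``log2`` after the log
    transform.
    """

    values: pd.DataFrame  # genes x samples
    cohorts: pd.Series  # sample id -> cohort id
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        self.cohorts = pd.Series(self.cohorts).reindex(self.values.columns)
        if self.cohorts.isna().any():
            missing = list(self.cohorts.index[self.cohorts.isna()])
            raise ValueError(f"samples without cohort tag: {missing[:5]}")
        if self.scale != "log2" and (self.values.values < 0).any():
            raise ValueError("negative expression values on a non-log scale")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.cohorts.copy(), self.scale)


@dataclass
class CohortAnnotation:
    """Per-sample diagnosis (CON/MCI/AD), ordinal stage code and cohort id."""

    table: pd.DataFrame  # index: sample id; columns: diagnosis, stage, cohort

    def __post_init__(self) -> None:
        required = {"diagnosis", "stage", "cohort"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        bad = set(self.table["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise ValueError(f"unknown diagnoses: {sorted(bad)}")
        expected = self.table["diagnosis"].map(STAGE_CODE)
        if not (self.table["stage"] == expected).all():
            raise ValueError("stage codes inconsistent with diagnosis (CON=0, MCI=1, AD=2)")

    @classmethod
    def from_lists(
        cls,
        sample_ids: Sequence[str],
        diagnoses: Sequence[str],
        cohort: str | Sequence[str],
    ) -> "CohortAnnotation":
        cohorts = [cohort] * len(sample_ids) if isinstance(cohort, str) else list(cohort)
        table = pd.DataFrame(
            {
                "diagnosis": list(diagnoses),
                "stage": [STAGE_CODE[d] for d in diagnoses],
                "cohort": cohorts,
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        return cls(table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def diagnosis(self) -> pd.Series:
        return self.table["diagnosis"]

    @property
    def stage(self) -> pd.Series:
        return self.table["stage"]

    @property
    def cohort(self) -> pd.Series:
        return self.table["cohort"]

    def subset(self, sample_ids: Sequence[str]) -> "CohortAnnotation":
        return CohortAnnotation(self.table.loc[list(sample_ids)])

    def concat(self, other: "CohortAnnotation") -> "CohortAnnotation":
        return CohortAnnotation(pd.concat([self.table, other.table]))


@dataclass
class SignatureSet:
    """Marker-gene signatures per cell type plus a cell-type -> lineage map."""

    signatures: dict[str, list[str]]
    lineage_map: dict[str, str]

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
        unmapped = set(self.signatures) - set(self.lineage_map)
        if unmapped:
            raise ValueError(f"cell types without lineage: {sorted(unmapped)}")
        bad = set(self.lineage_map.values()) - set(LINEAGES)
        if bad:
            raise ValueError(f"unknown lineages: {sorted(bad)}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.signatures)


@dataclass
class CellScoreMatrix:
    """Cell type x sample signature scores in [0, 1] with the lineage map."""

    scores: pd.DataFrame  # cell types x samples
    lineage_map: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.scores.values
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("cell scores must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


FEATURE_TYPES = ("mRNA", "mRNA-ratio", "cell", "cell-ratio")


@dataclass
class FeatureTable:
    """Named, typed features x samples with per-feature selection metadata.

    ``metadata`` carries whatever per-feature statistics the cascade has
    computed so far (sd, importance, label_r, ...); it always shares the
    feature index with ``values``.
    """

    values: pd.DataFrame  # features x samples
    feature_types: pd.Series  # feature -> one of FEATURE_TYPES
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature names must be unique")
        self.feature_types = pd.Series(self.feature_types).reindex(self.values.index)
        if self.feature_types.isna().any():
            raise ValueError("every feature needs a feature type")
        bad = set(self.feature_types) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature types: {sorted(bad)}")
        if not np.isfinite(self.values.values).all():
            raise ValueError("feature values must be finite")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.values.index)
        else:
            self.metadata = self.metadata.reindex(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        feats = list(features)
        return FeatureTable(
            self.values.loc[feats],
            self.feature_types.loc[feats],
            self.metadata.loc[feats],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(self.values[ids], self.feature_types, self.metadata)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if list(self.values.columns) != list(other.values.columns):
            raise ValueError("feature tables must share sample columns to concatenate")
        return FeatureTable(
            pd.concat([self.values, other.values]),
            pd.concat([self.feature_types, other.feature_types]),
            pd.concat([self.metadata, other.metadata]),
        )

    @classmethod
    def from_expression(cls, X: ExpressionMatrix) -> "FeatureTable":
        types = pd.Series("mRNA", index=X.values.index)
        return cls(X.values.copy(), types)

    @classmethod
    def from_cell_scores(cls, C: CellScoreMatrix) -> "FeatureTable":
        types = pd.Series("cell", index=C.scores.index)
        return cls(C.scores.copy(), types)


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort or study.

    ``fractions``: cell types x samples, columns summing to 1.
    ``de_genes``: DataFrame with columns gene, direction (+1/-1).
    ``trend_pairs``: list of (cell_a, cell_b, direction) where direction is the
    sign of the planted monotone change of log(score_a/score_b) with stage.
    """

    fractions: pd.DataFrame
    de_genes: pd.DataFrame
    trend_pairs: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=0).values
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("fraction columns must sum to 1")


def stage_labels(annotation: CohortAnnotation, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Ordinal 0/1/2 labels aligned to ``sample_ids`` (default: annotation order)."""
    ids = list(sample_ids) if sample_ids is not None else annotation.sample_ids
    return annotation.table.loc[ids, "stage"].to_numpy(dtype=int)
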
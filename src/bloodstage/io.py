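"""Readers and writers for the plain-text interchange formats.

Expression and feature matrices travel as TSV (rows = genes/features, header =
sample ids), annotations as CSV, signatures and term sets as GMT, reports as
JSON.  The expression scale flag is recorded in a JSON sidecar next to the
matrix so a round-trip preserves it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .containers import (
    CellScoreMatrix,
    CohortAnnotation,
    ExpressionMatrix,
    FeatureTable,
    SignatureSet,
)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    X.values.to_csv(path, sep="\t", index_label="gene")
    meta = {"scale": X.scale, "cohorts": X.cohorts.to_dict()}
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene")
    values.index.name = None
    meta = json.loads(_sidecar(path).read_text())
    cohorts = pd.Series(meta["cohorts"]).reindex(values.columns)
    return ExpressionMatrix(values, cohorts, meta["scale"])


def write_annotation(ann: CohortAnnotation, path: str | Path) -> None:
    ann.table.to_csv(Path(path), index_label="sample")


def read_annotation(path: str | Path) -> CohortAnnotation:
    table = pd.read_csv(Path(path), index_col="sample")
    return CohortAnnotation(table)


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "") -> None:
    """Write gene sets in GMT: name <tab> description <tab> gene1 <tab> ..."""
    lines = []
    for name, genes in sets.items():
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_signatures(S: SignatureSet, gmt_path: str | Path, lineage_path: str | Path) -> None:
    write_gmt(S.signatures, gmt_path, description="marker signature")
    lm = pd.DataFrame(
        {"cell_type": list(S.lineage_map), "lineage": list(S.lineage_map.values())}
    )
    lm.to_csv(Path(lineage_path), sep="\t", index=False)


def read_signatures(gmt_path: str | Path, lineage_path: str | Path) -> SignatureSet:
    sigs = read_gmt(gmt_path)
    lm = pd.read_csv(Path(lineage_path), sep="\t")
    lineage_map = dict(zip(lm["cell_type"], lm["lineage"]))
    return SignatureSet(sigs, lineage_map)


def write_cell_scores(C: CellScoreMatrix, path: str | Path, lineage_path: str | Path | None = None) -> None:
    C.scores.to_csv(Path(path), sep="\t", index_label="cell_type")
    if lineage_path is not None:
        lm = pd.DataFrame(
            {"cell_type": list(C.lineage_map), "lineage": list(C.lineage_map.values())}
        )
        lm.to_csv(Path(lineage_path), sep="\t", index=False)


def read_cell_scores(path: str | Path, lineage_path: str | Path) -> CellScoreMatrix:
    scores = pd.read_csv(Path(path), sep="\t", index_col="cell_type")
    lm = pd.read_csv(Path(lineage_path), sep="\t")
    return CellScoreMatrix(scores, dict(zip(lm["cell_type"], lm["lineage"])))


def write_features(F: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    F.values.to_csv(path, sep="\t", index_label="feature")
    meta = {
        "feature_types": F.feature_types.to_dict(),
        "metadata": json.loads(F.metadata.to_json(orient="index")),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_features(path: str | Path) -> FeatureTable:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="feature")
    values.index.name = None
    meta = json.loads(_sidecar(path).read_text())
    types = pd.Series(meta["feature_types"]).reindex(values.index)
    metadata = pd.DataFrame.from_dict(meta["metadata"], orient="index").reindex(values.index)
    return FeatureTable(values, types, metadata)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
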
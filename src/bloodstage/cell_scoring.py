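"""Signature-based per-sample cell-type scores and lineage composition.

The score of a cell type in a sample is the mean percentile rank of its
marker genes within that sample:

    score = mean over signature genes of (rank_ij - 0.5) / G

with ascending within-sample ranks (ties averaged) over all G genes.  The
score lies in (0, 1), is invariant to any strictly monotone per-sample
transform of expression, and increases monotonically with the cell type's
true abundance in a mixture — a transparent surrogate for signature-
enrichment deconvolution tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    DIAGNOSES,
    LINEAGES,
    CellScoreMatrix,
    CohortAnnotation,
    ExpressionMatrix,
    SignatureSet,
)


def score_signatures(X: ExpressionMatrix, S: SignatureSet) -> CellScoreMatrix:
    """Mean-percentile-rank score for every signature in every sample."""
    gene_index = {g: i for i, g in enumerate(X.values.index)}
    missing = {
        name: genes
        for name, genes in S.signatures.items()
        if not any(g in gene_index for g in genes)
    }
    if missing:
        raise ValueError(f"signatures with no genes present in the matrix: {sorted(missing)}")

    G = X.values.shape[0]
    ranks = rankdata(X.values.to_numpy(), axis=0)  # ascending, ties -> average
    pct = (ranks - 0.5) / G
    rows = []
    for name, genes in S.signatures.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        rows.append(pct[idx, :].mean(axis=0))
    scores = pd.DataFrame(rows, index=list(S.signatures), columns=X.values.columns)
    return CellScoreMatrix(scores, dict(S.lineage_map))


def aggregate_lineages(C: CellScoreMatrix, annotation: CohortAnnotation) -> pd.DataFrame:
    """Per-diagnosis-group lineage composition (rows = lineage, cols = group).

    Each entry is the mean score over the lineage's cell types and the
    group's samples, renormalized across lineages so every group column sums
    to 1 — the stacked-composition view of how the five lineages shift with
    stage.
    """
    unmapped = set(C.cell_types) - set(C.lineage_map)
    if unmapped:
        raise ValueError(f"cell types without lineage mapping: {sorted(unmapped)}")
    lineages = [l for l in LINEAGES if l in set(C.lineage_map[ct] for ct in C.cell_types)]
    groups = [d for d in DIAGNOSES if (annotation.diagnosis == d).any()]
    out = pd.DataFrame(index=lineages, columns=groups, dtype=float)
    diag = annotation.diagnosis
    for g in groups:
        ids = [s for s in C.sample_ids if diag.get(s) == g]
        if not ids:
            continue
        for lin in lineages:
            cts = [ct for ct in C.cell_types if C.lineage_map[ct] == lin]
            out.loc[lin, g] = C.scores.loc[cts, ids].to_numpy().mean()
    out = out / out.sum(axis=0)
    return out
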
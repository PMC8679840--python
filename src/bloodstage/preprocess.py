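"""Library-size normalization and two-cohort harmonization.

Normalization rescales every sample to a fixed million-count total:
``x'_ij = x_ij / sum_j x_ij * 1e6``, making samples comparable regardless of
overall array intensity.  Downstream analyses default to ``log2(x' + 1)``;
two cohorts measured on different platforms are merged on their shared genes,
optionally z-scaling each gene within each cohort first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

TOTAL = 1e6


def normalize_library_size(X: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so its values sum to 10^6 (parts-per-million).

    Idempotent up to the scale flag, and invariant to any per-sample global
    scaling of the raw input.
    """
    if X.scale == "log2":
        raise ValueError("cannot library-size normalize log2 data")
    totals = X.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with non-positive total intensity: {list(zero.index)}")
    values = X.values.div(totals, axis=1) * TOTAL
    return ExpressionMatrix(values, X.cohorts.copy(), scale="normalized")


def log_transform(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); requires normalized input and pseudocount > 0."""
    if X.scale != "normalized":
        raise ValueError(f"log_transform expects normalized input, got scale={X.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = np.log2(X.values + pseudocount)
    return ExpressionMatrix(values, X.cohorts.copy(), scale="log2")


def intersect_and_merge(
    A: ExpressionMatrix,
    B: ExpressionMatrix,
    standardize_per_cohort: bool = False,
) -> ExpressionMatrix:
    """Merge two cohorts on their shared genes.

    With ``standardize_per_cohort`` every gene is centered and scaled to unit
    variance within each cohort before concatenation — the minimal guard
    against platform/batch offsets when pooling cohorts for modeling.
    Zero-variance genes within a cohort are centered only.
    """
    if A.scale != B.scale:
        raise ValueError(f"scale mismatch: {A.scale!r} vs {B.scale!r}")
    shared = A.values.index.intersection(B.values.index)
    if len(shared) == 0:
        raise ValueError("empty gene intersection between cohorts")
    overlap_samples = set(A.sample_ids) & set(B.sample_ids)
    if overlap_samples:
        raise ValueError(f"cohorts share sample ids: {sorted(overlap_samples)[:5]}")
    parts = []
    for M in (A, B):
        vals = M.values.loc[shared]
        if standardize_per_cohort:
            mean = vals.mean(axis=1)
            sd = vals.std(axis=1, ddof=0).replace(0.0, 1.0)
            vals = vals.sub(mean, axis=0).div(sd, axis=0)
        parts.append(vals)
    values = pd.concat(parts, axis=1)
    cohorts = pd.concat([A.cohorts, B.cohorts])
    scale = "log2" if (A.scale == "log2" or standardize_per_cohort) else A.scale
    return ExpressionMatrix(values, cohorts, scale=scale)
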
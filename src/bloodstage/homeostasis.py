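"""Monotone cell-ratio trends across the CON -> MCI -> AD stage order.

A cell-ratio pair (A, B) shows a "gradual" homeostasis shift when the group
medians of log2((score_A + eps)/(score_B + eps)) change strictly
monotonically with stage AND a Jonckheere-Terpstra ordered-alternative test
rejects at level alpha.  The JT statistic is the sum of pairwise
Mann-Whitney counts over all stage-ordered group pairs (ties 1/2); the null
distribution is enumerated exactly for small samples and approximated
normally otherwise.

Pairs are additionally classed by hematopoietic lineage: HSC/Lymphoid/
Myeloid count as hematopoietic, Epithelial/Stroma as non-hematopoietic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import DIAGNOSES, HEMATOPOIETIC, CellScoreMatrix, CohortAnnotation
from .dge import bh_adjust

#: offset on [0,1] cell scores before forming ratios
SCORE_EPSILON = 1e-4

#: total-sample ceiling for the exact permutation null
EXACT_N_MAX = 12


def jonckheere_statistic(groups: list[np.ndarray]) -> float:
    """JT statistic: sum over ordered group pairs i<j of U_ij (ties 1/2)."""
    stat = 0.0
    for i, j in combinations(range(len(groups)), 2):
        a, b = groups[i], groups[j]
        diff = b[:, None] - a[None, :]
        stat += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(stat)


def _jt_exact_p(groups: list[np.ndarray], observed: float, alternative: str) -> float:
    """Exact permutation p by enumerating all group assignments of the pooled values."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = np.arange(n)
    stats = []

    def rec(remaining: np.ndarray, gi: int, chosen: list[np.ndarray]):
        if gi == len(sizes) - 1:
            parts = [pooled[c] for c in chosen] + [pooled[remaining]]
            stats.append(jonckheere_statistic(parts))
            return
        for combo in combinations(range(len(remaining)), sizes[gi]):
            mask = np.zeros(len(remaining), dtype=bool)
            mask[list(combo)] = True
            rec(remaining[~mask], gi + 1, chosen + [remaining[mask]])

    rec(idx, 0, [])
    stats_arr = np.array(stats)
    if alternative == "increasing":
        return float((stats_arr >= observed - 1e-12).mean())
    return float((stats_arr <= observed + 1e-12).mean())


def jonckheere_test(groups: list[np.ndarray], alternative: str = "increasing") -> tuple[float, float]:
    """One-sided Jonckheere-Terpstra test against an ordered alternative.

    Returns (statistic, p).  Exact enumeration when the pooled sample is
    small enough; otherwise the normal approximation with the standard
    no-tie variance and a 0.5 continuity correction.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    stat = jonckheere_statistic(groups)
    n = sum(len(g) for g in groups)
    if n <= EXACT_N_MAX and comb(n, len(groups[0])) < 20000:
        return stat, _jt_exact_p(groups, stat, alternative)
    sizes = np.array([len(g) for g in groups], dtype=float)
    mean = (n * n - (sizes**2).sum()) / 4.0
    var = (n * n * (2 * n + 3) - (sizes**2 * (2 * sizes + 3)).sum()) / 72.0
    if var <= 0:
        return stat, 1.0
    if alternative == "increasing":
        z = (stat - mean - 0.5) / np.sqrt(var)
        return stat, float(norm.sf(z))
    z = (stat - mean + 0.5) / np.sqrt(var)
    return stat, float(norm.cdf(z))


@dataclass
class TrendResult:
    """Trend call for one ordered cell pair (ratio A over B)."""

    pair: tuple[str, str]
    medians: dict[str, float]  # diagnosis -> group median of the log2 ratio
    direction: str  # up | down | none
    statistic: float
    p: float
    q: float
    lineage_class: str

    def to_row(self) -> dict:
        return {
            "cell_a": self.pair[0],
            "cell_b": self.pair[1],
            **{f"median_{g}": self.medians[g] for g in DIAGNOSES},
            "direction": self.direction,
            "statistic": self.statistic,
            "p": self.p,
            "q": self.q,
            "lineage_class": self.lineage_class,
        }


def classify_pair_lineage(pair: tuple[str, str], lineage_map: dict[str, str]) -> str:
    """Hematopoietic side classification of an ordered cell pair."""
    sides = []
    for ct in pair:
        if ct not in lineage_map:
            raise ValueError(f"cell type {ct!r} has no lineage mapping")
        sides.append("hematopoietic" if lineage_map[ct] in HEMATOPOIETIC else "non-hematopoietic")
    return f"{sides[0]}/{sides[1]}"


def _log_ratios(C: CellScoreMatrix, epsilon: float = SCORE_EPSILON) -> dict[tuple[str, str], np.ndarray]:
    log_scores = np.log2(C.scores.to_numpy(dtype=float) + epsilon)
    cts = C.cell_types
    out = {}
    for i, a in enumerate(cts):
        for j, b in enumerate(cts):
            if i != j:
                out[(a, b)] = log_scores[i] - log_scores[j]
    return out


def cell_ratio_trends(
    C: CellScoreMatrix,
    annotation: CohortAnnotation,
    alpha: float = 0.05,
    epsilon: float = SCORE_EPSILON,
) -> list[TrendResult]:
    """Trend calls for every ordered cell pair.

    Direction is "up" iff the CON/MCI/AD medians are strictly increasing and
    the trend p-value is <= alpha; "down" symmetrically; "none" otherwise.
    Since neither direction is pre-specified, the reported p is the
    two-sided ordered-alternative value 2 * min(p_increasing, p_decreasing)
    (capped at 1) — a one-sided p in the data-chosen direction would double
    the false-call rate.  BH q-values are computed across all ordered pairs.
    """
    diag = annotation.diagnosis
    sample_ids = C.sample_ids
    group_pos: dict[str, list[int]] = {}
    for g in DIAGNOSES:
        pos = [k for k, s in enumerate(sample_ids) if diag.get(s) == g]
        if len(pos) < 2:
            raise ValueError(f"diagnosis group {g!r} needs >= 2 samples, got {len(pos)}")
        group_pos[g] = pos

    ratios = _log_ratios(C, epsilon)
    results: list[TrendResult] = []
    for (a, b), vals in ratios.items():
        groups = [vals[group_pos[g]] for g in DIAGNOSES]
        medians = {g: float(np.median(v)) for g, v in zip(DIAGNOSES, groups)}
        up = medians["CON"] < medians["MCI"] < medians["AD"]
        down = medians["CON"] > medians["MCI"] > medians["AD"]
        stat, p_inc = jonckheere_test(groups, "increasing")
        _, p_dec = jonckheere_test(groups, "decreasing")
        p = min(1.0, 2.0 * min(p_inc, p_dec))
        if up and p <= alpha:
            direction = "up"
        elif down and p <= alpha:
            direction = "down"
        else:
            direction = "none"
        results.append(
            TrendResult(
                pair=(a, b),
                medians=medians,
                direction=direction,
                statistic=stat,
                p=p,
                q=np.nan,
                lineage_class=classify_pair_lineage((a, b), C.lineage_map),
            )
        )
    qs = bh_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def trends_frame(results: list[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def top_ratio_union(
    C: CellScoreMatrix,
    annotation: CohortAnnotation,
    k: int = 10,
    epsilon: float = SCORE_EPSILON,
) -> pd.DataFrame:
    """Union of the per-group top-k ratios by |group median|.

    Rows are the union of each diagnosis group's k largest-|median| ordered
    ratios; boolean columns flag per-group membership.  Ties are broken by
    pair name for determinism.
    """
    ratios = _log_ratios(C, epsilon)
    if len(ratios) < k:
        raise ValueError(f"only {len(ratios)} ratios available, need k={k}")
    diag = annotation.diagnosis
    sample_ids = C.sample_ids
    names = [f"{a}/{b}" for a, b in ratios]
    vals = np.vstack(list(ratios.values()))
    member: dict[str, set[str]] = {}
    medians = pd.DataFrame(index=names, columns=list(DIAGNOSES), dtype=float)
    for g in DIAGNOSES:
        pos = [i for i, s in enumerate(sample_ids) if diag.get(s) == g]
        med = np.median(vals[:, pos], axis=1)
        medians[g] = med
        order = sorted(zip(-np.abs(med), names))
        member[g] = {name for _, name in order[:k]}
    union = sorted(set().union(*member.values()))
    out = medians.loc[union].copy()
    for g in DIAGNOSES:
        out[f"top_{g}"] = [name in member[g] for name in union]
    return out
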
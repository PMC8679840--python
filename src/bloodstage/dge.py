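"""Pairwise moderated-t differential expression with FDR control.

For each gene a pooled two-sample t-statistic is moderated by shrinking the
gene-wise variance toward an empirical-Bayes prior estimated from all genes:

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_tilde_g   = dmean_g / (s_tilde_g * sqrt(1/n1 + 1/n2))

with p-values from a t distribution on d0 + d_g degrees of freedom.  The
prior (d0, s0^2) is fitted by moment matching on log s_g^2: under the scaled
inverse-chi-square prior, log(s_g^2 / s0^2) is distributed as a log-F whose
mean and variance involve digamma/trigamma functions; the trigamma equation
is inverted by Newton iteration.  d0 -> 0 recovers the ordinary pooled t;
d0 -> infinity pins every variance at s0^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CohortAnnotation, ExpressionMatrix

#: the three pairwise stage contrasts, each as (numerator, denominator) group
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("AD", "CON"),
    ("MCI", "CON"),
    ("AD", "MCI"),
)


@dataclass
class DGEResult:
    """Per-gene moderated-t results for one pairwise contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # index: gene; columns: delta, s2, df, t, p, q
    d0: float
    s0_sq: float

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "contrast", f"{self.contrast[0]}_vs_{self.contrast[1]}")
        return out


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x.

    trigamma is convex decreasing on (0, inf) with range (0, inf), so the
    solution is unique.  Large y -> small x; y -> 0 -> x -> inf.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from gene-wise variances by log-scale moment matching.

    Returns ``d0 = inf`` when the observed spread of log-variances is no
    larger than the sampling spread (all extra variation absorbed by the
    prior), and falls back to ``d0 = 0`` (ordinary t) when too few positive
    variances are available to fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        warnings.warn(
            "fewer than 10 genes with positive variance; falling back to d0=0 (ordinary t)",
            RuntimeWarning,
            stacklevel=2,
        )
        return (0.0, float(np.median(s2[ok]))) if ok.any() else (0.0, 1.0)
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - special.polygamma(1, df / 2.0)
    if excess <= 1e-10:
        # no evidence of gene-to-gene variance heterogeneity: infinite prior df
        s0_sq = np.exp(e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0))
        return float("inf"), float(s0_sq)
    d0 = 2.0 * trigamma_inverse(float(excess))
    log_s0 = e_z - special.polygamma(0, df / 2.0) + special.polygamma(0, d0 / 2.0) - np.log(d0 / df)
    return float(d0), float(np.exp(log_s0))


def moderated_t_test(
    X: ExpressionMatrix,
    annotation: CohortAnnotation,
    contrast: tuple[str, str],
    d0_override: float | None = None,
) -> DGEResult:
    """Moderated two-sample t for ``contrast = (group_a, group_b)``.

    ``delta`` is mean(group_a) - mean(group_b) per gene (log2 units on log2
    input).  ``d0_override`` forces the prior df (0 = ordinary pooled t),
    bypassing the empirical-Bayes fit.
    """
    group_a, group_b = contrast
    diag = annotation.diagnosis
    ids_a = [s for s in X.sample_ids if diag.get(s) == group_a]
    ids_b = [s for s in X.sample_ids if diag.get(s) == group_b]
    n1, n2 = len(ids_a), len(ids_b)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {group_a}:{n1}, {group_b}:{n2}")

    A = X.values[ids_a].to_numpy(dtype=float)
    B = X.values[ids_b].to_numpy(dtype=float)
    delta = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    else:
        d0, s0_sq = fit_variance_prior(s2, df)

    if np.isinf(d0):
        post_s2 = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        post_s2 = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df

    se = np.sqrt(post_s2 * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(delta)
    pos = se > 0
    t[pos] = delta[pos] / se[pos]
    degen = ~pos & (delta != 0)  # zero posterior variance but nonzero difference
    t[degen] = np.sign(delta[degen]) * np.inf
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(~pos & (delta == 0), 1.0, p)

    table = pd.DataFrame(
        {"delta": delta, "s2": s2, "df": float(df), "t": t, "p": p},
        index=X.values.index,
    )
    table["q"] = bh_adjust(table["p"].to_numpy())
    return DGEResult(contrast=contrast, table=table, d0=d0, s0_sq=s0_sq)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    q_(i) = min_{j >= i} ( m * p_(j) / j ) over the ascending order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_contrasts(
    X: ExpressionMatrix,
    annotation: CohortAnnotation,
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
) -> dict[tuple[str, str], DGEResult]:
    return {c: moderated_t_test(X, annotation, c) for c in contrasts}


def select_degs(
    results: dict[tuple[str, str], DGEResult],
    q_threshold: float = 0.05,
    effect_threshold: float = 0.0,
) -> tuple[dict[tuple[str, str], list[str]], list[str]]:
    """Genes with q <= q_threshold and |delta| >= effect_threshold, per contrast + union."""
    if q_threshold < 0 or effect_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    per_contrast: dict[tuple[str, str], list[str]] = {}
    union: set[str] = set()
    for contrast, res in results.items():
        mask = (res.table["q"] <= q_threshold) & (res.table["delta"].abs() >= effect_threshold)
        genes = list(res.table.index[mask])
        per_contrast[contrast] = genes
        union.update(genes)
    return per_contrast, sorted(union)
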
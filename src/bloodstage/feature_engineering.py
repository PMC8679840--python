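"""Ratio-feature construction and the thresholded selection cascade.

The cascade mirrors a staged biomarker-screening recipe:

1. standard-deviation filter (absolute threshold, or keep a stated fraction),
2. greedy collinearity filter so no surviving pair has |Pearson r| above a
   bound (higher-SD member kept),
3. recursive feature elimination with a linear one-vs-rest classifier,
   removing a fixed fraction of the least important features per iteration
   (importance = mean absolute standardized coefficient across classes),
   with cross-validated accuracy recorded along the way,
4. cumulative-importance cut: the smallest descending-importance prefix of
   the ranked pool whose normalized weights reach a target mass.

Ratio features pair two parent features on the log scale (a difference), a
"new dimension" capturing relative rather than absolute abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import FeatureTable


@dataclass
class CascadeConfig:
    """Thresholds and knobs of the selection cascade.

    Setting ``sd_threshold``/``sd_retain_quantile`` both to None skips the SD
    stage; ``r_max=None`` skips the collinearity stage; ``fraction_per_iter=
    None`` skips elimination (and the cut); ``cumulative_mass=None`` skips
    the cut.
    """

    sd_threshold: float | None = None
    sd_retain_quantile: float | None = 0.75
    r_max: float | None = 0.9
    fraction_per_iter: float | None = 0.01
    cumulative_mass: float | None = 0.75
    n_ratio_candidates: int = 100
    cv_folds: int = 5
    rfe_floor_fraction: float = 0.2
    seed: int = 0


@dataclass
class SelectionReport:
    """Stage-by-stage bookkeeping of the cascade."""

    stages: list[dict] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)
    importances: dict[str, float] = field(default_factory=dict)
    rfe_history: list[dict] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int, **params) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name} increased the feature count ({n_in} -> {n_out})")
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out, "params": params})

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "final_features": self.final_features,
            "importances": self.importances,
            "rfe_history": self.rfe_history,
        }


def build_ratio_features(
    F: FeatureTable,
    candidates: Sequence[str],
    epsilon: float = 1e-8,
    log_scale: bool = True,
) -> FeatureTable:
    """One ratio feature per unordered candidate pair, lexicographic orientation.

    On log2-scale input the ratio is the difference a - b (no epsilon); on a
    raw scale it is log2((a + eps)/(b + eps)).  The feature "a/b" always has
    a < b by name, making storage canonical: the reverse orientation is its
    negation.
    """
    cands = sorted(set(candidates))
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate features to build ratios")
    missing = set(cands) - set(F.feature_names)
    if missing:
        raise ValueError(f"candidates not in feature table: {sorted(missing)[:5]}")
    if not log_scale and epsilon <= 0:
        raise ValueError("epsilon must be > 0 for non-log input")

    vals = F.values.loc[cands].to_numpy(dtype=float)
    if not log_scale:
        vals = np.log2(vals + epsilon)
    types = F.feature_types.loc[cands]

    names, rows, rtypes = [], [], []
    for i, a in enumerate(cands):
        for j in range(i + 1, len(cands)):
            b = cands[j]
            names.append(f"{a}/{b}")
            rows.append(vals[i] - vals[j])
            rtypes.append("cell-ratio" if (types[a] == "cell" and types[b] == "cell") else "mRNA-ratio")
    values = pd.DataFrame(rows, index=names, columns=F.values.columns)
    return FeatureTable(values, pd.Series(rtypes, index=names))


def _sd(F: FeatureTable) -> pd.Series:
    return F.values.std(axis=1, ddof=1)


def _sd_order(sd: pd.Series) -> list[str]:
    """Feature names by descending SD, ties broken by ascending name."""
    frame = pd.DataFrame({"sd": sd, "name": sd.index})
    frame = frame.sort_values(["sd", "name"], ascending=[False, True], kind="mergesort")
    return list(frame.index)


def sd_filter(
    F: FeatureTable,
    threshold: float | None = None,
    retain_quantile: float | None = None,
) -> FeatureTable:
    """Drop low-variability features.

    Exactly one of ``threshold`` (drop SD < threshold) or ``retain_quantile``
    (keep the stated top fraction by SD, ties keeping the higher SD then
    name order) must be given.
    """
    if (threshold is None) == (retain_quantile is None):
        raise ValueError("give exactly one of threshold / retain_quantile")
    sd = _sd(F)
    if retain_quantile is not None:
        if not (0 < retain_quantile <= 1):
            raise ValueError("retain_quantile must lie in (0, 1]")
        k = max(1, int(np.floor(retain_quantile * len(sd) + 1e-9)))
        keep = _sd_order(sd)[:k]
        keep = [f for f in F.feature_names if f in set(keep)]  # preserve input order
    else:
        keep = list(sd.index[sd >= threshold])
    out = F.subset(keep)
    out.metadata["sd"] = sd.loc[keep]
    return out


def collinearity_filter(F: FeatureTable, r_max: float = 0.9) -> FeatureTable:
    """Greedy descending-SD pruning so no surviving pair has |r| > r_max.

    Features are visited in descending-SD order (ties by name); a feature is
    kept iff its maximum absolute Pearson correlation against the already
    kept set is <= r_max.  Zero-SD features are rejected — run sd_filter
    first.
    """
    if r_max is None or not (0 < r_max <= 1):
        raise ValueError("r_max must lie in (0, 1]")
    sd = _sd(F)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])[:5]
        raise ValueError(f"zero-SD features present (run sd_filter first): {bad}")
    order = _sd_order(sd)
    X = F.values.loc[order].to_numpy(dtype=float)
    n = X.shape[1]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    kept_idx: list[int] = []
    for i in range(len(order)):
        if not kept_idx:
            kept_idx.append(i)
            continue
        r = np.abs(Z[kept_idx] @ Z[i] / n)
        if r.max() <= r_max + 1e-12:
            kept_idx.append(i)
    keep_set = {order[i] for i in kept_idx}
    keep = [f for f in F.feature_names if f in keep_set]
    out = F.subset(keep)
    out.metadata["sd"] = sd.loc[keep]
    return out


def _standardize(values: pd.DataFrame) -> pd.DataFrame:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])[:5]
        raise ValueError(f"zero-variance features cannot be standardized: {bad}")
    return values.sub(mean, axis=0).div(sd, axis=0)


def _fit_importance(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Mean |coefficient| across one-vs-rest linear classifiers (deterministic)."""
    clf = LinearSVC(dual=False, random_state=seed, max_iter=5000)
    clf.fit(X, y)
    coef = np.atleast_2d(clf.coef_)
    return np.abs(coef).mean(axis=0)


def rank_by_importance(F: FeatureTable, labels: np.ndarray, seed: int = 0) -> pd.Series:
    """Single-fit importance of every feature (standardized), descending order."""
    Z = _standardize(F.values)
    imp = _fit_importance(Z.to_numpy().T, np.asarray(labels), seed)
    s = pd.Series(imp, index=F.feature_names)
    return s.sort_values(ascending=False, kind="mergesort")


@dataclass
class RFEResult:
    """Outcome of recursive elimination.

    ``ranking`` lists every input feature from most to least important
    (survivors by final-fit importance, then eliminated features in reverse
    elimination order).  ``importances`` carries the survivors' final-fit
    importances; ``history`` one row per iteration.
    """

    ranking: list[str]
    survivors: list[str]
    importances: pd.Series
    history: pd.DataFrame


def recursive_elimination(
    F: FeatureTable,
    labels: np.ndarray,
    fraction_per_iter: float = 0.01,
    cv_folds: int = 5,
    seed: int = 0,
    n_features_floor: int = 1,
) -> RFEResult:
    """Iteratively drop the least important features.

    Each iteration fits a linear one-vs-rest classifier on the standardized
    surviving features, scores importance as the mean absolute coefficient
    across classes, and removes ``max(1, ceil(fraction_per_iter * current))``
    lowest-importance features (ties broken by name), stopping at
    ``n_features_floor``.  ``cv_folds >= 2`` records stratified
    cross-validated accuracy per iteration; the result is deterministic
    given data, labels and seed.
    """
    if not (0 < fraction_per_iter < 1):
        raise ValueError("fraction_per_iter must lie in (0, 1)")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if len(F.feature_names) < 2:
        raise ValueError("need at least 2 features")

    Z = _standardize(F.values)
    current = sorted(F.feature_names)
    eliminated: list[str] = []
    history_rows = []
    final_imp: pd.Series | None = None

    splitter = (
        StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        if cv_folds and cv_folds >= 2
        else None
    )

    while True:
        X = Z.loc[current].to_numpy().T
        imp = pd.Series(_fit_importance(X, labels, seed), index=current)
        cv_acc = np.nan
        if splitter is not None:
            accs = []
            for tr, te in splitter.split(X, labels):
                clf = LinearSVC(dual=False, random_state=seed, max_iter=5000)
                clf.fit(X[tr], labels[tr])
                accs.append(float((clf.predict(X[te]) == labels[te]).mean()))
            cv_acc = float(np.mean(accs))
        history_rows.append({"n_features": len(current), "cv_accuracy": cv_acc})
        if len(current) <= n_features_floor:
            final_imp = imp
            break
        n_remove = max(1, int(np.ceil(fraction_per_iter * len(current))))
        n_remove = min(n_remove, len(current) - n_features_floor)
        order = pd.DataFrame({"imp": imp, "name": imp.index}).sort_values(
            ["imp", "name"], ascending=[True, True], kind="mergesort"
        )
        victims = list(order.index[:n_remove])
        # within a batch, record weakest first so reverse order ranks them correctly
        eliminated.extend(victims)
        current = [f for f in current if f not in set(victims)]
        final_imp = imp

    surv_order = pd.DataFrame({"imp": final_imp.loc[current], "name": current}).sort_values(
        ["imp", "name"], ascending=[False, True], kind="mergesort"
    )
    survivors = list(surv_order.index)
    ranking = survivors + eliminated[::-1]
    return RFEResult(
        ranking=ranking,
        survivors=survivors,
        importances=final_imp.loc[survivors],
        history=pd.DataFrame(history_rows),
    )


def cumulative_importance_cut(importances: pd.Series, mass: float = 0.75) -> tuple[list[str], pd.Series]:
    """Smallest descending-importance prefix whose normalized weights reach ``mass``.

    Returns the kept feature names and the normalized importances of the
    whole ranked pool (summing to 1).  Ties are broken by name order.
    """
    if not (0 < mass <= 1):
        raise ValueError("mass must lie in (0, 1]")
    imp = pd.Series(importances, dtype=float)
    if (imp < 0).any():
        raise ValueError("importances must be >= 0")
    total = imp.sum()
    if total == 0:
        raise ValueError("all-zero importances")
    norm = imp / total
    order = pd.DataFrame({"imp": norm, "name": norm.index}).sort_values(
        ["imp", "name"], ascending=[False, True], kind="mergesort"
    )
    cum = order["imp"].cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), mass - 1e-12) + 1)
    n_keep = min(n_keep, len(order))
    return list(order.index[:n_keep]), norm


def label_correlation(F: FeatureTable, labels: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of each feature with the ordinal stage code.

    Zero-variance features get r = 0 with ``zero_variance = True``.
    """
    y = np.asarray(labels, dtype=float)
    if len(y) != len(F.sample_ids):
        raise ValueError("labels length must match sample count")
    X = F.values.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    flat = sx == 0
    denom = np.where(flat, 1.0, sx * sy)
    r = (xc @ yc) / denom
    r[flat] = 0.0
    return pd.DataFrame({"r": r, "zero_variance": flat}, index=F.feature_names)


def run_cascade(
    F: FeatureTable,
    labels: np.ndarray,
    config: CascadeConfig | None = None,
) -> tuple[FeatureTable, SelectionReport]:
    """SD filter -> collinearity filter -> recursive elimination -> mass cut."""
    config = config or CascadeConfig()
    report = SelectionReport()
    current = F

    if config.sd_threshold is not None or config.sd_retain_quantile is not None:
        n_in = len(current.feature_names)
        current = sd_filter(current, config.sd_threshold, config.sd_retain_quantile)
        report.record(
            "sd_filter", n_in, len(current.feature_names),
            threshold=config.sd_threshold, retain_quantile=config.sd_retain_quantile,
        )

    if config.r_max is not None:
        n_in = len(current.feature_names)
        current = collinearity_filter(current, config.r_max)
        report.record("collinearity_filter", n_in, len(current.feature_names), r_max=config.r_max)
        _assert_no_collinear_pair(current, config.r_max)

    importances: pd.Series | None = None
    if config.fraction_per_iter is not None:
        n_in = len(current.feature_names)
        floor = max(10, int(np.ceil(config.rfe_floor_fraction * n_in)))
        floor = min(floor, n_in)
        rfe = recursive_elimination(
            current, labels,
            fraction_per_iter=config.fraction_per_iter,
            cv_folds=config.cv_folds,
            seed=config.seed,
            n_features_floor=floor,
        )
        current = current.subset(rfe.survivors)
        importances = rfe.importances
        current.metadata["importance"] = importances
        report.record(
            "recursive_elimination", n_in, len(current.feature_names),
            fraction_per_iter=config.fraction_per_iter, cv_folds=config.cv_folds, floor=floor,
        )
        report.rfe_history = rfe.history.to_dict(orient="records")

        if config.cumulative_mass is not None:
            n_in = len(current.feature_names)
            kept, norm = cumulative_importance_cut(importances, config.cumulative_mass)
            kept_in_order = [f for f in current.feature_names if f in set(kept)]
            current = current.subset(kept_in_order)
            current.metadata["importance"] = norm.loc[kept_in_order]
            report.record("cumulative_importance_cut", n_in, len(current.feature_names), mass=config.cumulative_mass)
            report.importances = {k: float(v) for k, v in norm.items()}

    corr = label_correlation(current, labels)
    current.metadata["label_r"] = corr["r"]
    report.final_features = list(current.feature_names)
    if not report.importances and importances is not None:
        report.importances = {k: float(v / importances.sum()) for k, v in importances.items()}
    return current, report


def _assert_no_collinear_pair(F: FeatureTable, r_max: float) -> None:
    """Hard invariant: no surviving pair may exceed the correlation bound."""
    X = F.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        return
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 0.0)
    worst = np.abs(corr).max()
    if worst > r_max + 1e-9:
        raise AssertionError(f"collinearity invariant violated: max |r| = {worst:.4f} > {r_max}")
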
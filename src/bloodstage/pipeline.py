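"""End-to-end orchestration of the two modeling workflows.

Workflow "model1" trains on mRNA features alone: simulate (optional) ->
normalize -> log2 -> merge cohorts -> differential expression -> SD +
collinearity + elimination cascade -> four-algorithm training and
cross-cohort evaluation.

Workflow "model2" additionally scores cell-type signatures and builds
mRNA-ratio and cell-ratio features before the cascade (no SD stage: ratio
and score features live on deliberately different scales), then adds the
cell-ratio homeostasis trend analysis and, when term sets are supplied,
hypergeometric enrichment of the optimal mRNA features.

Every run writes its artifacts plus a manifest recording the configuration
hash and the hash of every artifact; a rerun with the same configuration
reproduces the manifest hash bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cell_scoring import aggregate_lineages, score_signatures
from .classification import ALGORITHMS, run_protocols
from .containers import CohortAnnotation, FeatureTable, stage_labels
from .dge import run_contrasts, select_degs
from .enrichment import enrichment_frame, hypergeometric_enrichment
from .feature_engineering import (
    CascadeConfig,
    build_ratio_features,
    rank_by_importance,
    run_cascade,
)
from .homeostasis import cell_ratio_trends, top_ratio_union, trends_frame
from .preprocess import intersect_and_merge, log_transform, normalize_library_size
from .synthetic_data import SimulationConfig, generate_study


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run."""

    workflow: str = "model2"  # model1 | model2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    q_threshold: float = 0.05
    effect_threshold: float = 0.0
    algorithms: tuple[str, ...] = ALGORITHMS
    trend_alpha: float = 0.05
    top_k_ratios: int = 10
    test_size: float = 0.3
    term_sets_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in ("model1", "model2"):
            raise ValueError(f"workflow must be model1 or model2, got {self.workflow!r}")
        # one master seed drives simulation, cascade CV and model fits
        self.simulation.seed = self.seed
        self.cascade.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cas = d.pop("cascade", {})
        algos = d.pop("algorithms", list(ALGORITHMS))
        return cls(
            simulation=SimulationConfig(**sim) if isinstance(sim, dict) else sim,
            cascade=CascadeConfig(**cas) if isinstance(cas, dict) else cas,
            algorithms=tuple(algos),
            **d,
        )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured workflow; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(writer, *args) -> None:
        path = args[-1]
        writer(*args)
        artifacts.append(Path(path))

    # ---- simulate ---------------------------------------------------------
    signatures, cohorts, truth = generate_study(config.simulation)
    io.write_signatures(signatures, out / "signatures.gmt", out / "lineages.tsv")
    artifacts += [out / "signatures.gmt", out / "lineages.tsv"]
    annotations = []
    normalized = {}
    for cohort_id, (X, ann) in cohorts.items():
        save(io.write_expression, X, out / f"expression_{cohort_id}.tsv")
        normalized[cohort_id] = log_transform(normalize_library_size(X))
        annotations.append(ann)
    annotation = annotations[0]
    for ann in annotations[1:]:
        annotation = annotation.concat(ann)
    save(io.write_annotation, annotation, out / "annotation.csv")
    io.write_json(
        {
            "de_genes": truth.de_genes.to_dict(orient="list"),
            "trend_pairs": truth.trend_pairs,
        },
        out / "ground_truth.json",
    )
    artifacts.append(out / "ground_truth.json")

    # ---- preprocess -------------------------------------------------------
    cohort_ids = list(cohorts)
    merged_log = intersect_and_merge(normalized[cohort_ids[0]], normalized[cohort_ids[1]], standardize_per_cohort=False)
    merged_std = intersect_and_merge(normalized[cohort_ids[0]], normalized[cohort_ids[1]], standardize_per_cohort=True)
    save(io.write_expression, merged_log, out / "merged_log2.tsv")

    # ---- differential expression -----------------------------------------
    results = run_contrasts(merged_log, annotation)
    dge_frames = [res.to_frame() for res in results.values()]
    dge_all = pd.concat(dge_frames)
    dge_all.to_csv(out / "dge.tsv", sep="\t", index_label="gene")
    artifacts.append(out / "dge.tsv")
    per_contrast, deg_union = select_degs(results, config.q_threshold, config.effect_threshold)
    io.write_json(
        {
            "per_contrast": {f"{a}_vs_{b}": genes for (a, b), genes in per_contrast.items()},
            "union": deg_union,
        },
        out / "degs.json",
    )
    artifacts.append(out / "degs.json")

    labels = stage_labels(annotation, merged_std.sample_ids)

    # ---- feature assembly -------------------------------------------------
    mrna_pool = deg_union if deg_union else list(merged_std.values.index)
    mrna = FeatureTable(
        merged_std.values.loc[mrna_pool],
        pd.Series("mRNA", index=mrna_pool),
    )
    features = mrna
    cell_scores = None
    cascade_cfg = config.cascade

    if config.workflow == "model2":
        cell_scores = score_signatures(merged_log, signatures)
        save(io.write_cell_scores, cell_scores, out / "cell_scores.tsv")
        composition = aggregate_lineages(cell_scores, annotation)
        composition.to_csv(out / "lineage_composition.tsv", sep="\t", index_label="lineage")
        artifacts.append(out / "lineage_composition.tsv")

        mrna_log = FeatureTable(
            merged_log.values.loc[mrna_pool], pd.Series("mRNA", index=mrna_pool)
        )
        n_cand = min(cascade_cfg.n_ratio_candidates, len(mrna_pool))
        candidates = list(rank_by_importance(mrna, labels, seed=config.seed).index[:n_cand])
        mrna_ratios = build_ratio_features(mrna_log, candidates, log_scale=True)
        cells = FeatureTable.from_cell_scores(cell_scores)
        cell_log = FeatureTable(
            np.log2(cells.values + 1e-4), cells.feature_types
        )
        cell_ratios = build_ratio_features(cell_log, cells.feature_names, log_scale=True)
        features = mrna.concat(mrna_ratios).concat(cells).concat(cell_ratios)
        # mixed feature classes live on different scales: no SD stage in model2
        cascade_cfg = dataclasses.replace(cascade_cfg, sd_threshold=None, sd_retain_quantile=None)

    # ---- selection cascade ------------------------------------------------
    optimal, report = run_cascade(features, labels, cascade_cfg)
    save(io.write_features, optimal, out / "features_optimal.tsv")
    io.write_json(report.to_dict(), out / "selection_report.json")
    artifacts.append(out / "selection_report.json")

    # ---- modeling ---------------------------------------------------------
    protocols = run_protocols(
        optimal, annotation, config.algorithms, seed=config.seed, test_size=config.test_size
    )
    model_reports = {
        proto: {algo: rep.to_dict() for algo, rep in reps.items()}
        for proto, reps in protocols.items()
    }
    io.write_json(model_reports, out / "model_reports.json")
    artifacts.append(out / "model_reports.json")
    for proto, reps in protocols.items():
        for algo, rep in reps.items():
            for cohort, conf in rep.confusion.items():
                path = out / f"confusion_{proto}_{algo}_{cohort}.csv"
                conf.to_csv(path)
                artifacts.append(path)

    # ---- homeostasis trends (model2) --------------------------------------
    trend_summary = None
    if config.workflow == "model2" and cell_scores is not None:
        trends = cell_ratio_trends(cell_scores, annotation, alpha=config.trend_alpha)
        tf = trends_frame(trends)
        tf.to_csv(out / "trends.tsv", sep="\t", index=False)
        artifacts.append(out / "trends.tsv")
        union = top_ratio_union(cell_scores, annotation, k=config.top_k_ratios)
        union.to_csv(out / "top_ratio_union.tsv", sep="\t", index_label="ratio")
        artifacts.append(out / "top_ratio_union.tsv")
        trend_summary = {
            "n_pairs_tested": len(trends),
            "n_up": int(sum(t.direction == "up" for t in trends)),
            "n_down": int(sum(t.direction == "down" for t in trends)),
        }

    # ---- enrichment (optional, user-supplied term sets) --------------------
    if config.term_sets_path:
        term_sets = io.read_gmt(config.term_sets_path)
        universe = list(merged_log.values.index)
        query = sorted(
            {f for f in optimal.feature_names if optimal.feature_types[f] == "mRNA"}
            | {p for f in optimal.feature_names if optimal.feature_types[f] == "mRNA-ratio" for p in f.split("/")}
        )
        enr = hypergeometric_enrichment(query, term_sets, universe)
        enrichment_frame(enr).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        artifacts.append(out / "enrichment.tsv")

    # ---- manifest ----------------------------------------------------------
    sidecars = [io._sidecar(p) for p in artifacts if io._sidecar(p).exists()]
    manifest = {
        "workflow": config.workflow,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stage_counts": report.stages,
        "artifacts": {
            str(p.relative_to(out)): _file_hash(p) for p in sorted(set(artifacts + sidecars))
        },
    }
    if trend_summary:
        manifest["trends"] = trend_summary
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    io.write_json(manifest, out / "manifest.json")
    return manifest
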
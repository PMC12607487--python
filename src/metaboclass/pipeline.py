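"""End-to-end discrimination pipeline and run reporting.

Stage order: cutoff filter -> HCA (z-scored) -> PCA -> correlation-based
feature selection -> PLS-DA (R², Q², permutation test, VIP). Every stage
writes a CSV/JSON artifact and the run emits a machine-readable summary in
which every stage parameter is recorded — no silent defaults.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import AbundanceTable, SampleClasses, align, read_abundance_table, read_classes
from .preprocessing import CutoffConfig, cutoff_filter, zscore
from .clustering_ordination import hca, pca
from .feature_selection import correlation_clusters, pearson_matrix, select_representatives
from .plsda import fit, permutation_test, q_squared, r_squared, scores_for_plot, vip
from .synthetic_data import GeneratorConfig, generate_abundance

logger = logging.getLogger("metaboclass")


@dataclass
class RunConfig:
    """All knobs of one pipeline run. Either CSV inputs or a simulation
    preset; every field lands in the emitted summary."""

    table_path: str | None = None
    classes_path: str | None = None
    simulate: str | None = None  # "paper-like" preset of the generator
    threshold: float = 10.0
    rule: str = "any_sample"
    corr_threshold: float = 0.7
    n_select: int = 4
    n_components: int = 2
    folds: int = 5
    permutations: int = 1000
    seed: int = 0
    out_dir: str = "metaboclass_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**payload)


def _load_inputs(config: RunConfig) -> tuple[AbundanceTable, SampleClasses]:
    if config.simulate is not None:
        if config.simulate != "paper-like":
            raise ValueError(f"unknown simulation preset {config.simulate!r}")
        return generate_abundance(GeneratorConfig(seed=config.seed))
    if config.table_path is None or config.classes_path is None:
        raise ValueError("either simulate preset or table_path + classes_path required")
    for path in (config.table_path, config.classes_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    return read_abundance_table(config.table_path), read_classes(config.classes_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full stage sequence and write per-stage artifacts.

    Returns the summary dict (also written as ``summary.json``).
    Deterministic for a fixed config: rerunning writes byte-identical
    artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        "q2": int(rng.integers(2**31 - 1)),
        "permutation": int(rng.integers(2**31 - 1)),
    }

    logger.info("stage load: start")
    table, classes = _load_inputs(config)
    table, y = align(table, classes)
    logger.info("stage load: %d features x %d samples", table.n_features, table.n_samples)

    logger.info("stage filter: threshold=%s rule=%s", config.threshold, config.rule)
    filtered = cutoff_filter(table, CutoffConfig(config.threshold, config.rule))
    filtered.to_csv(out / "filtered.csv")

    z = zscore(filtered)
    sample_tree, feature_tree = hca(z)
    sample_tree.to_frame().to_csv(out / "hca_sample_merges.csv", index=False)
    feature_tree.to_frame().to_csv(out / "hca_feature_merges.csv", index=False)

    X = filtered.values.T  # samples x features
    pca_result = pca(X, n_components=2)
    pd.DataFrame(
        {
            "sample": filtered.sample_ids,
            "PC1": pca_result.scores[:, 0],
            "PC2": pca_result.scores[:, 1],
            "class": [classes.name_of(v) for v in y],
        }
    ).to_csv(out / "pca_scores.csv", index=False)

    logger.info("stage select: |r|>=%s, n_select=%d", config.corr_threshold, config.n_select)
    clusters = correlation_clusters(pearson_matrix(filtered), config.corr_threshold)
    n_select = min(config.n_select, clusters.n_clusters)
    selected = select_representatives(clusters, filtered, n_select=n_select)
    selected_table = filtered.subset_features(selected)
    selected_table.to_csv(out / "selected.csv")
    pca_selected = pca(selected_table.values.T, n_components=min(2, len(selected)))

    logger.info("stage plsda: %d components, k=%d, seed=%d", config.n_components, config.folds, seeds["q2"])
    Xf = pd.DataFrame(X, columns=filtered.feature_ids)
    model = fit(Xf, y, n_components=config.n_components)
    stats = r_squared(model, X, y)
    cv = q_squared(X, y, k=config.folds, n_components=config.n_components, seed=seeds["q2"])
    scores_for_plot(model, classes, filtered.sample_ids).to_csv(out / "plsda_scores.csv", index=False)

    Xs = selected_table.values.T
    model_sel = fit(Xs, y, n_components=min(config.n_components, len(selected)))
    stats_sel = r_squared(model_sel, Xs, y)
    cv_sel = q_squared(Xs, y, k=config.folds, n_components=model_sel.n_components, seed=seeds["q2"])

    logger.info("stage permutation: %d runs, seed=%d", config.permutations, seeds["permutation"])
    perm = permutation_test(
        X, y, n_runs=config.permutations, k=config.folds,
        n_components=config.n_components, seed=seeds["permutation"],
    )
    pd.DataFrame({"permuted_q2": perm.permuted_q2}).to_csv(out / "permutation_q2.csv", index=False)

    importance = vip(model)
    importance.feature_ids = filtered.feature_ids
    vip_frame = importance.to_frame()
    vip_frame["above_threshold"] = importance.above_threshold()
    vip_frame.to_csv(out / "vip.csv", index=False)

    summary = {
        "package_version": __version__,
        "settings": asdict(config),
        "derived_seeds": seeds,
        "n_samples": table.n_samples,
        "feature_counts": {
            "initial": table.n_features,
            "after_cutoff": filtered.n_features,
            "after_selection": len(selected),
        },
        "hca_sample_order": sample_tree.ordered_items(),
        "pca": {
            "explained_variance_ratio": [round(v, 6) for v in pca_result.explained_variance_ratio],
            "cumulative_variance": round(pca_result.cumulative_variance, 6),
            "cumulative_variance_selected": round(pca_selected.cumulative_variance, 6),
        },
        "correlation_clusters": {"n_clusters": clusters.n_clusters, "threshold": config.corr_threshold},
        "selected_features": selected,
        "plsda": {
            "r2": round(stats.r2, 6),
            "q2": round(cv.q2, 6),
            "r2_selected": round(stats_sel.r2, 6),
            "q2_selected": round(cv_sel.q2, 6),
            "permutation_p_value": perm.p_value,
            "permutation_runs": perm.n_runs,
            "observed_q2": round(perm.observed_q2, 6),
        },
        "vip": {
            "threshold": importance.threshold,
            "n_above_threshold": int(importance.above_threshold().sum()),
            "features_above_threshold": sorted(
                f for f, ok in zip(filtered.feature_ids, importance.above_threshold()) if ok
            ),
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.txt").write_text(render_report(summary))
    logger.info("run complete: artifacts in %s", out)
    return summary


def render_report(summary: dict) -> str:
    """Human-readable text report over a pipeline summary."""
    lines = [
        f"metaboclass {summary['package_version']} run report",
        "=" * 44,
        "",
        "Settings:",
    ]
    for key, value in sorted(summary["settings"].items()):
        lines.append(f"  {key} = {value}")
    for key, value in sorted(summary["derived_seeds"].items()):
        lines.append(f"  seed[{key}] = {value}")
    counts = summary["feature_counts"]
    lines += [
        "",
        f"Feature reduction: {counts['initial']} -> {counts['after_cutoff']} "
        f"(cutoff) -> {counts['after_selection']} (correlation selection)",
        f"PCA cumulative variance (2 PCs): {summary['pca']['cumulative_variance']:.1%}"
        f" | selected features: {summary['pca']['cumulative_variance_selected']:.1%}",
        "",
        "PLS-DA:",
        f"  R2 = {summary['plsda']['r2']:.4f}   Q2 = {summary['plsda']['q2']:.4f}",
        f"  R2 (selected) = {summary['plsda']['r2_selected']:.4f}   "
        f"Q2 (selected) = {summary['plsda']['q2_selected']:.4f}",
        f"  permutation p = {summary['plsda']['permutation_p_value']} "
        f"({summary['plsda']['permutation_runs']} runs)",
        "",
        f"VIP >= {summary['vip']['threshold']}:",
    ]
    flagged = summary["vip"]["features_above_threshold"]
    if flagged:
        lines += [f"  {name}" for name in flagged]
    else:
        lines.append("  no features above threshold")
    lines.append("")
    return "\n".join(lines)
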
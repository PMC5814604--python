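"""End-to-end pipeline: cohort -> filter -> features -> clusters -> tables.

Stages run in the order filter -> impute/features -> clustering (elbow or
fixed k) -> smoothed curves & naming -> bouts -> group comparison, and every
artifact lands in one output directory together with a machine-readable run
manifest. Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_cohort import CohortDataset, filter_valid_participants, read_cohort
from .features import (
    NORMALIZED_MVPA,
    RAW,
    normalized_feature_matrix,
    raw_feature_matrix,
    write_feature_matrix,
)
from .bouts import cohort_bout_summaries
from .clustering import elbow_scan, lloyd_kmeans, name_clusters
from .smoothing import curves_frame, plot_curves, smooth_cluster_curves
from .compare import ComparisonSpec, cluster_summary_table, compare_groups
from .synthetic_data import default_trial_config, generate_cohort

log = logging.getLogger("acticlust")

ARTIFACTS = (
    "exclusion_report.csv",
    "features.csv",
    "elbow_scan.json",
    "labels.csv",
    "curves.csv",
    "bout_summary.csv",
    "comparison.csv",
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Exactly one of ``input`` (a long CSV path) or ``simulate`` must be set.
    ``k`` fixes the number of clusters; when None the elbow scan up to
    ``k_max`` chooses it.
    """

    out_dir: str
    input: str | None = None
    simulate: bool = False
    feature_kind: str = RAW            # "raw" | "normalized_mvpa"
    k: int | None = None
    k_max: int = 5
    restarts: int = 25
    seed: int | None = None
    span: float = 0.1
    alpha: float = 0.05
    elbow_threshold: float = 0.10
    degenerate_policy: str = "exclude"
    plot: bool = False

    def __post_init__(self) -> None:
        if bool(self.input) == bool(self.simulate):
            raise ValueError("exactly one of input / simulate must be given")
        if self.feature_kind in ("normalized", "normalized_mvpa"):
            self.feature_kind = NORMALIZED_MVPA
        elif self.feature_kind != RAW:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k is None and self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            log.info("stage %s", name)
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def default_comparison_specs(cohort: CohortDataset) -> list[ComparisonSpec]:
    """Compare every covariate column by its dtype (ids/labels excluded)."""
    specs = []
    for col in cohort.covariates.columns:
        if col in ("archetype",):
            continue
        kind = (
            "continuous"
            if pd.api.types.is_numeric_dtype(cohort.covariates[col])
            else "categorical"
        )
        specs.append(ComparisonSpec(col, kind))
    return specs


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        cohort, planted = _stage("simulate")(generate_cohort)(
            default_trial_config(), seed=config.seed
        )
        planted.to_csv(out / "planted_labels.csv")
    else:
        cohort = _stage("read")(read_cohort)(config.input)

    cohort, report = _stage("filter")(filter_valid_participants)(cohort)
    report.to_csv(out / "exclusion_report.csv", index=False)

    if config.feature_kind == RAW:
        features = _stage("features")(raw_feature_matrix)(cohort)
        degenerate: list[str] = []
    else:
        features, degenerate = _stage("features")(normalized_feature_matrix)(
            cohort, degenerate_policy=config.degenerate_policy
        )
    write_feature_matrix(
        features, out / "features.csv", out / "features.json",
        degenerate_ids=degenerate,
    )

    if config.k is None:
        scan = _stage("elbow")(elbow_scan)(
            features, config.k_max, restarts=config.restarts,
            seed=config.seed, threshold=config.elbow_threshold,
        )
        chosen_k = scan.chosen_k
        result = scan.results[chosen_k - 1]
    else:
        chosen_k = config.k
        result = _stage("cluster")(lloyd_kmeans)(
            features, chosen_k, restarts=config.restarts, seed=config.seed
        )
        scan = None
    with open(out / "elbow_scan.json", "w") as fh:
        json.dump(
            {
                "k_values": scan.k_values.tolist() if scan else [chosen_k],
                "wss_by_k": scan.wss_by_k.tolist() if scan else [result.wss],
                "chosen_k": int(chosen_k),
                "threshold": config.elbow_threshold if scan else None,
                "wss": result.wss,
                "variance_explained": result.variance_explained,
            },
            fh,
            indent=2,
        )

    curves = _stage("curves")(smooth_cluster_curves)(features, result.labels, span=config.span)
    names = name_clusters(result, curves, features.kind)
    curves_frame(curves, names).to_csv(out / "curves.csv", index=False)
    if config.plot:
        ylabel = "mean METs" if features.kind == RAW else "mean normalized MVPA frequency"
        plot_curves(curves, out / "curves.png", names, ylabel=ylabel)

    pd.DataFrame(
        {
            "participant_id": features.participant_ids,
            "cluster": result.labels,
            "name": [names[int(c)] for c in result.labels],
        }
    ).to_csv(out / "labels.csv", index=False)

    bouts = _stage("bouts")(cohort_bout_summaries)(cohort)
    bouts.to_csv(out / "bout_summary.csv", index=False)

    # comparison runs on participants that made it into the feature matrix
    feat_ids = set(features.participant_ids)
    sub = CohortDataset(
        [t for t in cohort.traces if t.participant_id in feat_ids],
        cohort.covariates.loc[cohort.covariates.index.isin(feat_ids)],
    )
    specs = default_comparison_specs(sub)
    labels_by_id = {pid: int(c) for pid, c in zip(features.participant_ids, result.labels)}
    table = _stage("compare")(cluster_summary_table)(
        sub, labels_by_id, bouts[bouts["participant_id"].isin(feat_ids)],
        specs, names=names, alpha=config.alpha,
    )
    table.to_csv(out / "comparison.csv", index=False)
    (out / "comparison.md").write_text(table.to_markdown(index=False) + "\n")

    manifest = {
        "acticlust_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        "n_participants": len(cohort),
        "n_excluded": len(report),
        "chosen_k": int(chosen_k),
        "cluster_sizes": result.cluster_sizes().tolist(),
        "cluster_names": {str(c): n for c, n in names.items()},
        "wss": result.wss,
        "variance_explained": result.variance_explained,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %s", out)
    return out


def run_from_manifest(manifest_path) -> Path:
    """Re-run a pipeline from a previously written manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(RunConfig(**manifest["config"]))
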
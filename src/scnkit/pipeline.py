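"""End-to-end orchestration: config in, seeded reproducible report bundle out.

Stage order mirrors the analysis: demographics -> confound regression ->
per-group covariance networks -> thresholded graph series -> metric curves
-> AUC permutation tests (BH-FDR over nodes for nodal metrics) -> clinical
partial correlations. A master seed drives every random component through
counter-derived ``numpy.random.SeedSequence`` children, so identical
config + seed gives byte-identical numeric output regardless of stage
interleaving.

Defaults follow the study design the pipeline models: sparsity 0.05-0.50 in
0.01 steps (46 levels), 5000 permutations, 100 small-world null graphs,
FDR alpha 0.05. Tests and the reproduction script run the same pipeline at
reduced permutation counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_io, graphmetrics, inference, preprocess, scn
from .synthetic_cohort import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and context."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for one full analysis run."""

    # inputs: either file paths or a synthetic generator block
    volumes_path: str | None = None
    clinical_path: str | None = None
    synthetic: dict | None = None

    covariates: tuple[str, ...] = ("age", "gender")
    group_order: tuple[str, str] | None = None  # (group1, group2); default sorted

    sparsity_min: float = 0.05
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    rounding_rule: str = "round"

    n_perm: int = 5000
    global_metrics: tuple[str, ...] = graphmetrics.GLOBAL_METRICS
    nodal_metrics: tuple[str, ...] = graphmetrics.NODAL_METRICS
    fdr_alpha: float = 0.05
    bc_normalized: bool = False

    include_small_world: bool = True   # descriptive per-group sigma curves
    small_world_nulls: int = 100

    partial_corr_rois: tuple[str, ...] | None = None
    partial_corr_variables: tuple[str, ...] | None = None
    partial_corr_group: str | None = None

    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.synthetic is None and (self.volumes_path is None or self.clinical_path is None):
            raise PipelineError(
                "[config] provide either volumes_path + clinical_path or a synthetic block"
            )
        if not (0 < self.sparsity_min < self.sparsity_max <= 1):
            raise PipelineError("[config] need 0 < sparsity_min < sparsity_max <= 1")
        if self.sparsity_step <= 0:
            raise PipelineError("[config] sparsity_step must be positive")
        if self.n_perm < 1:
            raise PipelineError("[config] n_perm must be >= 1")
        unknown = set(self.global_metrics) - set(graphmetrics.GLOBAL_METRICS) - {"small_world"}
        if unknown:
            raise PipelineError(f"[config] unknown global metrics {sorted(unknown)}")
        unknown = set(self.nodal_metrics) - set(graphmetrics.NODAL_METRICS)
        if unknown:
            raise PipelineError(f"[config] unknown nodal metrics {sorted(unknown)}")

    def sparsities(self) -> np.ndarray:
        return scn.sparsity_grid(self.sparsity_min, self.sparsity_max, self.sparsity_step)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("covariates", "group_order", "global_metrics", "nodal_metrics",
                    "partial_corr_rois", "partial_corr_variables"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise PipelineError(f"[config] unknown keys {sorted(extra)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return PipelineConfig.from_dict(d)


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""

    class _Ctx:
        def __init__(self, label):
            self.label = label
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", self.label)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"[{self.label}] {exc}") from exc
            logger.info("stage %s: done in %.2fs", self.label, dt)

    return _Ctx(name)


def plot_metric_curves(global_curves: pd.DataFrame, out_path: str | Path) -> None:
    """Plot each global metric's sparsity curve per group (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = sorted(global_curves["metric"].unique())
    fig, axes = plt.subplots(1, len(metrics), figsize=(3.2 * len(metrics), 3), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = global_curves[global_curves["metric"] == metric]
        for group, gdf in sub.groupby("group"):
            ax.plot(gdf["sparsity"], gdf["value"], label=str(group))
        ax.set_title(metric)
        ax.set_xlabel("sparsity")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report.

    The report is a plain dict of scalars, nested dicts and DataFrames, the
    exact structure written by :func:`scnkit.data_io.write_report`.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    sparsities = config.sparsities()
    report: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "derived_seeds": {},
    }

    with _stage("load"):
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", int(master.generate_state(1)[0] % (2**31)))
            syn_cfg = SyntheticConfig.from_dict(syn)
            volumes, cohort, truth = generate_cohort(syn_cfg)
            report["synthetic_seed"] = syn_cfg.seed
            report["ground_truth"] = json.loads(truth.to_json())
        else:
            volumes = data_io.read_volume_table(config.volumes_path)
            cohort = data_io.read_clinical_table(config.clinical_path)
            truth = None
        cohort = cohort.aligned_to(volumes)
        levels = cohort.group_levels
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        if config.group_order:
            g1, g2 = config.group_order
        elif truth is not None:
            g1, g2 = "patient", "control"  # generator's labels, patient first
        else:
            g1, g2 = tuple(levels)
        report["groups"] = {
            "group1": str(g1),
            "group2": str(g2),
            "n_group1": int(cohort.subjects_in_group(g1).sum()),
            "n_group2": int(cohort.subjects_in_group(g2).sum()),
        }
        n_roi = volumes.n_roi
        report["network"] = {
            "n_roi": n_roi,
            "n_sparsity_levels": int(len(sparsities)),
            "sparsities": sparsities,
            "n_candidate_edges": int(n_roi * (n_roi - 1) // 2),
        }

    with _stage("demographics"):
        report["demographics"] = preprocess.demographic_table(cohort)

    with _stage("confound_regression"):
        model = preprocess.regress_confounds(volumes, cohort, config.covariates)
        res1 = model.residuals_for_group(cohort, g1)
        res2 = model.residuals_for_group(cohort, g2)

    with _stage("covariance_networks"):
        net1 = scn.build_covariance_network(res1, group=str(g1), roi_labels=volumes.roi_labels)
        net2 = scn.build_covariance_network(res2, group=str(g2), roi_labels=volumes.roi_labels)
        series1 = scn.build_graph_series(net1, sparsities, config.rounding_rule)
        series2 = scn.build_graph_series(net2, sparsities, config.rounding_rule)
        report["network"]["edge_counts"] = series1.edge_counts

    with _stage("metric_curves"):
        sw_seed = master.spawn(1)[0]
        report["derived_seeds"]["small_world"] = sw_seed.entropy
        rng_sw = np.random.default_rng(sw_seed)
        curves = []
        for series in (series1, series2):
            gset = graphmetrics.global_metric_series(
                series,
                include_small_world=config.include_small_world,
                n_null=config.small_world_nulls,
                rng=rng_sw,
            )
            for name, vals in gset.as_dict().items():
                for s, v in zip(sparsities, vals):
                    curves.append(
                        {"group": series.group, "metric": name, "sparsity": s, "value": v}
                    )
        report["global_curves"] = pd.DataFrame(curves)

    with _stage("permutation_tests"):
        global_rows, nodal_frames = [], []
        counter = 0
        for metric in config.global_metrics:
            child = np.random.SeedSequence(entropy=config.seed, spawn_key=(1, counter))
            counter += 1
            report["derived_seeds"][f"perm_{metric}"] = [1, counter - 1]
            extractor = inference.metric_curve_extractor(
                metric, sparsities, config.rounding_rule,
                small_world_nulls=config.small_world_nulls,
            )
            res = inference.permutation_test(
                res1, res2, extractor, sparsities,
                n_perm=config.n_perm, rng=np.random.default_rng(child), metric=metric,
            )
            global_rows.append(res.to_frame())
        for metric in config.nodal_metrics:
            child = np.random.SeedSequence(entropy=config.seed, spawn_key=(1, counter))
            counter += 1
            report["derived_seeds"][f"perm_{metric}"] = [1, counter - 1]
            extractor = inference.metric_curve_extractor(
                metric, sparsities, config.rounding_rule, bc_normalized=config.bc_normalized,
            )
            res = inference.permutation_test(
                res1, res2, extractor, sparsities,
                n_perm=config.n_perm, rng=np.random.default_rng(child),
                labels=volumes.roi_labels, metric=metric,
            )
            nodal_frames.append(res.to_frame())
        report["global_permutation"] = (
            pd.concat(global_rows, ignore_index=True) if global_rows else pd.DataFrame()
        )
        report["nodal_permutation"] = (
            pd.concat(nodal_frames, ignore_index=True) if nodal_frames else pd.DataFrame()
        )
        if len(report["nodal_permutation"]):
            sig = report["nodal_permutation"].query("q < @config.fdr_alpha")
            report["n_significant_nodal"] = int(len(sig))

    with _stage("partial_correlations"):
        rois = config.partial_corr_rois
        variables = config.partial_corr_variables
        if rois is None and truth is not None:
            rois = (volumes.roi_labels[truth.clinical_target_roi],)
        if variables is None and truth is not None:
            variables = ("score",)
        if rois and variables:
            pgroup = config.partial_corr_group
            if pgroup is None:
                pgroup = g1
            report["partial_correlations"] = inference.clinical_partial_correlations(
                volumes, cohort, rois, variables,
                covariates=config.covariates, group=pgroup,
            )

    if config.out_dir is not None:
        with _stage("write_report"):
            data_io.write_report(report, config.out_dir)
    return report
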
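"""End-to-end run orchestration: split -> network -> modules -> selection -> reports.

A run is fully described by a :class:`RunConfig`; every random draw consumes
a child seed derived from the single top-level seed, so a whole run is
reproducible from one integer.  Artifacts (CSV/GraphML/YAML) are written to
the run directory as each stage completes, so a failed stage still leaves
its predecessors on disk.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, network as net, scoring, selection, synthetic
from .data import (
    LabeledFeatureTable,
    load_feature_table,
    save_feature_table,
    split_cohort,
    standardize,
)
from .modules import tag_graph_with_modules
from .svm import SVMConfig, fit_svm_scores

log = logging.getLogger("nemtie")


@dataclass
class RunConfig:
    """Validated settings for one pipeline run (defaults follow the method)."""

    input_csv: str | None = None  # None -> synthetic default scenario
    label_column: str = "TMB_label"
    tmb_cutoff: float = 15.5
    ratios: tuple = (0.70, 0.20, 0.10)
    cv_method: str = "stratified_kfold"
    cv_folds: int = 5
    k: int = 3
    alpha: float = 0.5
    beta: float = 0.5
    pso_inertia: float = 0.8
    pso_c1: float = 1.49445
    pso_c2: float = 1.49445
    pso_particles: int = 20
    pso_iterations: int = 100
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    holdout_tuning: bool = False
    run_baselines: bool = False
    n_baseline_features: int = 13
    n_boot: int = 2000
    seed: int = 0
    out_dir: str = "nemtie_run"

    def __post_init__(self):
        if abs(self.alpha + self.beta - 1.0) > 1e-9 or self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative and sum to 1")
        if len(self.ratios) != 3 or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must be three fractions summing to 1")
        if self.k < 2:
            raise ValueError("clique size k must be >= 2")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["ratios"] = list(self.ratios)
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["ratios"] = tuple(payload["ratios"])
        return cls(**payload)


def _child_seeds(seed: int, n: int = 8) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(
    config: RunConfig, table: LabeledFeatureTable | None = None
) -> dict:
    """Execute the full workflow; returns a dict of in-memory results.

    Stages: cohort split, train-referenced standardization, information-gain
    network, PSO threshold tuning with clique-percolation modules, greedy
    subset selection, final SVM metrics, per-module report, optional
    baseline comparison.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = _child_seeds(config.seed)
    split_seed, cv_seed, pso_seed, svm_seed, boot_seed, base_seed, data_seed, _ = seeds

    stage = "load"
    try:
        if table is None:
            if config.input_csv:
                table = load_feature_table(
                    config.input_csv, config.label_column, tmb_cutoff=config.tmb_cutoff
                )
            else:
                table, manifest = synthetic.generate(
                    synthetic.default_scenario(seed=data_seed)
                )
                manifest.to_csv(out / "synthetic_manifest.csv", index=False)
                save_feature_table(table, out / "synthetic_table.csv")

        stage = "split"
        t0 = time.perf_counter()
        split = split_cohort(table, ratios=config.ratios, seed=split_seed)
        split.to_manifest(table.sample_ids).to_csv(out / "split_manifest.csv", index=False)

        stage = "standardize"
        table_std, std_params = standardize(table, fit_idx=split.train_idx)
        std_params.to_yaml(out / "standardization.yaml")

        stage = "network"
        cv = net.CVProtocol(method=config.cv_method, n_splits=config.cv_folds, seed=cv_seed)
        ten = net.build_entropy_matrix(table_std, cv=cv)
        ten = net.normalize_adjacency(ten)
        net.network_to_frame(ten, "E").to_csv(out / "entropy_matrix.csv")
        net.network_to_frame(ten, "R").to_csv(out / "adjacency_matrix.csv")
        log.info("network built in %.1fs", time.perf_counter() - t0)

        stage = "select"
        svm_config = SVMConfig(kernel=config.svm_kernel, C=config.svm_C, seed=svm_seed)
        loss_config = selection.LossConfig(
            alpha=config.alpha, beta=config.beta, svm=svm_config
        )
        pso_config = selection.PSOConfig(
            inertia=config.pso_inertia,
            c1=config.pso_c1,
            c2=config.pso_c2,
            n_particles=config.pso_particles,
            n_iterations=config.pso_iterations,
            seed=pso_seed,
        )
        result = selection.select_features(
            table_std,
            split,
            ten,
            loss_config=loss_config,
            pso_config=pso_config,
            k=config.k,
            holdout_tuning=config.holdout_tuning,
            metric_seed=boot_seed,
            n_boot=config.n_boot,
        )
        log.info(
            "T*=%.4f, D=%d modules, %d features selected",
            result.T_star, result.modules_used.D, len(result.selected_features),
        )

        stage = "write-selection"
        graph = net.threshold_graph(ten, result.T_star)
        degrees = net.feature_degrees(graph)
        pd.DataFrame(
            {
                "feature_name": result.selected_features,
                "degree": [degrees[j] for j in result.selected_indices],
            }
        ).to_csv(out / "selected_features.csv", index=False)
        pd.DataFrame(
            {
                "iteration": np.arange(1, len(result.loss_trace) + 1),
                "best_composite_auc": result.loss_trace,
            }
        ).to_csv(out / "loss_trace.csv", index=False)
        tag_graph_with_modules(graph, result.modules_used)
        net.export_graphml(graph, out / "network.graphml")
        net.edge_list(ten, result.T_star).to_csv(out / "edges.csv", index=False)
        result.modules_used.to_frame(table.feature_names).to_csv(
            out / "modules.csv", index=False
        )
        summary = {
            "T_star": result.T_star,
            "selected_features": list(result.selected_features),
            "n_modules": result.modules_used.D,
            "seeds": {
                "top_level": config.seed, "split": split_seed, "cv": cv_seed,
                "pso": pso_seed, "svm": svm_seed, "bootstrap": boot_seed,
            },
        }
        (out / "selection_summary.yaml").write_text(yaml.safe_dump(summary))

        stage = "metrics"
        if result.final_metrics:
            baselines.metrics_frame(
                [result.final_metrics[s] for s in ("train", "test", "validation")]
            ).to_csv(out / "metrics.csv", index=False)
            scores = selection.fit_final_model(
                table_std, split, result.selected_indices, loss_config
            )
            score_rows = []
            for name, idx in split.splits.items():
                for i, s in zip(idx, scores[name]):
                    score_rows.append(
                        {"sample_id": table.sample_ids[i], "split": name,
                         "score": float(s), "label": int(table.C[i])}
                    )
            pd.DataFrame(score_rows).to_csv(out / "decision_scores.csv", index=False)

        stage = "module-report"
        reports = scoring.per_module_svm_evaluation(
            result.modules_used, table_std, split, svm_config
        )
        scoring.report_frame(reports).to_csv(out / "module_report.csv", index=False)

        stage = "association"
        assoc = baselines.pearson_pfdr(table_std)
        assoc["degree"] = [degrees[j] for j in range(table.n)]
        assoc.to_csv(out / "feature_association.csv", index=False)

        comparison = None
        if config.run_baselines:
            stage = "baselines"
            methods = make_method_suite(config, ten)
            auc_table, comparison = baselines.compare_methods_resampled(
                table_std, methods, n_resamples=10, ratios=config.ratios,
                base_seed=base_seed,
            )
            auc_table.to_csv(out / "comparison_aucs.csv", index=False)
            comparison.to_csv(out / "comparison.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "table": table,
        "split": split,
        "network": ten,
        "result": result,
        "module_reports": reports,
        "association": assoc,
        "comparison": comparison,
        "out_dir": str(out),
    }


def make_method_suite(config: RunConfig, shared_network=None) -> dict:
    """Method callables (table, split, seed) -> test AUC for comparisons.

    The NEM-TIE entry rebuilds its network per resample unless a shared
    network is supplied (splits only affect the SVM stages, mirroring the
    all-sample network construction).
    """

    def nemtie_method(table, split, seed):
        ten = shared_network
        if ten is None:
            cv = net.CVProtocol(
                method=config.cv_method, n_splits=config.cv_folds, seed=seed
            )
            ten = net.normalize_adjacency(net.build_entropy_matrix(table, cv=cv))
        loss_config = selection.LossConfig(
            alpha=config.alpha, beta=config.beta,
            svm=SVMConfig(kernel=config.svm_kernel, C=config.svm_C, seed=seed),
        )
        pso_config = selection.PSOConfig(
            inertia=config.pso_inertia, c1=config.pso_c1, c2=config.pso_c2,
            n_particles=config.pso_particles, n_iterations=config.pso_iterations,
            seed=seed,
        )
        res = selection.select_features(
            table, split, ten, loss_config=loss_config, pso_config=pso_config,
            k=config.k, n_boot=50, metric_seed=seed,
        )
        if not res.final_metrics:
            return 0.5
        return res.final_metrics["test"].auc

    def _svm_test_auc(table, split, cols, seed):
        scores = fit_svm_scores(
            table, split, cols, SVMConfig(kernel=config.svm_kernel, C=config.svm_C, seed=seed)
        )
        return baselines.auc_score(scores["test"], table.C[split.test_idx])

    def mrmr_method(table, split, seed):
        cols = baselines.mrmr_select(table, split, n_select=config.n_baseline_features)
        return _svm_test_auc(table, split, cols, seed)

    def laplacian_method(table, split, seed):
        cols = baselines.laplacian_score_select(
            table, n_select=config.n_baseline_features
        )
        return _svm_test_auc(table, split, cols, seed)

    return {
        "nemtie": nemtie_method,
        "mrmr_svm": mrmr_method,
        "laplacian_svm": laplacian_method,
    }


def render_reports(run_dir) -> dict:
    """Derive human-readable report files from a completed run directory.

    Writes per-split ROC coordinate CSVs and a selected-feature table joining
    network degree with the label-association test.
    """
    from sklearn.metrics import roc_curve

    run = Path(run_dir)
    scores_path = run / "decision_scores.csv"
    if not scores_path.exists():
        raise FileNotFoundError(f"missing decision scores in {run_dir}; run the pipeline first")
    scores = pd.read_csv(scores_path)
    written = {}
    for name, grp in scores.groupby("split"):
        fpr, tpr, thr = roc_curve(grp["label"], grp["score"])
        path = run / f"roc_{name}.csv"
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(path, index=False)
        written[name] = str(path)

    selected = pd.read_csv(run / "selected_features.csv")
    assoc = pd.read_csv(run / "feature_association.csv")
    report = selected.merge(
        assoc[["feature_name", "pearson_r", "p_value", "q_value"]],
        on="feature_name", how="left",
    )
    report_path = run / "selected_feature_report.csv"
    report.to_csv(report_path, index=False)
    written["selected_feature_report"] = str(report_path)
    return written
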
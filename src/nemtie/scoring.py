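"""Fisher-type LDA scoring of modules and the per-module SVM evaluation.

Each module's feature submatrix is scored with a multivariate Fisher ratio

    Z = || (mu+ - mu-)(mu+ - mu-)^T ||_F / || v+ + v- ||

where mu+/mu- are the class mean vectors and v+/v- the per-feature unbiased
within-class variance vectors.  Z is invariant under a common positive
rescaling of the module's features and grows with between-class separation.

The per-module report mirrors the classical module table: each module's
features alone are fed to an SVM and AUCs on train/test/validation plus
their mean are recorded; modules whose mean AUC exceeds 0.8 (strictly) are
flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import auc_score
from .data import CohortSplit, LabeledFeatureTable
from .modules import ModuleSet
from .svm import SVMConfig, fit_svm_scores

SIGNIFICANT_AUC = 0.8  # strict > on the three-split mean
_DENOM_FLOOR = 1e-12


def lda_module_score(submatrix: np.ndarray, labels) -> float:
    """Fisher discriminant score Z >= 0 of a module feature submatrix."""
    X = np.atleast_2d(np.asarray(submatrix, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    y = np.asarray(labels, dtype=int)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 samples for the unbiased scatter")
    d = pos.mean(axis=0) - neg.mean(axis=0)
    numerator = np.linalg.norm(np.outer(d, d), "fro")  # == ||d||^2
    scatter = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    denominator = max(np.linalg.norm(scatter), _DENOM_FLOOR)
    return float(numerator / denominator)


def module_scores(modules: ModuleSet, table: LabeledFeatureTable) -> dict:
    """Z score per module id."""
    return {
        mod.module_id: lda_module_score(table.X[:, mod.sorted_indices()], table.C)
        for mod in modules
    }


def refine_modules(
    modules: ModuleSet, table: LabeledFeatureTable, keep: int | float | None = None
) -> tuple[ModuleSet, dict]:
    """Rank modules by Z descending (ties broken by module id); keep the top.

    ``keep`` may be an integer count or a fraction in (0, 1) interpreted as
    the top quantile (at least one module is always kept).  With
    ``keep=None`` all modules are retained in rank order — the ranking is
    recorded and downstream selection does the pruning.
    """
    if len(modules) == 0:
        raise ValueError("no modules to refine")
    if keep is not None and keep <= 0:
        raise ValueError("keep must be positive")
    scores = module_scores(modules, table)
    ranked = sorted(modules, key=lambda mod: (-scores[mod.module_id], mod.module_id))
    if keep is not None:
        if isinstance(keep, float) and 0 < keep < 1:
            keep = max(1, int(round(keep * len(ranked))))
        ranked = ranked[: int(keep)]
    return ModuleSet(modules=tuple(ranked), k=modules.k), scores


@dataclass(frozen=True)
class ModuleScoreReport:
    module_id: int
    features: tuple
    Z: float
    auc_train: float
    auc_test: float
    auc_validation: float
    flagged: bool

    @property
    def auc_mean(self) -> float:
        return (self.auc_train + self.auc_test + self.auc_validation) / 3


def flag_significant(auc_mean: float, threshold: float = SIGNIFICANT_AUC) -> bool:
    """Strictly-greater rule: a mean AUC of exactly 0.8 is not flagged."""
    return auc_mean > threshold


def per_module_svm_evaluation(
    modules: ModuleSet,
    table: LabeledFeatureTable,
    split: CohortSplit,
    svm_config: SVMConfig | None = None,
) -> list:
    """Fit an SVM per module (train split only) and report per-split AUCs."""
    svm_config = svm_config or SVMConfig()
    reports = []
    for mod in modules:
        cols = mod.sorted_indices()
        scores = fit_svm_scores(table, split, cols, svm_config)
        aucs = {
            name: auc_score(scores[name], table.C[idx])
            for name, idx in split.splits.items()
        }
        Z = lda_module_score(table.X[:, cols], table.C)
        mean_auc = float(np.mean([aucs["train"], aucs["test"], aucs["validation"]]))
        reports.append(
            ModuleScoreReport(
                module_id=mod.module_id,
                features=tuple(table.feature_names[j] for j in cols),
                Z=Z,
                auc_train=aucs["train"],
                auc_test=aucs["test"],
                auc_validation=aucs["validation"],
                flagged=flag_significant(mean_auc),
            )
        )
    return reports


def report_frame(reports) -> pd.DataFrame:
    """Module table: one row per module with AUCs, Z and the significance flag."""
    rows = [
        {
            "module_id": r.module_id,
            "features": ";".join(r.features),
            "AUC_train": r.auc_train,
            "AUC_test": r.auc_test,
            "AUC_validation": r.auc_validation,
            "AUC_mean": r.auc_mean,
            "Z": r.Z,
            "flagged": r.flagged,
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "module_id", "features", "AUC_train", "AUC_test",
            "AUC_validation", "AUC_mean", "Z", "flagged",
        ],
    )
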
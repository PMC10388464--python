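"""Shared SVM evaluator: a standardized SVM producing decision scores per split.

All stages that need a classifier (threshold evaluation, greedy selection,
per-module reports, baselines) go through this wrapper so kernel and
regularization settings stay consistent and configurable in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import CohortSplit, LabeledFeatureTable


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel SVM with C=1 and feature-count-scaled gamma by default."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0

    def build(self) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        kernel=self.kernel,
                        C=self.C,
                        gamma=self.gamma,
                        random_state=self.seed,
                    ),
                ),
            ]
        )


def fit_svm_scores(
    table: LabeledFeatureTable,
    split: CohortSplit,
    feature_indices,
    config: SVMConfig | None = None,
) -> dict:
    """Fit on the train split (given columns only); decision scores per split."""
    config = config or SVMConfig()
    cols = list(feature_indices)
    if not cols:
        raise ValueError("feature_indices must be nonempty")
    model = config.build()
    ytr = table.C[split.train_idx]
    if len(set(ytr.tolist())) < 2:
        raise ValueError("training split contains a single class")
    model.fit(table.X[split.train_idx][:, cols], ytr)
    return {
        name: model.decision_function(table.X[idx][:, cols])
        for name, idx in split.splits.items()
    }
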
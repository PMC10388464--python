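"""Outer selection loop: PSO over the adjacency threshold, greedy subset search.

The adjacency threshold ``T`` is tuned by canonical global-best particle
swarm optimization against a composite AUC objective

    AUC = alpha * AUC_train + beta * AUC_test        (alpha = beta = 1/2)

evaluated by an SVM on the union of clique-percolation module features at
``T``.  At the optimum ``T*`` a forward greedy search then picks the compact
feature subset (constrained to the module union) maximizing the same
composite objective.

Note the composite deliberately includes the test split, so the test set
participates in model selection; an optional holdout-tuning mode replaces it
with an inner validation fold carved out of the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .baselines import auc_score, classification_metrics
from .data import CohortSplit, LabeledFeatureTable
from .modules import ModuleSet, cpm_communities_from_matrix, order_modules
from .network import TransferEntropyNetwork
from .svm import SVMConfig, fit_svm_scores


@dataclass(frozen=True)
class LossConfig:
    """Composite-AUC weights and the SVM behind the objective."""

    alpha: float = 0.5
    beta: float = 0.5
    svm: SVMConfig = field(default_factory=SVMConfig)

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")


@dataclass(frozen=True)
class PSOConfig:
    """Canonical global-best PSO settings (inertia a, accelerations c1, c2)."""

    inertia: float = 0.8
    c1: float = 1.49445
    c2: float = 1.49445
    n_particles: int = 20
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one NEM-TIE selection run."""

    T_star: float
    selected_features: tuple  # feature names
    selected_indices: tuple
    modules_used: ModuleSet
    loss_trace: np.ndarray  # best composite AUC per PSO iteration (non-decreasing)
    greedy_trace: tuple  # composite AUC after each accepted greedy step
    final_metrics: dict  # split name -> EvaluationMetrics


def composite_auc_loss(auc_train: float, auc_test: float, config: LossConfig) -> float:
    """alpha * AUC_train + beta * AUC_test; the optimizer maximizes this."""
    for v in (auc_train, auc_test):
        if not (0 <= v <= 1):
            raise ValueError("AUC values must lie in [0, 1]")
    return config.alpha * auc_train + config.beta * auc_test


def _composite_for_columns(
    table: LabeledFeatureTable,
    split: CohortSplit,
    cols,
    loss_config: LossConfig,
) -> float:
    scores = fit_svm_scores(table, split, cols, loss_config.svm)
    return composite_auc_loss(
        auc_score(scores["train"], table.C[split.train_idx]),
        auc_score(scores["test"], table.C[split.test_idx]),
        loss_config,
    )


def evaluate_threshold(
    T: float,
    table: LabeledFeatureTable,
    split: CohortSplit,
    network: TransferEntropyNetwork,
    loss_config: LossConfig | None = None,
    k: int = 3,
) -> tuple[float, ModuleSet, list]:
    """Composite AUC of the SVM on the union of module features at T.

    An empty module set scores at chance (0.5 * (alpha + beta)) so the swarm
    can traverse dead regions of the threshold axis.
    """
    loss_config = loss_config or LossConfig()
    if network.R is None:
        raise ValueError("network adjacency R not computed")
    if not (0 <= T <= 1):
        raise ValueError("threshold T must lie in [0, 1]")
    communities = cpm_communities_from_matrix(network.R > T, k)
    modules = order_modules(communities, k, label=lambda v: network.feature_names[v])
    union = modules.feature_union()
    if not union:
        return 0.5 * (loss_config.alpha + loss_config.beta), modules, union
    return _composite_for_columns(table, split, union, loss_config), modules, union


def pso_optimize_threshold(
    objective, config: PSOConfig | None = None, bounds: tuple = (0.0, 1.0)
) -> tuple[float, float, np.ndarray]:
    """Maximize a scalar objective on [lo, hi] with global-best PSO.

    Velocity update: v <- a*v + c1*r1*(pbest - x) + c2*r2*(gbest - x);
    positions clamped to the bounds.  Returns (best position, best value,
    per-iteration best-value trace).  Deterministic for a fixed seed.
    """
    config = config or PSOConfig()
    lo, hi = bounds
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(lo, hi, config.n_particles)
    v = np.zeros(config.n_particles)

    def f(t):
        val = float(objective(float(t)))
        if not np.isfinite(val):
            raise ValueError(f"objective returned non-finite value at T={t}")
        return val

    pbest_x = x.copy()
    pbest_v = np.array([f(t) for t in x])
    g = int(np.argmax(pbest_v))
    gbest_x, gbest_v = float(pbest_x[g]), float(pbest_v[g])
    trace = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        r1 = rng.uniform(size=config.n_particles)
        r2 = rng.uniform(size=config.n_particles)
        v = config.inertia * v + config.c1 * r1 * (pbest_x - x) + config.c2 * r2 * (gbest_x - x)
        x = np.clip(x + v, lo, hi)
        vals = np.array([f(t) for t in x])
        better = vals > pbest_v
        pbest_x[better] = x[better]
        pbest_v[better] = vals[better]
        g = int(np.argmax(pbest_v))
        if pbest_v[g] > gbest_v:
            gbest_x, gbest_v = float(pbest_x[g]), float(pbest_v[g])
        trace[it] = gbest_v
    return gbest_x, gbest_v, trace


def greedy_feature_subset(
    candidate_features,
    table: LabeledFeatureTable,
    split: CohortSplit,
    loss_config: LossConfig | None = None,
    tol: float = 1e-4,
    exhaustive: bool = False,
) -> tuple[list, list]:
    """Forward greedy subset search maximizing the composite AUC.

    Starting empty, repeatedly add the candidate improving the objective the
    most; stop when no addition improves by more than *tol*.  Ties break on
    the lowest feature index.  ``exhaustive=True`` (<= 15 candidates) searches
    all nonempty subsets instead — a yardstick for greedy quality.
    """
    loss_config = loss_config or LossConfig()
    candidates = sorted(int(j) for j in candidate_features)
    if not candidates:
        raise ValueError("candidate feature set is empty")

    if exhaustive:
        if len(candidates) > 15:
            raise ValueError("exhaustive search limited to 15 candidates")
        best_subset, best_val = None, -np.inf
        for r in range(1, len(candidates) + 1):
            for combo in combinations(candidates, r):
                val = _composite_for_columns(table, split, list(combo), loss_config)
                if val > best_val + 1e-12:
                    best_subset, best_val = list(combo), val
        return best_subset, [best_val]

    selected: list = []
    trace: list = []
    current = -np.inf
    remaining = candidates.copy()
    while remaining:
        best_j, best_val = None, -np.inf
        for j in remaining:  # ascending index order makes ties deterministic
            val = _composite_for_columns(table, split, selected + [j], loss_config)
            if val > best_val:
                best_j, best_val = j, val
        if best_val <= current + tol and selected:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current = best_val
        trace.append(best_val)
    return selected, trace


def fit_final_model(
    table: LabeledFeatureTable,
    split: CohortSplit,
    feature_indices,
    loss_config: LossConfig | None = None,
) -> dict:
    """Fit the SVM on the selected features; decision scores for every split."""
    loss_config = loss_config or LossConfig()
    return fit_svm_scores(table, split, list(feature_indices), loss_config.svm)


def _holdout_split(table, split, seed: int) -> CohortSplit:
    """Inner tuning split: carve a pseudo-test fold out of the training split.

    Used by holdout-tuning mode so the real test split stays untouched during
    threshold/subset search.
    """
    rng = np.random.default_rng(seed)
    train = split.train_idx.copy()
    inner_test = []
    for c in (0, 1):
        cls = train[table.C[train] == c]
        cls = rng.permutation(cls)
        n_hold = max(1, int(round(len(cls) * 0.25)))
        inner_test.extend(cls[:n_hold])
    inner_test = np.sort(np.asarray(inner_test))
    inner_train = np.setdiff1d(train, inner_test)
    return CohortSplit(inner_train, inner_test, split.validation_idx, split.ratios, seed)


def select_features(
    table: LabeledFeatureTable,
    split: CohortSplit,
    network: TransferEntropyNetwork,
    loss_config: LossConfig | None = None,
    pso_config: PSOConfig | None = None,
    k: int = 3,
    greedy_tol: float = 1e-4,
    holdout_tuning: bool = False,
    metric_seed: int = 0,
    n_boot: int = 2000,
) -> SelectionResult:
    """Full outer loop: PSO threshold tuning, greedy subset, final metrics.

    The composite objective is piecewise constant between consecutive values
    of ``R``, so evaluations are memoized per distinct edge set; the swarm
    only pays for thresholds that actually change the graph.
    """
    loss_config = loss_config or LossConfig()
    pso_config = pso_config or PSOConfig()
    if network.R is None:
        raise ValueError("network adjacency R not computed")
    tuning_split = (
        _holdout_split(table, split, pso_config.seed) if holdout_tuning else split
    )

    off = network.R[~np.eye(network.n, dtype=bool)]
    levels = np.unique(off)
    module_cache: dict = {}
    loss_cache: dict = {}

    def modules_at(T: float):
        # the edge set only changes when T crosses a distinct value of R
        key = int(np.searchsorted(levels, T, side="right"))
        if key not in module_cache:
            communities = cpm_communities_from_matrix(network.R > T, k)
            modules = order_modules(
                communities, k, label=lambda v: network.feature_names[v]
            )
            module_cache[key] = (modules, modules.feature_union())
        return module_cache[key]

    def objective(T: float) -> float:
        _, union = modules_at(T)
        ukey = tuple(union)
        if ukey not in loss_cache:
            if not union:
                loss_cache[ukey] = 0.5 * (loss_config.alpha + loss_config.beta)
            else:
                loss_cache[ukey] = _composite_for_columns(
                    table, tuning_split, union, loss_config
                )
        return loss_cache[ukey]

    T_star, _, trace = pso_optimize_threshold(objective, pso_config)
    modules, union = modules_at(T_star)
    if union:
        selected, greedy_trace = greedy_feature_subset(
            union, table, tuning_split, loss_config, tol=greedy_tol
        )
        scores = fit_final_model(table, split, selected, loss_config)
        final = {
            name: classification_metrics(
                scores[name],
                table.C[idx],
                n_boot=n_boot,
                seed=metric_seed,
                split_name=name,
            )
            for name, idx in split.splits.items()
        }
    else:  # degenerate run: no module survives any threshold
        selected, greedy_trace, final = [], [], {}
    return SelectionResult(
        T_star=float(T_star),
        selected_features=tuple(table.feature_names[j] for j in selected),
        selected_indices=tuple(selected),
        modules_used=modules,
        loss_trace=trace,
        greedy_trace=tuple(greedy_trace),
        final_metrics=final,
    )
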
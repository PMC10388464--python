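"""Baseline feature selectors and the statistical evaluation battery.

Contains the rank-based AUC (with tie credit), sensitivity/specificity with
stratified bootstrap confidence intervals, mRMR and Laplacian-score feature
ranking, point-biserial Pearson tests with Storey positive-FDR q-values, and
the resampled paired t-test used to compare selection methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from sklearn.metrics import mutual_info_score

from .data import CohortSplit, LabeledFeatureTable, split_cohort


# ---------------------------------------------------------------------------
# AUC / sensitivity / specificity
# ---------------------------------------------------------------------------

def auc_score(scores, labels) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with 0.5 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _sens_spec(scores, y, threshold: float) -> tuple[float, float]:
    pred = scores > threshold
    sens = float(np.mean(pred[y == 1]))
    spec = float(np.mean(~pred[y == 0]))
    return sens, spec


def youden_threshold(scores, labels) -> float:
    """Operating point maximizing sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    cuts = np.concatenate([[-np.inf], np.unique(scores)])
    best, best_j = cuts[0], -np.inf
    for c in cuts:
        sens, spec = _sens_spec(scores, y, c)
        j = sens + spec - 1
        if j > best_j:
            best, best_j = c, j
    return float(best)


@dataclass(frozen=True)
class EvaluationMetrics:
    split_name: str
    auc: float
    sensitivity: float
    specificity: float
    ci: dict
    n_boot: int

    def as_row(self) -> dict:
        row = {"split": self.split_name}
        for name, value in (
            ("AUC", self.auc),
            ("Sensitivity", self.sensitivity),
            ("Specificity", self.specificity),
        ):
            lo, hi = self.ci[name]
            row[name] = value
            row[f"{name}_CI"] = f"{value:.4f} ({lo:.4f}-{hi:.4f})"
        return row


def classification_metrics(
    scores,
    labels,
    threshold: float = 0.0,
    operating: str = "fixed",
    n_boot: int = 2000,
    seed: int = 0,
    split_name: str = "",
) -> EvaluationMetrics:
    """AUC / sensitivity / specificity with stratified bootstrap percentile CIs.

    Decision scores above *threshold* (default 0, the SVM margin) predict the
    positive class; ``operating="youden"`` picks the Youden-optimal cut
    instead.  Bootstrap resamples positives and negatives separately.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len({0, 1} & set(np.unique(y))) < 2:
        raise ValueError("both classes required")
    if operating == "youden":
        threshold = youden_threshold(scores, y)
    auc = auc_score(scores, y)
    sens, spec = _sens_spec(scores, y, threshold)

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boot = np.empty((n_boot, 3))
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        s, yy = scores[idx], y[idx]
        boot[b, 0] = auc_score(s, yy)
        boot[b, 1], boot[b, 2] = _sens_spec(s, yy, threshold)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    ci = {
        "AUC": (float(lo[0]), float(hi[0])),
        "Sensitivity": (float(lo[1]), float(hi[1])),
        "Specificity": (float(lo[2]), float(hi[2])),
    }
    return EvaluationMetrics(split_name, auc, sens, spec, ci, n_boot)


def metrics_frame(metrics) -> pd.DataFrame:
    return pd.DataFrame([m.as_row() for m in metrics])


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    uniq = np.unique(col)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, col)
    # equal-frequency bins; duplicate edges collapse for heavy ties
    edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, col, side="right")


def mrmr_select(
    table: LabeledFeatureTable,
    split: CohortSplit | None = None,
    n_select: int = 10,
    n_bins: int = 4,
) -> list:
    """Classic mutual-information-difference mRMR ranking (feature indices).

    Features are discretized into equal-frequency bins on the train split;
    the first pick maximizes relevance I(f; C), each later pick maximizes
    relevance minus mean redundancy with the already-selected set.
    """
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > table.n:
        raise ValueError("n_select exceeds the number of features")
    rows = split.train_idx if split is not None else np.arange(table.m)
    X = table.X[rows]
    y = table.C[rows]
    disc = np.column_stack([_discretize(X[:, j], n_bins) for j in range(table.n)])
    relevance = np.array([mutual_info_score(disc[:, j], y) for j in range(table.n)])

    selected: list = []
    remaining = list(range(table.n))
    redundancy = np.zeros(table.n)
    while len(selected) < n_select:
        if selected:
            last = selected[-1]
            for j in remaining:
                redundancy[j] += mutual_info_score(disc[:, j], disc[:, last])
            crit = relevance - np.array(
                [redundancy[j] / len(selected) for j in range(table.n)]
            )
        else:
            crit = relevance.copy()
        best = max(remaining, key=lambda j: (crit[j], -j))
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# Laplacian score
# ---------------------------------------------------------------------------

def laplacian_score_select(
    table: LabeledFeatureTable, n_select: int = 10, knn: int = 5
) -> list:
    """Laplacian-score ranking (ascending: lower preserves locality better).

    Sample affinity: k-nearest-neighbour graph with a heat kernel whose
    bandwidth is the median pairwise distance.  Returns the best *n_select*
    feature indices; zero-variance features always rank last.
    """
    if knn >= table.m:
        raise ValueError("knn must be smaller than the number of samples")
    X = table.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Xs = (X - mu) / np.where(sd == 0, 1.0, sd)
    D2 = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=2)
    med = np.median(np.sqrt(D2[np.triu_indices(table.m, k=1)]))
    if med == 0:
        raise ValueError("all samples identical; affinity graph degenerate")
    W = np.zeros_like(D2)
    order = np.argsort(D2, axis=1)
    for i in range(table.m):
        nbrs = order[i, 1 : knn + 1]
        W[i, nbrs] = np.exp(-D2[i, nbrs] / (med**2))
    W = np.maximum(W, W.T)
    deg = W.sum(axis=1)
    L = np.diag(deg) - W

    scores = np.full(table.n, np.inf)
    for j in range(table.n):
        f = X[:, j]
        if np.ptp(f) == 0:
            continue  # variance floor: constant features rank last
        f_tilde = f - (f @ deg) / deg.sum()
        denom = f_tilde @ (deg * f_tilde)
        if denom < 1e-12:
            continue
        scores[j] = (f_tilde @ L @ f_tilde) / denom
    ranked = sorted(range(table.n), key=lambda j: (scores[j], j))
    return ranked[:n_select]


# ---------------------------------------------------------------------------
# Pearson correlation + positive FDR (Storey q-values)
# ---------------------------------------------------------------------------

def storey_qvalues(p_values, lambdas=None) -> np.ndarray:
    """Storey positive-FDR q-values with the cubic-spline pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a cubic
    spline and read off at the largest lambda; falls back to pi0 = 1 when the
    estimate is unstable (few tests).
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        pi0 = 1.0
    else:
        pi0_lam = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
        spline = CubicSpline(lambdas, pi0_lam)
        pi0 = float(np.clip(spline(lambdas[-1]), 1.0 / m, 1.0))
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank, idx in zip(range(m, 0, -1), order[::-1]):
        prev = min(prev, pi0 * p[idx] * m / rank)
        q[idx] = prev
    return q


def pearson_pfdr(
    table: LabeledFeatureTable,
    feature_subset=None,
    labels=None,
) -> pd.DataFrame:
    """Per-feature Pearson r against the binary label with pFDR q-values.

    Equivalent to the point-biserial correlation; two-sided p from the exact
    t reference distribution.  Zero-variance features get r = 0, p = 1 and a
    ``zero_variance`` flag.
    """
    if table.m < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    cols = list(feature_subset) if feature_subset is not None else list(range(table.n))
    y = np.asarray(labels if labels is not None else table.C, dtype=float)
    X = table.X[:, cols]
    mc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((mc**2).sum(axis=0) * (yc**2).sum())
    zero_var = denom == 0
    r = np.zeros(len(cols))
    np.divide(mc.T @ yc, denom, out=r, where=~zero_var)
    r = np.clip(r, -1.0, 1.0)
    dof = table.m - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), dof)
    p[np.abs(r) == 1.0] = 0.0
    p[zero_var] = 1.0
    q = storey_qvalues(p)
    return pd.DataFrame(
        {
            "feature_name": [table.feature_names[j] for j in cols],
            "pearson_r": r,
            "p_value": p,
            "q_value": q,
            "zero_variance": zero_var,
        }
    )


# ---------------------------------------------------------------------------
# Resampled method comparison
# ---------------------------------------------------------------------------

def compare_methods_resampled(
    table: LabeledFeatureTable,
    methods: dict,
    n_resamples: int = 10,
    ratios: tuple = (0.70, 0.20, 0.10),
    base_seed: int = 0,
    sides: str = "two",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-split the cohort *n_resamples* times, run each method, paired t-test.

    *methods* maps a name to ``callable(table, split, seed) -> test AUC``.
    The comparison is paired on the shared splits.  A method failure drops
    that resample pairwise (recorded as NaN).  Returns (per-resample AUC
    table, pairwise comparison table with t statistic and p-value).
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    names = list(methods)
    aucs = pd.DataFrame(index=range(n_resamples), columns=names, dtype=float)
    for rep in range(n_resamples):
        seed = int((base_seed * 7919 + rep) % (2**31))
        split = split_cohort(table, ratios=ratios, seed=seed)
        for name in names:
            try:
                aucs.loc[rep, name] = float(methods[name](table, split, seed))
            except Exception:
                aucs.loc[rep, name] = np.nan

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair = aucs[[a, b]].dropna()
            diff = pair[a].to_numpy() - pair[b].to_numpy()
            if np.allclose(diff.std(ddof=1), 0):
                if np.allclose(diff.mean(), 0):
                    t_stat, p = 0.0, 1.0
                else:
                    t_stat, p = np.sign(diff.mean()) * np.inf, 0.0
            else:
                alternative = "greater" if sides == "one" else "two-sided"
                t_stat, p = stats.ttest_rel(pair[a], pair[b], alternative=alternative)
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "n": len(pair),
                    "mean_auc_a": pair[a].mean(),
                    "mean_auc_b": pair[b].mean(),
                    "t": float(t_stat),
                    "p_value": float(p),
                    "sides": sides,
                }
            )
    return aucs, pd.DataFrame(rows)
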
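"""Network evolution model: LDA-accuracy information gain and adjacency matrix.

Every feature (and feature pair) is probed with a pooled-covariance linear
discriminant classifier under cross-validation; the resulting accuracies
``p_x``, ``p_y``, ``p_xy`` feed a pointwise-mutual-information-style gain

    E(X, Y | C) = p_xy * ln(p_xy / (p_x * p_y))

which, min-max normalized to [0, 1], is the weighted adjacency ``R`` of the
feature network.  Thresholding ``R`` at ``T`` yields the graph whose clique
communities are mined downstream.

The pair accuracies dominate the cost (n(n-1)/2 classifier fits), so the
2-D discriminant is solved in closed form for all pairs at once per CV fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import LabeledFeatureTable

ACC_EPS = 1e-6  # accuracies clipped to [ACC_EPS, 1] so logs stay finite
LDA_RIDGE = 1e-6  # ridge added to pooled covariance; survives collinear pairs


@dataclass(frozen=True)
class CVProtocol:
    """Accuracy-estimation protocol for the LDA probe.

    ``stratified_kfold`` (default: 5 folds repeated 5 times with seeded
    shuffles, averaging out fold-assignment noise in the accuracy estimates)
    or ``resubstitution`` (train = test = all samples).
    """

    method: str = "stratified_kfold"
    n_splits: int = 5
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("stratified_kfold", "resubstitution"):
            raise ValueError(f"unknown CV method {self.method!r}")

    def describe(self) -> str:
        if self.method == "resubstitution":
            return "resubstitution"
        return (
            f"stratified {self.n_splits}-fold CV x {self.n_repeats} repeats "
            f"(seed={self.seed})"
        )

    def folds(self, C: np.ndarray):
        m = len(C)
        if self.method == "resubstitution":
            idx = np.arange(m)
            yield idx, idx
            return
        for rep in range(self.n_repeats):
            skf = StratifiedKFold(
                n_splits=self.n_splits, shuffle=True,
                random_state=(self.seed + rep) % (2**31),
            )
            for tr, te in skf.split(np.zeros((m, 1)), C):
                yield tr, te


@dataclass(frozen=True)
class TransferEntropyNetwork:
    """Information-gain matrix ``E`` and normalized adjacency ``R`` over features."""

    feature_names: tuple
    p_single: np.ndarray
    E: np.ndarray
    R: np.ndarray | None
    accuracy_protocol: str

    @property
    def n(self) -> int:
        return len(self.feature_names)


def _lda_fold_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, ridge: float = LDA_RIDGE
) -> np.ndarray:
    """Pooled-covariance LDA with class priors; returns 0/1 predictions."""
    pos, neg = Xtr[ytr == 1], Xtr[ytr == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("CV training fold contains a single class")
    mu1, mu0 = pos.mean(axis=0), neg.mean(axis=0)
    a1, a0 = pos - mu1, neg - mu0
    dof = max(len(pos) + len(neg) - 2, 1)
    S = (a1.T @ a1 + a0.T @ a0) / dof
    S = S + ridge * np.eye(S.shape[0])
    d = mu1 - mu0
    w = np.linalg.solve(S, d)
    b = -w @ (mu1 + mu0) / 2 + np.log(len(pos) / len(neg))
    return (Xte @ w + b > 0).astype(int)


def lda_accuracy(
    table: LabeledFeatureTable,
    feature_subset: Sequence[int],
    cv: CVProtocol = CVProtocol(),
    ridge: float = LDA_RIDGE,
) -> float:
    """Cross-validated LDA accuracy on the given feature column(s), in [eps, 1]."""
    cols = np.asarray(list(feature_subset), dtype=int)
    if cols.size == 0:
        raise ValueError("feature_subset must be nonempty")
    X = table.X[:, cols]
    correct = 0
    total = 0
    for tr, te in cv.folds(table.C):
        pred = _lda_fold_predict(X[tr], table.C[tr], X[te], ridge)
        correct += int(np.sum(pred == table.C[te]))
        total += len(te)
    return float(np.clip(correct / total, ACC_EPS, 1.0))


def pair_information_gain(p_x: float, p_y: float, p_xy: float) -> float:
    """Pointwise information gain ``p_xy * ln(p_xy / (p_x p_y))``; may be negative."""
    for v in (p_x, p_y, p_xy):
        if not (0 < v <= 1):
            raise ValueError("accuracies must lie in (0, 1]")
    return float(p_xy * np.log(p_xy / (p_x * p_y)))


def _fold_pair_correct(
    X: np.ndarray, y: np.ndarray, tr: np.ndarray, te: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Correct-prediction counts on a fold for all single features and pairs.

    Closed-form 2x2 pooled-covariance solve, broadcast over all feature pairs.
    Matches :func:`_lda_fold_predict` exactly for 1- and 2-column subsets.
    """
    Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
    pos, neg = Xtr[ytr == 1], Xtr[ytr == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("CV training fold contains a single class")
    mu1, mu0 = pos.mean(axis=0), neg.mean(axis=0)
    a1, a0 = pos - mu1, neg - mu0
    dof = max(len(pos) + len(neg) - 2, 1)
    S = (a1.T @ a1 + a0.T @ a0) / dof  # pooled covariance, all features at once
    d = mu1 - mu0
    prior = np.log(len(pos) / len(neg))
    Xc = Xte - (mu1 + mu0) / 2

    # single features: w = d / (S_jj + ridge)
    var = np.diag(S) + ridge
    score_s = Xc * (d / var) + prior
    correct_s = ((score_s > 0).astype(int) == yte[:, None]).sum(axis=0)

    # pairs: invert [[S_jj+r, S_jk], [S_jk, S_kk+r]] analytically
    Sjj = var[:, None]
    Skk = var[None, :]
    Sjk = S
    det = Sjj * Skk - Sjk**2
    w1 = (Skk * d[:, None] - Sjk * d[None, :]) / det
    w2 = (Sjj * d[None, :] - Sjk * d[:, None]) / det
    score_p = Xc[:, :, None] * w1[None] + Xc[:, None, :] * w2[None] + prior
    correct_p = ((score_p > 0).astype(int) == yte[:, None, None]).sum(axis=0)
    return correct_s, correct_p


def build_entropy_matrix(
    table: LabeledFeatureTable,
    cv: CVProtocol = CVProtocol(),
    ridge: float = LDA_RIDGE,
) -> TransferEntropyNetwork:
    """Fill the information-gain matrix ``E`` over all feature pairs (R unset)."""
    n = table.n
    if n < 2:
        raise ValueError("at least two features are required to build a network")
    correct_s = np.zeros(n)
    correct_p = np.zeros((n, n))
    total = 0
    for tr, te in cv.folds(table.C):
        cs, cp = _fold_pair_correct(table.X, table.C, tr, te, ridge)
        correct_s += cs
        correct_p += cp
        total += len(te)
    p_single = np.clip(correct_s / total, ACC_EPS, 1.0)
    p_pair = np.clip(correct_p / total, ACC_EPS, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = p_pair * np.log(p_pair / np.outer(p_single, p_single))
    np.fill_diagonal(E, 0.0)
    E = (E + E.T) / 2  # enforce exact symmetry against float noise
    return TransferEntropyNetwork(
        feature_names=table.feature_names,
        p_single=p_single,
        E=E,
        R=None,
        accuracy_protocol=cv.describe(),
    )


def normalize_adjacency(network: TransferEntropyNetwork) -> TransferEntropyNetwork:
    """Min-max normalize the off-diagonal of ``E`` into ``R`` in [0, 1].

    If all off-diagonal gains are equal the network degenerates to R = 0
    everywhere (an edgeless graph at any positive threshold).
    """
    n = network.n
    off = ~np.eye(n, dtype=bool)
    lo, hi = network.E[off].min(), network.E[off].max()
    if hi == lo:
        R = np.zeros_like(network.E)
    else:
        R = (network.E - lo) / (hi - lo)
    R[~off] = 0.0
    return replace(network, R=R)


def threshold_graph(network: TransferEntropyNetwork, T: float) -> nx.Graph:
    """Graph with an edge (j, k) wherever ``R[j, k] > T`` (strict).

    Nodes are feature indices with a ``label`` attribute holding the name;
    isolated features remain as nodes.
    """
    if network.R is None:
        raise ValueError("adjacency R not computed; call normalize_adjacency first")
    if not (0 <= T <= 1):
        raise ValueError("threshold T must lie in [0, 1]")
    n = network.n
    G = nx.Graph()
    G.add_nodes_from(
        (j, {"label": network.feature_names[j]}) for j in range(n)
    )
    jj, kk = np.nonzero(np.triu(network.R > T, k=1))
    G.add_weighted_edges_from(
        (int(j), int(k), float(network.R[j, k])) for j, k in zip(jj, kk)
    )
    return G


def feature_degrees(graph: nx.Graph) -> dict:
    """Degree of every feature node in the thresholded graph."""
    return dict(graph.degree())


def network_to_frame(network: TransferEntropyNetwork, which: str = "R") -> pd.DataFrame:
    M = network.R if which == "R" else network.E
    if M is None:
        raise ValueError(f"matrix {which} not computed")
    names = list(network.feature_names)
    return pd.DataFrame(M, index=names, columns=names)


def edge_list(network: TransferEntropyNetwork, T: float) -> pd.DataFrame:
    """3-column edge list (feature_j, feature_k, weight) of the graph at T."""
    G = threshold_graph(network, T)
    rows = [
        {
            "feature_j": network.feature_names[j],
            "feature_k": network.feature_names[k],
            "weight": w,
        }
        for j, k, w in G.edges.data("weight")
    ]
    return pd.DataFrame(rows, columns=["feature_j", "feature_k", "weight"])


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
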
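"""Brute-force reference implementations used only as test oracles."""

from itertools import combinations

import networkx as nx
import numpy as np


def brute_force_k_cliques(graph: nx.Graph, k: int) -> set:
    """All k-vertex subsets that are fully connected, by direct enumeration."""
    out = set()
    for sub in combinations(sorted(graph.nodes()), k):
        if all(graph.has_edge(u, v) for u, v in combinations(sub, 2)):
            out.add(frozenset(sub))
    return out


def brute_force_clique_percolation(graph: nx.Graph, k: int) -> set:
    """CPM communities: components of the clique graph under (k-1)-overlap."""
    cliques = sorted(brute_force_k_cliques(graph, k), key=sorted)
    meta = nx.Graph()
    meta.add_nodes_from(range(len(cliques)))
    for i, j in combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) >= k - 1:
            meta.add_edge(i, j)
    communities = set()
    for component in nx.connected_components(meta):
        members = frozenset().union(*(cliques[i] for i in component))
        communities.add(members)
    return communities


def pair_counting_auc(scores, labels) -> float:
    """AUC by exhaustive concordant/discordant pair counting with tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
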
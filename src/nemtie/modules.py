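"""Clique-percolation communities (feature modules) on the thresholded network.

A k-clique community is the union of all k-cliques reachable from one another
through (k-1)-vertex overlaps.  Communities may overlap; isolated vertices and
plain edges are never modules.  For the default k = 3 (triangle percolation)
a union-find over triangle edges is used, which stays fast on the dense
graphs visited at low adjacency thresholds; other k delegate to networkx.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import k_clique_communities

from .data import LabeledFeatureTable


@dataclass(frozen=True)
class FeatureModule:
    """One clique-percolation community: a set of >= k feature indices."""

    module_id: int
    feature_indices: frozenset
    k: int

    def __post_init__(self):
        object.__setattr__(self, "feature_indices", frozenset(int(i) for i in self.feature_indices))
        if len(self.feature_indices) < self.k:
            raise ValueError("module smaller than its clique size k")

    def sorted_indices(self) -> list:
        return sorted(self.feature_indices)


@dataclass(frozen=True)
class ModuleSet:
    """Ordered collection of feature modules found at one threshold."""

    modules: tuple
    k: int

    def __post_init__(self):
        object.__setattr__(self, "modules", tuple(self.modules))

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, i) -> FeatureModule:
        return self.modules[i]

    @property
    def D(self) -> int:
        """Total number of modules."""
        return len(self.modules)

    def feature_union(self) -> list:
        out = set()
        for mod in self.modules:
            out |= mod.feature_indices
        return sorted(out)

    def to_frame(self, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for mod in self.modules:
            for j in mod.sorted_indices():
                rows.append(
                    {
                        "module_id": mod.module_id,
                        "feature_name": feature_names[j] if feature_names else str(j),
                    }
                )
        return pd.DataFrame(rows, columns=["module_id", "feature_name"])


def enumerate_k_cliques(graph: nx.Graph, k: int) -> set:
    """All fully-connected vertex subsets of size k, as frozensets."""
    if k < 2:
        raise ValueError("clique size k must be >= 2")
    cliques = set()
    for maximal in nx.find_cliques(graph):
        if len(maximal) >= k:
            for sub in combinations(sorted(maximal), k):
                cliques.add(frozenset(sub))
    return cliques


def _triangle_percolation_matrix(A: np.ndarray) -> list:
    """3-clique percolation via connected components of the triangle-edge graph.

    Two 3-cliques are adjacent iff they share an edge, so communities are the
    components of the graph whose vertices are *edges* and whose links join
    edges lying in a common triangle.  Everything is vectorized so dense
    thresholded graphs (low T) stay cheap.  ``A`` is a symmetric boolean
    adjacency matrix; returns frozensets of integer vertex indices.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = A.shape[0]
    ei, ej = np.nonzero(np.triu(A, k=1))
    n_edges = len(ei)
    if n_edges == 0:
        return []
    eid_mat = np.full((n, n), -1, dtype=np.int32)
    eid_mat[ei, ej] = eid_mat[ej, ei] = np.arange(n_edges, dtype=np.int32)

    # enumerate each triangle {a<b<c} exactly once, from its edge (a, b) and
    # completing vertex c > b: linking (a,b)-(a,c) and (a,b)-(b,c) already
    # makes every triangle's three edges mutually connected
    common = A[ei] & A[ej]
    common &= np.arange(n)[None, :] > ej[:, None]
    rows, ws = np.nonzero(common)
    if rows.size == 0:
        return []
    rows = rows.astype(np.int32)
    link_a = eid_mat[ei[rows], ws]
    link_b = eid_mat[ej[rows], ws]
    src = np.concatenate([rows, rows])
    dst = np.concatenate([link_a, link_b])
    adj = coo_matrix((np.ones(len(src), dtype=np.int8), (src, dst)), shape=(n_edges, n_edges))
    _, labels = connected_components(adj, directed=False)

    in_triangle = np.zeros(n_edges, dtype=bool)
    in_triangle[rows] = True
    in_triangle[link_a] = True
    in_triangle[link_b] = True
    groups: dict = {}
    for eid in np.flatnonzero(in_triangle):
        groups.setdefault(labels[eid], set()).update((int(ei[eid]), int(ej[eid])))
    return [frozenset(g) for g in groups.values()]


def cpm_communities_from_matrix(A: np.ndarray, k: int = 3) -> list:
    """Clique-percolation communities of a boolean adjacency matrix.

    Fast vectorized path for k = 3; other k go through networkx.  Returns
    unordered frozensets of integer vertex indices.
    """
    if k < 2:
        raise ValueError("clique size k must be >= 2")
    A = np.asarray(A, dtype=bool)
    if k == 3:
        return _triangle_percolation_matrix(A)
    G = nx.from_numpy_array(A)
    return [frozenset(int(v) for v in c) for c in k_clique_communities(G, k)]


def clique_percolation(
    graph: nx.Graph, k: int = 3, include_edges: bool = False
) -> ModuleSet:
    """Clique-percolation communities of the graph as a :class:`ModuleSet`.

    Module ids are assigned deterministically: modules sorted by size
    descending, then by the lexicographically smallest member label.
    ``include_edges`` additionally appends each edge that belongs to no
    community as a 2-clique module — an exploratory option, off by default
    (bare edges are not communities under CPM semantics).
    """
    if k < 2:
        raise ValueError("clique size k must be >= 2")
    if graph.number_of_edges() == 0:
        return ModuleSet(modules=(), k=k)
    nodes = sorted(graph.nodes())
    pos = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in graph.edges():
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = True
    communities = [
        frozenset(nodes[i] for i in c) for c in cpm_communities_from_matrix(A, k)
    ]
    if include_edges:
        covered = set().union(frozenset(), *communities)
        for u, v in graph.edges():
            if u not in covered or v not in covered:
                communities.append(frozenset({u, v}))

    def label(v):
        return str(graph.nodes[v].get("label", v))

    k_eff = 2 if include_edges else k
    return order_modules(communities, k_eff, label)


def order_modules(communities, k: int, label=str) -> ModuleSet:
    """Deterministic module ids: size descending, then smallest member label."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(label(v) for v in c)))
    modules = tuple(
        FeatureModule(module_id=i, feature_indices=frozenset(c), k=k)
        for i, c in enumerate(ordered)
    )
    return ModuleSet(modules=modules, k=k)


def modules_to_submatrices(
    table: LabeledFeatureTable, modules: ModuleSet | Iterable[FeatureModule]
) -> list:
    """Column-sliced submatrices X_ms, one per module, in module order."""
    out = []
    for mod in modules:
        cols = mod.sorted_indices()
        if cols and (min(cols) < 0 or max(cols) >= table.n):
            raise IndexError(f"module {mod.module_id} references out-of-range features")
        out.append(table.X[:, cols])
    return out


def tag_graph_with_modules(graph: nx.Graph, modules: ModuleSet) -> nx.Graph:
    """Annotate nodes with a comma-joined list of module ids (GraphML-friendly)."""
    member: dict = {}
    for mod in modules:
        for v in mod.feature_indices:
            member.setdefault(v, []).append(mod.module_id)
    for v in graph.nodes():
        graph.nodes[v]["modules"] = ",".join(str(i) for i in member.get(v, []))
    return graph
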
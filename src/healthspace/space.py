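"""The disease space: proximity network, maximum spanning trees, backbones.

Proximity between two diseases is the minimum of the two conditional
probabilities of co-RDD,

    Phi[i, j] = min{ P(RDD_i >= 1 | RDD_j >= 1), P(RDD_j >= 1 | RDD_i >= 1) }
              = |{c : M[c,i] = M[c,j] = 1}| / max(ubiquity_i, ubiquity_j),

which is symmetric by construction and avoids a rare disease looking close to
everything.  The disease space is the maximum spanning tree (MST) of Phi plus
the strongest non-tree links, added in decreasing weight until the average
degree reaches a target (four, by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_panel import CountryDiseaseMatrix
from .rdd import DegenerateInputError, IncidenceMatrix


@dataclass
class ProximityMatrix:
    """Symmetric k x k proximity matrix in [0, 1] with zero diagonal."""

    Phi: np.ndarray
    diseases: list[str]
    year: int | None = None

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        if not np.allclose(self.Phi, self.Phi.T):
            raise ValueError("proximity matrix must be symmetric")
        if (self.Phi < 0).any() or (self.Phi > 1).any():
            raise ValueError("proximities must lie in [0, 1]")
        if np.diagonal(self.Phi).any():
            raise ValueError("diagonal must be zero (self-pairs excluded)")


def compute_proximity(M: IncidenceMatrix | np.ndarray) -> ProximityMatrix:
    """Pairwise disease proximity from the binary incidence matrix."""
    if isinstance(M, IncidenceMatrix):
        arr, diseases, year = M.M, M.diseases, M.year
    else:
        arr = np.asarray(M)
        diseases = [f"d{j}" for j in range(arr.shape[1])]
        year = None
    ubiquity = arr.sum(axis=0)
    if (ubiquity == 0).any():
        raise DegenerateInputError("cannot condition on a disease with zero ubiquity")
    co = arr.T.astype(float) @ arr.astype(float)  # co-occurrence counts
    denom = np.maximum.outer(ubiquity, ubiquity).astype(float)
    Phi = co / denom
    np.fill_diagonal(Phi, 0.0)
    return ProximityMatrix(Phi, diseases, year=year)


def _sorted_edges(graph: nx.Graph) -> list[tuple]:
    """Edges by decreasing weight; ties broken by (source, target) labels."""
    return sorted(
        ((u, v, d["weight"]) for u, v, d in graph.edges(data=True)),
        key=lambda e: (-e[2], str(min(e[0], e[1], key=str)), str(max(e[0], e[1], key=str))),
    )


def max_spanning_tree(
    weights, labels: list[str] | None = None, on_disconnected: str = "forest"
) -> list[tuple]:
    """Maximum spanning tree (Kruskal) of a weighted graph.

    ``weights`` is either a symmetric nonnegative matrix (zero = no edge) or a
    networkx graph with 'weight' edge attributes.  Returns the tree as a list
    of (u, v, weight) edges.  A disconnected positive-weight graph either
    raises (``on_disconnected="error"``) or yields a maximum spanning forest
    with a warning.  Equal-weight ties break lexicographically on labels, so
    the output is deterministic.
    """
    if isinstance(weights, nx.Graph):
        graph = weights
    else:
        arr = np.asarray(weights, dtype=float)
        if labels is None:
            labels = [f"n{i}" for i in range(arr.shape[0])]
        graph = nx.Graph()
        graph.add_nodes_from(labels)
        ii, jj = np.nonzero(np.triu(arr, k=1))
        graph.add_weighted_edges_from(
            (labels[i], labels[j], float(arr[i, j])) for i, j in zip(ii, jj)
        )

    uf = nx.utils.UnionFind(graph.nodes())
    tree = []
    for u, v, w in _sorted_edges(graph):
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.append((u, v, w))
    if len(tree) < graph.number_of_nodes() - 1:
        if on_disconnected == "error":
            raise ValueError("positive-weight graph is disconnected")
        warnings.warn(
            "graph is disconnected; returning a maximum spanning forest",
            stacklevel=2,
        )
    return tree


def added_edge_count(k: int, target_avg_degree: float) -> int:
    """Edges beyond the spanning tree needed to first reach the degree target."""
    return max(0, math.ceil(k * target_avg_degree / 2) - (k - 1))


def build_disease_space(
    Phi: ProximityMatrix, target_avg_degree: float = 4.0
) -> nx.Graph:
    """Disease-space backbone: MST of Phi plus strongest non-MST links.

    Links are added in strictly decreasing proximity (ties lexicographic)
    until the average degree 2|E|/|V| first reaches ``target_avg_degree``.
    Zero-proximity pairs are never linked.  Each edge carries ``in_mst``;
    the graph records the weakest added link as ``graph.graph["cutoff"]``.
    """
    k = len(Phi.diseases)
    if target_avg_degree < 2 * (k - 1) / k:
        raise ValueError("target average degree is below that of a spanning tree")

    full = nx.Graph()
    full.add_nodes_from(Phi.diseases)
    ii, jj = np.nonzero(np.triu(Phi.Phi, k=1))
    full.add_weighted_edges_from(
        (Phi.diseases[i], Phi.diseases[j], float(Phi.Phi[i, j]))
        for i, j in zip(ii, jj)
    )

    mst_edges = max_spanning_tree(full)
    net = nx.Graph(cutoff=None)
    net.add_nodes_from((n, {"label": n, "kind": "disease"}) for n in Phi.diseases)
    net.add_edges_from((u, v, {"weight": w, "in_mst": True}) for u, v, w in mst_edges)

    in_tree = set(map(frozenset, ((u, v) for u, v, _ in mst_edges)))
    for u, v, w in _sorted_edges(full):
        if 2 * net.number_of_edges() / k >= target_avg_degree:
            break
        if frozenset((u, v)) in in_tree:
            continue
        net.add_edge(u, v, weight=w, in_mst=False)
        net.graph["cutoff"] = w
    return net


def build_country_disease_graph(
    E: CountryDiseaseMatrix, weight: str = "rate", rdd_matrix=None
) -> nx.Graph:
    """Weighted bipartite country-disease network with its MST flagged.

    One node per country (kind="country") and per disease (kind="disease");
    an edge for every positive cell, weighted by the prevalence rate (or the
    RDD ratio when ``weight="rdd"`` and ``rdd_matrix`` is given).  Edges on
    the maximum spanning tree (l + k - 1 edges when connected) are flagged
    ``in_mst``.
    """
    if weight == "rate":
        W = E.E
    elif weight == "rdd":
        if rdd_matrix is None:
            raise ValueError('weight="rdd" requires rdd_matrix')
        W = rdd_matrix.R
    else:
        raise ValueError(f"unknown edge weight: {weight!r}")

    groups = E.disease_groups or [""] * len(E.diseases)
    g = nx.Graph()
    for c in E.countries:
        g.add_node(f"C::{c}", label=c, kind="country", group="")
    for d, grp in zip(E.diseases, groups):
        g.add_node(f"D::{d}", label=d, kind="disease", group=grp)
    ii, jj = np.nonzero(W)
    for i, j in zip(ii, jj):
        g.add_edge(f"C::{E.countries[i]}", f"D::{E.diseases[j]}", weight=float(W[i, j]))

    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        warnings.warn(f"bipartite graph has {n_comp} components", stacklevel=2)
    tree = set(map(frozenset, ((u, v) for u, v, _ in max_spanning_tree(g))))
    for u, v in g.edges():
        g[u][v]["in_mst"] = frozenset((u, v)) in tree
    return g
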
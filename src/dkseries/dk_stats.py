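"""The dk-distribution hierarchy of degree-labelled subgraph statistics.

The dk-distribution of a graph G tallies G's connected subgraphs of size
d with nodes labelled by their degree *in G*:

* d = 0 — the average degree ``2M/N`` (a single scalar);
* d = 1 — the degree distribution, nodes (size-1 subgraphs) per degree;
* d = 2 — the joint degree distribution, edges per unordered degree pair;
* d = 3 — degree-labelled triangles and wedges (connected induced
  3-node subgraphs: a triangle triple is counted once as a triangle,
  not additionally as three wedges).

The hierarchy is *inclusive*: each level determines all lower ones (the
degree distribution yields the average degree; the joint degree
distribution yields the degree distribution through its marginals; the
labelled 3-subgraph tallies determine the clustering spectrum exactly).
Fractional levels 2.1 and 2.5 augment the d = 2 statistic with,
respectively, the scalar mean clustering c-bar and the degree-dependent
clustering spectrum c-bar(k); they are the targets of the annealed
rewiring in :mod:`dkseries.rewiring`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import networkx as nx

__all__ = [
    "Labeled3kDistribution",
    "ClusteringStats",
    "DkStatistics",
    "average_degree",
    "degree_distribution",
    "joint_degree_distribution",
    "labeled_3k_distribution",
    "clustering_stats",
    "dk_statistics",
    "l1_distance_clustering",
]


@dataclass(frozen=True)
class Labeled3kDistribution:
    """Counts of connected induced 3-node subgraphs, degree-labelled.

    ``triangles`` maps a sorted degree triple to a count; ``wedges``
    maps ``(sorted end degrees, centre degree)`` to a count.
    """

    triangles: dict[tuple[int, int, int], int] = field(default_factory=dict)
    wedges: dict[tuple[tuple[int, int], int], int] = field(default_factory=dict)

    @property
    def n_triangles(self) -> int:
        return sum(self.triangles.values())

    @property
    def n_wedges(self) -> int:
        return sum(self.wedges.values())

    @property
    def total(self) -> int:
        """Total number of connected induced 3-node subgraphs."""
        return self.n_triangles + self.n_wedges


@dataclass(frozen=True)
class ClusteringStats:
    """Mean clustering c-bar and the clustering spectrum c-bar(k).

    Local clustering of a node u with degree k >= 2 is
    ``triangles_at(u) / C(k, 2)``; nodes with degree < 2 contribute 0 to
    the unweighted mean over all nodes and are excluded from
    ``by_degree``.
    """

    mean_clustering: float
    by_degree: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DkStatistics:
    """The full dk snapshot of a graph (levels 0, 1, 2, 3 and 2.x)."""

    d0: float
    d1: dict[int, int]
    d2: dict[tuple[int, int], int]
    d3: Labeled3kDistribution
    clustering: ClusteringStats


def average_degree(g: nx.Graph) -> float:
    """The 0k statistic: 2M/N."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("average degree is undefined for the empty graph")
    return 2.0 * g.number_of_edges() / n


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """The 1k statistic: number of nodes N(k) of each degree k.

    Declared isolated nodes appear under k = 0.
    """
    counts: dict[int, int] = {}
    for _, k in g.degree():
        counts[k] = counts.get(k, 0) + 1
    return counts


def joint_degree_distribution(g: nx.Graph) -> dict[tuple[int, int], int]:
    """The 2k statistic: number of edges m(k1, k2) per unordered degree pair."""
    deg = dict(g.degree())
    counts: dict[tuple[int, int], int] = {}
    for u, v in g.edges():
        key = (deg[u], deg[v]) if deg[u] <= deg[v] else (deg[v], deg[u])
        counts[key] = counts.get(key, 0) + 1
    return counts


def labeled_3k_distribution(g: nx.Graph) -> Labeled3kDistribution:
    """The 3k statistic: degree-labelled triangles and wedges.

    Subgraphs are connected *induced* 3-node subgraphs: a triple
    inducing 3 edges is one triangle; a triple inducing exactly 2 edges
    is one wedge keyed by (sorted end degrees, centre degree).
    """
    deg = dict(g.degree())
    order = {u: i for i, u in enumerate(g.nodes())}
    adj = {u: set(g.neighbors(u)) for u in g.nodes()}

    triangles: dict[tuple[int, int, int], int] = {}
    wedges: dict[tuple[tuple[int, int], int], int] = {}

    for u, v in g.edges():
        # canonical: count triangle at its highest-order vertex pair
        for w in adj[u] & adj[v]:
            if order[w] > max(order[u], order[v]):
                key = tuple(sorted((deg[u], deg[v], deg[w])))
                triangles[key] = triangles.get(key, 0) + 1
    for c in g.nodes():
        nbrs = sorted(adj[c], key=order.__getitem__)
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                a, b = nbrs[i], nbrs[j]
                if b not in adj[a]:
                    ends = (deg[a], deg[b]) if deg[a] <= deg[b] else (deg[b], deg[a])
                    key = (ends, deg[c])
                    wedges[key] = wedges.get(key, 0) + 1
    return Labeled3kDistribution(triangles=triangles, wedges=wedges)


def clustering_stats(g: nx.Graph) -> ClusteringStats:
    """Mean clustering and the clustering spectrum c-bar(k) for k >= 2."""
    n = g.number_of_nodes()
    if n == 0:
        return ClusteringStats(mean_clustering=0.0, by_degree={})
    local = nx.clustering(g)  # 0.0 for degree < 2
    mean = sum(local.values()) / n
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for u, k in g.degree():
        if k >= 2:
            sums[k] = sums.get(k, 0.0) + local[u]
            counts[k] = counts.get(k, 0) + 1
    by_degree = {k: sums[k] / counts[k] for k in sums}
    return ClusteringStats(mean_clustering=mean, by_degree=by_degree)


def dk_statistics(g: nx.Graph) -> DkStatistics:
    """Bundle all dk statistics of *g*; the target snapshot for rewiring."""
    return DkStatistics(
        d0=average_degree(g),
        d1=degree_distribution(g),
        d2=joint_degree_distribution(g),
        d3=labeled_3k_distribution(g),
        clustering=clustering_stats(g),
    )


def l1_distance_clustering(
    current: ClusteringStats, target: ClusteringStats, level: float
) -> float:
    """L1 distance between two clustering statistics at level 2.1 or 2.5.

    Level 2.1 compares the scalar means; level 2.5 sums absolute
    differences of c-bar(k) over the union of degrees present in either
    spectrum, with absent values taken as 0.
    """
    if level == 2.1:
        return abs(current.mean_clustering - target.mean_clustering)
    if level == 2.5:
        keys = set(current.by_degree) | set(target.by_degree)
        return sum(
            abs(current.by_degree.get(k, 0.0) - target.by_degree.get(k, 0.0))
            for k in keys
        )
    raise ValueError(f"level must be 2.1 or 2.5, got {level!r}")


def triangles_per_node(g: nx.Graph) -> dict:
    """Number of triangles through each node (each triangle counts once
    per member node).  Convenience used by the rewiring engine and tests."""
    tri = nx.triangles(g)
    return dict(tri)


def local_clustering_from_triangles(k: int, t: int) -> float:
    """Local clustering from degree *k* and triangle count *t* (0 if k < 2)."""
    if k < 2:
        return 0.0
    return t / comb(k, 2)
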
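"""Structural property battery for comparing a network with its null models.

Microscopic: degree distribution, average-neighbour-degree curve
k_nn(k), clustering spectrum c(k), distribution P(m) of common
neighbours over connected pairs, and connected induced subgraph censuses
of sizes 3 and 4.  Mesoscopic: k-core decomposition of nodes and the
k-density (truss) decomposition of edges.  Macroscopic: exact
betweenness averaged per degree class, the shortest-path hop-length
distribution P(l) with the diameter, and spectral summaries (top
adjacency eigenvalues and the Fiedler value of L = D - A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import scipy.sparse.linalg

__all__ = [
    "CountDistribution",
    "SubgraphCensus",
    "PathLengthStats",
    "SpectralSummary",
    "avg_neighbor_degree_curve",
    "common_neighbor_distribution",
    "subgraph_census",
    "k_core_decomposition",
    "k_density_decomposition",
    "betweenness_curve",
    "path_length_distribution",
    "spectral_summary",
    "ks_distance",
]

_DENSE_EIG_LIMIT = 1500


@dataclass(frozen=True)
class CountDistribution:
    """An empirical distribution over integer values."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def normalized(self) -> dict[int, float]:
        t = self.total
        if t == 0:
            return {}
        return {v: c / t for v, c in self.counts.items()}


@dataclass(frozen=True)
class SubgraphCensus:
    """Connected induced subgraph counts and concentrations at one size."""

    size: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def concentrations(self) -> dict[str, float]:
        t = sum(self.counts.values())
        if t == 0:
            return {name: 0.0 for name in self.counts}
        return {name: c / t for name, c in self.counts.items()}


@dataclass(frozen=True)
class PathLengthStats:
    """Hop-length distribution over reachable unordered pairs.

    Disconnected graphs are handled per component and pooled; the
    number of mutually unreachable pairs is reported alongside.
    """

    lengths: CountDistribution
    diameter: int
    unreachable_pairs: int


@dataclass(frozen=True)
class SpectralSummary:
    top_adjacency_eigenvalues: tuple[float, ...]
    fiedler_value: float


def avg_neighbor_degree_curve(g: nx.Graph) -> dict[int, float]:
    """k_nn(k): mean over degree-k nodes of their mean neighbour degree.

    Isolated nodes are excluded (they have no neighbours to average)."""
    curve = nx.average_degree_connectivity(g)
    return {k: v for k, v in curve.items() if k > 0}


def common_neighbor_distribution(g: nx.Graph) -> CountDistribution:
    """P(m): number of common neighbours per *connected* pair (edge)."""
    if g.number_of_edges() == 0:
        raise ValueError("P(m) requires at least one edge")
    adj = {u: set(g.neighbors(u)) for u in g.nodes()}
    counts: dict[int, int] = {}
    for u, v in g.edges():
        m = len(adj[u] & adj[v])
        counts[m] = counts.get(m, 0) + 1
    return CountDistribution(counts=counts)


# connected isomorphism classes, named by the field's conventional terms
SIZE3_CLASSES = ("wedge", "triangle")
SIZE4_CLASSES = ("path", "star", "cycle", "tailed_triangle", "diamond", "complete")

_CANONICAL_4 = {
    "path": [(0, 1), (1, 2), (2, 3)],
    "star": [(0, 1), (0, 2), (0, 3)],
    "cycle": [(0, 1), (1, 2), (2, 3), (3, 0)],
    "tailed_triangle": [(0, 1), (1, 2), (2, 0), (2, 3)],
    "diamond": [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3)],
    "complete": [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
}


def _isoclass_map(size: int) -> dict[int, str]:
    """Map igraph undirected isoclass ids -> class names, derived from
    canonical edge lists so the numbering never has to be hard-coded."""
    if size == 3:
        reps = {"wedge": [(0, 1), (1, 2)], "triangle": [(0, 1), (1, 2), (2, 0)]}
    else:
        reps = _CANONICAL_4
    return {
        ig.Graph(n=size, edges=e).isoclass(): name for name, e in reps.items()
    }


def subgraph_census(g: nx.Graph, size: int) -> SubgraphCensus:
    """Census of connected induced subgraphs on *size* in {3, 4} nodes.

    Counted with igraph's ESU enumeration; concentrations are each
    class's count divided by the total connected-induced count of that
    size.
    """
    if size not in (3, 4):
        raise ValueError("census size must be 3 or 4")
    names = SIZE3_CLASSES if size == 3 else SIZE4_CLASSES
    if g.number_of_nodes() < size:
        return SubgraphCensus(size=size, counts={name: 0 for name in names})
    nodes = list(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    h = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges()]
    )
    motif_counts = h.motifs_randesu(size=size)
    iso = _isoclass_map(size)
    counts = {name: 0 for name in names}
    for class_id, c in enumerate(motif_counts):
        if class_id in iso and not np.isnan(c):
            counts[iso[class_id]] = int(c)
    return SubgraphCensus(size=size, counts=counts)


def k_core_decomposition(g: nx.Graph) -> tuple[dict, CountDistribution]:
    """Coreness k_c per node, plus the distribution P(k_c).

    The k_c-core is the maximal subgraph in which every node has degree
    at least k_c; a node's coreness is the largest k_c admitting it.
    """
    core = nx.core_number(g)
    counts: dict[int, int] = {}
    for kc in core.values():
        counts[kc] = counts.get(kc, 0) + 1
    return core, CountDistribution(counts=counts)


def k_density_decomposition(g: nx.Graph) -> tuple[dict, CountDistribution]:
    """k-density k_d per edge, plus the distribution P(k_d).

    An edge's multiplicity is the number of common neighbours of its
    endpoints (the number of triangles through the edge).  The k_d-core
    is the maximal subgraph whose every edge has within-subgraph
    multiplicity >= k_d - 2; an edge's k-density is the largest k_d
    whose core contains it.  Every edge of a simple graph is in the
    2-core (multiplicity >= 0), so k_d >= 2.
    """
    if g.number_of_edges() == 0:
        raise ValueError("k-density requires at least one edge")
    adj = {u: set(g.neighbors(u)) for u in g.nodes()}
    mult = {}
    key = lambda u, v: (u, v) if str(u) <= str(v) else (v, u)
    for u, v in g.edges():
        mult[key(u, v)] = len(adj[u] & adj[v])
    kd: dict = {}
    k = 3
    while mult:
        # peel edges that cannot sit in the k-core (multiplicity < k - 2)
        queue = [e for e, m in mult.items() if m < k - 2]
        while queue:
            u, v = queue.pop()
            e = key(u, v)
            if e not in mult:
                continue
            del mult[e]
            kd[e] = k - 1
            for w in adj[u] & adj[v]:
                for other in (key(u, w), key(v, w)):
                    if other in mult:
                        mult[other] -= 1
                        if mult[other] < k - 2:
                            queue.append(other)
            adj[u].discard(v)
            adj[v].discard(u)
        k += 1
    counts: dict[int, int] = {}
    for v in kd.values():
        counts[v] = counts.get(v, 0) + 1
    return kd, CountDistribution(counts=counts)


def betweenness_curve(g: nx.Graph) -> dict[int, float]:
    """b(k): exact shortest-path betweenness averaged per degree class.

    Raw (unnormalized) values over unordered pairs, endpoints excluded;
    only degree-class averages and curve shapes are compared across an
    ensemble, so no (N-1)(N-2) normalization is applied.
    """
    bc = nx.betweenness_centrality(g, normalized=False)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for u, k in g.degree():
        sums[k] = sums.get(k, 0.0) + bc[u]
        counts[k] = counts.get(k, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def path_length_distribution(g: nx.Graph) -> PathLengthStats:
    """P(l): hop lengths of shortest paths over all reachable pairs.

    BFS from every node; pairs are unordered.  Components are pooled
    and the count of unreachable pairs is reported.
    """
    n = g.number_of_nodes()
    counts: dict[int, int] = {}
    for u in g.nodes():
        for _, l in nx.single_source_shortest_path_length(g, u).items():
            if l > 0:
                counts[l] = counts.get(l, 0) + 1
    counts = {l: c // 2 for l, c in counts.items()}  # each pair seen twice
    reachable_pairs = sum(counts.values())
    total_pairs = n * (n - 1) // 2
    diameter = max(counts) if counts else 0
    return PathLengthStats(
        lengths=CountDistribution(counts=counts),
        diameter=diameter,
        unreachable_pairs=total_pairs - reachable_pairs,
    )


def spectral_summary(g: nx.Graph, n_eigs: int = 10) -> SpectralSummary:
    """Top adjacency eigenvalues and the Fiedler value of L = D - A.

    The Fiedler value is the second-smallest Laplacian eigenvalue
    (algebraic connectivity); it is 0 exactly when the graph is
    disconnected.  Dense solvers are used up to ~1500 nodes, Lanczos
    (shift-inverted for the Laplacian end) beyond.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("spectral summary requires at least two nodes")
    n_eigs = min(n_eigs, n)
    if n <= _DENSE_EIG_LIMIT:
        a = nx.to_numpy_array(g)
        adj_eigs = np.sort(np.linalg.eigvalsh(a))[::-1][:n_eigs]
        lap = np.diag(a.sum(axis=1)) - a
        lap_eigs = np.sort(np.linalg.eigvalsh(lap))
        fiedler = float(lap_eigs[1])
    else:
        a = nx.to_scipy_sparse_array(g, format="csr", dtype=float)
        adj_eigs = scipy.sparse.linalg.eigsh(
            a, k=n_eigs, which="LA", return_eigenvectors=False
        )
        adj_eigs = np.sort(adj_eigs)[::-1]
        lap = scipy.sparse.csgraph.laplacian(a).tocsc()
        lo = scipy.sparse.linalg.eigsh(
            lap, k=2, sigma=-1e-2, which="LM", return_eigenvectors=False
        )
        fiedler = float(np.sort(lo)[1])
    fiedler = max(fiedler, 0.0) if abs(fiedler) < 1e-10 else fiedler
    return SpectralSummary(
        top_adjacency_eigenvalues=tuple(float(x) for x in adj_eigs),
        fiedler_value=fiedler,
    )


def ks_distance(p: CountDistribution, q: CountDistribution) -> float:
    """Kolmogorov-Smirnov distance between two integer-valued empirical
    distributions: the max absolute CDF difference over the union support."""
    if p.total == 0 or q.total == 0:
        raise ValueError("KS distance requires non-empty distributions")
    support = sorted(set(p.counts) | set(q.counts))
    pn, qn = p.normalized, q.normalized
    cp = cq = 0.0
    d = 0.0
    for v in support:
        cp += pn.get(v, 0.0)
        cq += qn.get(v, 0.0)
        d = max(d, abs(cp - cq))
    return d
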
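"""Independent brute-force oracles for cross-checking the implementation.

Everything here iterates directly over node subsets, pairs, or paths,
deliberately avoiding the code paths (and where possible the library
calls) used by the package itself.  Intended for graphs with at most a
few dozen nodes.
"""

from collections import deque
from itertools import combinations
from math import inf

import networkx as nx


def census_by_subsets(g: nx.Graph, size: int) -> dict[str, int]:
    """Classify every connected induced subgraph on `size` nodes by its
    (edge count, sorted induced degree sequence) signature."""
    sig3 = {(2, (1, 1, 2)): "wedge", (3, (2, 2, 2)): "triangle"}
    sig4 = {
        (3, (1, 1, 2, 2)): "path",
        (3, (1, 1, 1, 3)): "star",
        (4, (2, 2, 2, 2)): "cycle",
        (4, (1, 2, 2, 3)): "tailed_triangle",
        (5, (2, 2, 3, 3)): "diamond",
        (6, (3, 3, 3, 3)): "complete",
    }
    table = sig3 if size == 3 else sig4
    counts = {name: 0 for name in table.values()}
    for subset in combinations(g.nodes(), size):
        sub = g.subgraph(subset)
        if nx.is_connected(sub):
            sig = (sub.number_of_edges(), tuple(sorted(d for _, d in sub.degree())))
            counts[table[sig]] += 1
    return counts


def coreness_by_definition(g: nx.Graph) -> dict:
    """Coreness via the maximal-subgraph definition, one k at a time."""
    core = {u: 0 for u in g.nodes()}
    k = 1
    while True:
        sub = g.copy()
        changed = True
        while changed:
            drop = [u for u in sub.nodes() if sub.degree(u) < k]
            changed = bool(drop)
            sub.remove_nodes_from(drop)
        if sub.number_of_nodes() == 0:
            return core
        for u in sub.nodes():
            core[u] = k
        k += 1


def kdensity_by_definition(g: nx.Graph) -> dict:
    """Edge k-density via the maximal-subgraph definition per k."""
    def canon(u, v):
        return (u, v) if str(u) <= str(v) else (v, u)

    kd = {canon(u, v): 2 for u, v in g.edges()}
    k = 3
    while True:
        sub = g.copy()
        changed = True
        while changed:
            drop = [
                (u, v)
                for u, v in sub.edges()
                if len(set(sub.neighbors(u)) & set(sub.neighbors(v))) < k - 2
            ]
            changed = bool(drop)
            sub.remove_edges_from(drop)
        if sub.number_of_edges() == 0:
            return kd
        for u, v in sub.edges():
            kd[canon(u, v)] = k
        k += 1


def common_neighbor_counts(g: nx.Graph) -> dict[int, int]:
    counts: dict[int, int] = {}
    for u, v in g.edges():
        m = sum(1 for w in g.nodes() if w in g[u] and w in g[v])
        counts[m] = counts.get(m, 0) + 1
    return counts


def bfs_distances(g: nx.Graph, source) -> dict:
    """Hand-rolled BFS, independent of networkx shortest-path code."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def path_length_counts(g: nx.Graph) -> tuple[dict[int, int], int, int]:
    counts: dict[int, int] = {}
    unreachable = 0
    nodes = list(g.nodes())
    for i, u in enumerate(nodes):
        dist = bfs_distances(g, u)
        for v in nodes[i + 1:]:
            if v in dist:
                counts[dist[v]] = counts.get(dist[v], 0) + 1
            else:
                unreachable += 1
    diameter = max(counts) if counts else 0
    return counts, diameter, unreachable


def betweenness_by_path_enumeration(g: nx.Graph) -> dict:
    """Raw betweenness over unordered pairs by enumerating all shortest
    paths explicitly (feasible for tiny graphs only)."""
    bc = {u: 0.0 for u in g.nodes()}
    nodes = list(g.nodes())
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            shortest = inf
            paths = []
            for p in nx.all_simple_paths(g, s, t):
                if len(p) < shortest:
                    shortest = len(p)
                    paths = [p]
                elif len(p) == shortest:
                    paths.append(p)
            for p in paths:
                for w in p[1:-1]:
                    bc[w] += 1.0 / len(paths)
    return bc


def graphs_with_degree_sequence(n: int, degseq: tuple[int, ...]):
    """All labelled simple graphs on nodes 0..n-1 with the given degree
    sequence (degseq[i] = degree of node i), as frozensets of edges."""
    pairs = list(combinations(range(n), 2))
    m = sum(degseq) // 2
    found = []
    for edges in combinations(pairs, m):
        deg = [0] * n
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        if tuple(deg) == degseq:
            found.append(frozenset(frozenset(e) for e in edges))
    return found
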
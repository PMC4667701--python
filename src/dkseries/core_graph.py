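"""Graph data model, edge-list I/O and synthetic graph generation.

Graphs are plain :class:`networkx.Graph` objects restricted to *simple*
undirected graphs: no self-loops, no parallel edges, opaque (hashable)
node labels.  Every public function in this package validates or
preserves that restriction.

The edge-list text format is one edge per line, two whitespace-separated
node labels; ``#`` starts a comment.  Isolated nodes cannot be expressed
as edges, so a header comment of the form ``#nodes: a b c`` may declare
the full node set (degree-0 nodes matter for the 0k/1k statistics, which
are normalized by N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "GeneratorSpec",
    "validate_simple",
    "read_edge_list",
    "write_edge_list",
    "figure1_graph",
    "generate_synthetic",
]

_NODES_HEADER = "#nodes:"


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class GraphValidationError(ValueError):
    """Raised when an input graph is not a simple undirected graph."""


def validate_simple(g: nx.Graph) -> nx.Graph:
    """Validate that *g* is a simple undirected graph; return it unchanged.

    Raises
    ------
    GraphValidationError
        If *g* is directed, is a multigraph, or contains a self-loop.
    """
    if g.is_directed():
        raise GraphValidationError("graph must be undirected")
    if g.is_multigraph():
        raise GraphValidationError("graph must not be a multigraph")
    loops = list(nx.nodes_with_selfloops(g))
    if loops:
        raise GraphValidationError(f"graph has self-loops at nodes {loops[:5]}")
    return g


def read_edge_list(path) -> nx.Graph:
    """Read a simple undirected graph from an edge-list text file.

    Duplicate lines (including reversed duplicates) collapse to a single
    edge.  A ``#nodes:`` header declares isolated nodes.  Extra tokens
    after the first two on a line are ignored.

    Raises
    ------
    EdgeListParseError
        On a non-comment line with fewer than two tokens, or a self-loop
        line; the message names the offending 1-based line number.
    """
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith(_NODES_HEADER):
                    g.add_nodes_from(line[len(_NODES_HEADER):].split())
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected two node labels, got {line!r}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: self-loop {u!r}-{v!r} is not allowed"
                )
            g.add_edge(u, v)
    return validate_simple(g)


def write_edge_list(g: nx.Graph, path) -> None:
    """Write *g* as a deterministic edge-list text file.

    Endpoints are sorted within each line and lines are sorted, so equal
    graphs produce byte-identical files.  Isolated nodes are recorded in
    a ``#nodes:`` header; the output round-trips through
    :func:`read_edge_list` to a graph equal to *g* up to ``str()`` of the
    labels.
    """
    validate_simple(g)
    lines = sorted(
        tuple(sorted((str(u), str(v)))) for u, v in g.edges()
    )
    isolated = sorted(str(u) for u in g.nodes() if g.degree(u) == 0)
    with open(path, "w", encoding="utf-8") as fh:
        if isolated:
            fh.write(_NODES_HEADER + " " + " ".join(isolated) + "\n")
        for u, v in lines:
            fh.write(f"{u} {v}\n")


def figure1_graph() -> nx.Graph:
    """The four-node worked example: a triangle a-b-c with a pendant d on c.

    Degrees are 2, 2, 3, 1; the graph has one triangle (node degrees
    2, 2, 3) and two wedges (node degrees 2, 3, 1).  It is the smallest
    graph on which every level of the dk-hierarchy is non-trivial, and
    it serves as the exact fixture throughout the test-suite.
    """
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
    return g


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic heavy-tailed test-graph generator.

    Attributes
    ----------
    n_nodes:
        Number of nodes (>= 4).
    degree_exponent:
        Target exponent gamma of the sampled degree sequence,
        P(k) ~ k^(-gamma) on k = 1..max_degree.  Real networks typically
        show gamma in (2, 3).
    seed:
        RNG seed; the same spec always yields the same graph.
    max_degree_cap:
        Optional hard cap on sampled degrees (default: n_nodes - 1).
    """

    n_nodes: int
    degree_exponent: float = 2.5
    seed: int = 0
    max_degree_cap: int | None = None


class GenerationError(ValueError):
    """Raised when a GeneratorSpec cannot produce a usable graph."""


def _sample_degree_sequence(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    kmax = spec.max_degree_cap if spec.max_degree_cap is not None else spec.n_nodes - 1
    kmax = max(1, min(kmax, spec.n_nodes - 1))
    ks = np.arange(1, kmax + 1, dtype=float)
    weights = ks ** (-spec.degree_exponent)
    total = weights.sum()
    if not math.isfinite(total) or total <= 0:
        raise GenerationError(
            f"degree exponent {spec.degree_exponent} yields no valid degree weights"
        )
    degrees = rng.choice(np.arange(1, kmax + 1), size=spec.n_nodes, p=weights / total)
    if degrees.sum() % 2 == 1:
        # decrement one degree->even sum; prefer an entry > 1 to keep min degree 1
        candidates = np.flatnonzero(degrees > 1)
        idx = candidates[0] if len(candidates) else 0
        degrees[idx] -= 1
    if degrees.sum() == 0:
        raise GenerationError("sampled degree sequence is all zeros")
    return degrees.astype(int)


def generate_synthetic(spec: GeneratorSpec) -> nx.Graph:
    """Generate a configuration-model-style graph with a power-law-ish
    degree sequence, simplified to a simple graph.

    Stubs are paired as in the configuration model, then self-loops and
    parallel edges are removed (simplification) rather than restarting
    the pairing, so the realized degrees are bounded above by the
    sampled ones.  The pre-simplification target mean degree is stored
    in ``g.graph["target_mean_degree"]`` so callers can check how much
    the simplification cost.

    Node labels are strings ``"v0" .. "v{n-1}"``.
    """
    if spec.n_nodes < 4:
        raise GenerationError("n_nodes must be >= 4")
    rng = np.random.default_rng(spec.seed)
    degrees = _sample_degree_sequence(spec, rng)
    target_mean = float(degrees.sum()) / spec.n_nodes
    multi = nx.configuration_model(
        degrees.tolist(), seed=int(rng.integers(2**31 - 1))
    )
    g = nx.Graph(multi)  # collapses parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes()})
    g.graph["target_mean_degree"] = target_mean
    return validate_simple(g)
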
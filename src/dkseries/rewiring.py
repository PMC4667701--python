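"""dk-preserving randomization and clustering-targeted annealed rewiring.

Levels 0, 1 and 2 randomize a graph by Markov-chain edge swaps that
preserve the corresponding dk-statistic *exactly* at every step:

* level 0 — delete a uniform edge, connect a uniform vacant node pair
  (preserves N and M, hence the average degree);
* level 1 — the classical double edge swap (u1,v1),(u2,v2) ->
  (u1,v2),(u2,v1), preserving every node's degree;
* level 2 — the *restricted* double edge swap, in which the two swapped
  edges are required to have an endpoint of equal degree, which
  preserves the joint degree matrix and is ergodic over 2k-graphs.

Levels 2.1 and 2.5 run the restricted swap inside a simulated-annealing
loop: each proposal is accepted with probability min(1, exp(-beta*dH)),
where H is the L1 distance between the current and target clustering
(the scalar mean for 2.1, the degree-dependent spectrum for 2.5), and
beta grows geometrically from stage to stage.  The joint degree matrix
is preserved throughout regardless of convergence.

Proposals that would create a self-loop or a parallel edge (or that are
no-ops) are rejected and count as chain steps; the graph is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .core_graph import validate_simple
from .dk_stats import ClusteringStats, clustering_stats

__all__ = [
    "RewiringConfig",
    "ChainLog",
    "acceptance_probability",
    "swap_0k",
    "swap_1k",
    "swap_2k_restricted",
    "randomize",
    "target_rewire",
    "sample_dk_random",
]

_RANDOMIZING_LEVELS = (0, 1, 2)
_TARGETING_LEVELS = (2.1, 2.5)


@dataclass(frozen=True)
class RewiringConfig:
    """Parameters of a rewiring chain.

    Attributes
    ----------
    level:
        0, 1 or 2 for dk-preserving randomization; 2.1 or 2.5 for
        2k-preserving clustering-targeting annealing.
    swaps_per_edge:
        Attempted swaps per edge; a randomizing chain runs
        ``round(swaps_per_edge * M)`` attempts in total, an annealing
        chain that many attempts *per stage*.  The swap chain's mixing
        time is of the order of M swaps, so the default of 10 sweeps is
        a comfortable margin.
    beta_initial, beta_growth:
        Inverse temperature of the first annealing stage and its
        multiplicative growth per stage (ignored for level <= 2).
    tolerance:
        Stop the annealing once H <= tolerance.  ``None`` selects
        ``1e-4 * s`` where s is the size of the target's support
        (1 for level 2.1, the number of degree classes for 2.5).
    max_stages:
        Hard cap on annealing stages.
    patience:
        Stop early if the best H seen has not improved for this many
        consecutive stages (the chain is stuck in a local minimum or
        frozen); the best-H graph is returned either way.
    seed:
        Master RNG seed for the chain.
    """

    level: float = 1
    swaps_per_edge: float = 10.0
    beta_initial: float = 10.0
    beta_growth: float = 1.5
    tolerance: float | None = None
    max_stages: int = 200
    patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.level not in _RANDOMIZING_LEVELS and self.level not in _TARGETING_LEVELS:
            raise ValueError(f"level must be one of 0, 1, 2, 2.1, 2.5; got {self.level!r}")
        if self.swaps_per_edge < 0:
            raise ValueError("swaps_per_edge must be non-negative")
        if self.tolerance is not None and self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.beta_initial <= 0 or self.beta_growth < 1:
            raise ValueError("beta_initial must be > 0 and beta_growth >= 1")
        if self.max_stages < 1 or self.patience < 1:
            raise ValueError("max_stages and patience must be positive")


@dataclass
class ChainLog:
    """Bookkeeping of one rewiring chain.

    ``H_trace`` holds (attempt index, H) pairs recorded at stage
    boundaries; ``final_H`` is the H of the returned graph (0 for plain
    randomizing chains, whose statistic is preserved exactly).
    ``converged`` is False when an annealing chain exhausted its stage
    budget or stalled before reaching the tolerance.
    """

    attempted: int = 0
    accepted: int = 0
    final_H: float = 0.0
    H_trace: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = True


def acceptance_probability(delta_H: float, beta: float) -> float:
    """Metropolis acceptance probability min(1, exp(-beta * delta_H))."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if delta_H <= 0:
        return 1.0
    return math.exp(-beta * delta_H)


class _RewireState:
    """Mutable flat representation of a simple graph for fast rewiring.

    Nodes are dense ints 0..N-1 (``labels`` maps back); edges live in
    parallel endpoint arrays so a uniform edge (or edge endpoint) is an
    O(1) draw.  For restricted (2k) swaps, every edge endpoint is a
    "slot" (id = 2*edge + side) filed in a bucket keyed by the
    endpoint's degree, so a degree-matched partner edge is also an O(1)
    draw; bucket membership is patched in O(1) on each swap.
    """

    def __init__(self, g: nx.Graph, with_buckets: bool = False):
        self.labels = list(g.nodes())
        index = {u: i for i, u in enumerate(self.labels)}
        self.n = len(self.labels)
        self.adj: list[set[int]] = [set() for _ in range(self.n)]
        self.eu: list[int] = []
        self.ev: list[int] = []
        for u, v in g.edges():
            iu, iv = index[u], index[v]
            self.adj[iu].add(iv)
            self.adj[iv].add(iu)
            self.eu.append(iu)
            self.ev.append(iv)
        self.m = len(self.eu)
        self.deg = [len(a) for a in self.adj]  # fixed under 1k/2k chains
        self.bucket: dict[int, list[int]] = {}
        self.slot_pos: list[int] = []
        if with_buckets:
            self._build_buckets()

    def _build_buckets(self) -> None:
        self.slot_pos = [0] * (2 * self.m)
        self.bucket = {}
        for e in range(self.m):
            for side, node in ((0, self.eu[e]), (1, self.ev[e])):
                b = self.bucket.setdefault(self.deg[node], [])
                self.slot_pos[2 * e + side] = len(b)
                b.append(2 * e + side)

    def endpoint(self, e: int, side: int) -> int:
        return self.eu[e] if side == 0 else self.ev[e]

    def _set_endpoint(self, e: int, side: int, node: int) -> None:
        if side == 0:
            self.eu[e] = node
        else:
            self.ev[e] = node

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        lab = self.labels
        g.add_edges_from((lab[self.eu[e]], lab[self.ev[e]]) for e in range(self.m))
        return g

    # -- level 0 ----------------------------------------------------------
    def step_0k(self, rng: np.random.Generator) -> bool:
        if self.m == 0 or self.n < 2:
            return False
        e = int(rng.integers(self.m))
        i = int(rng.integers(self.n))
        j = int(rng.integers(self.n - 1))
        if j >= i:
            j += 1
        if j in self.adj[i]:
            return False
        u, v = self.eu[e], self.ev[e]
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[i].add(j)
        self.adj[j].add(i)
        self.eu[e], self.ev[e] = i, j
        self.deg[u] -= 1
        self.deg[v] -= 1
        self.deg[i] += 1
        self.deg[j] += 1
        return True

    # -- level 1 ----------------------------------------------------------
    def step_1k(self, rng: np.random.Generator) -> bool:
        if self.m < 2:
            return False
        e1 = int(rng.integers(self.m))
        e2 = int(rng.integers(self.m - 1))
        if e2 >= e1:
            e2 += 1
        u1, v1 = self.eu[e1], self.ev[e1]
        u2, v2 = self.eu[e2], self.ev[e2]
        if rng.random() < 0.5:
            u2, v2 = v2, u2
        if u1 == v2 or u2 == v1:
            return False
        if v2 in self.adj[u1] or v1 in self.adj[u2]:
            return False
        a = self.adj
        a[u1].discard(v1); a[v1].discard(u1)
        a[u2].discard(v2); a[v2].discard(u2)
        a[u1].add(v2); a[v2].add(u1)
        a[u2].add(v1); a[v1].add(u2)
        self.eu[e1], self.ev[e1] = u1, v2
        self.eu[e2], self.ev[e2] = u2, v1
        return True

    # -- level 2 ----------------------------------------------------------
    def propose_2k(self, rng: np.random.Generator):
        """Draw a restricted-swap proposal; None if invalid/no-op."""
        if self.m < 2:
            return None
        s1 = int(rng.integers(2 * self.m))
        e1, side1 = s1 >> 1, s1 & 1
        u1 = self.endpoint(e1, side1)
        b = self.bucket[self.deg[u1]]
        s2 = b[int(rng.integers(len(b)))]
        e2, side2 = s2 >> 1, s2 & 1
        if e1 == e2:
            return None
        u2 = self.endpoint(e2, side2)
        v1 = self.endpoint(e1, 1 - side1)
        v2 = self.endpoint(e2, 1 - side2)
        if u1 == u2 or v1 == v2 or u1 == v2 or u2 == v1:
            return None
        if v2 in self.adj[u1] or v1 in self.adj[u2]:
            return None
        return e1, side1, e2, side2

    def apply_2k(self, e1: int, side1: int, e2: int, side2: int) -> None:
        """Perform the restricted swap; applying the same arguments again
        undoes it (the operation is an involution given fixed anchors)."""
        u1 = self.endpoint(e1, side1)
        v1 = self.endpoint(e1, 1 - side1)
        u2 = self.endpoint(e2, side2)
        v2 = self.endpoint(e2, 1 - side2)
        a = self.adj
        a[u1].discard(v1); a[v1].discard(u1)
        a[u2].discard(v2); a[v2].discard(u2)
        a[u1].add(v2); a[v2].add(u1)
        a[u2].add(v1); a[v1].add(u2)
        self._set_endpoint(e1, 1 - side1, v2)
        self._set_endpoint(e2, 1 - side2, v1)
        # patch slot buckets: the non-anchor endpoints traded edges
        sa = 2 * e1 + (1 - side1)  # now occupied by v2
        sb = 2 * e2 + (1 - side2)  # now occupied by v1
        pa, pb = self.slot_pos[sa], self.slot_pos[sb]
        self.bucket[self.deg[v1]][pa] = sb
        self.bucket[self.deg[v2]][pb] = sa
        self.slot_pos[sa], self.slot_pos[sb] = pb, pa

    def step_2k(self, rng: np.random.Generator) -> bool:
        prop = self.propose_2k(rng)
        if prop is None:
            return False
        self.apply_2k(*prop)
        return True


def _one_shot(g: nx.Graph, rng: np.random.Generator, level: int) -> bool:
    validate_simple(g)
    state = _RewireState(g, with_buckets=(level == 2))
    step = {0: state.step_0k, 1: state.step_1k, 2: state.step_2k}[level]
    accepted = step(rng)
    if accepted:
        new = state.to_graph()
        g.clear_edges()
        g.add_edges_from(new.edges())
    return accepted


def swap_0k(g: nx.Graph, rng: np.random.Generator) -> bool:
    """Attempt one 0k swap on *g* in place; return whether it was accepted."""
    return _one_shot(g, rng, 0)


def swap_1k(g: nx.Graph, rng: np.random.Generator) -> bool:
    """Attempt one double edge swap on *g* in place."""
    return _one_shot(g, rng, 1)


def swap_2k_restricted(g: nx.Graph, rng: np.random.Generator) -> bool:
    """Attempt one restricted (joint-degree-preserving) swap on *g* in place."""
    return _one_shot(g, rng, 2)


def randomize(g: nx.Graph, cfg: RewiringConfig) -> tuple[nx.Graph, ChainLog]:
    """dk-randomize *g* at level 0, 1 or 2.

    Runs ``round(swaps_per_edge * M)`` attempted swaps on a copy of *g*;
    the level's dk-statistic of the output equals the input's exactly.
    """
    if cfg.level not in _RANDOMIZING_LEVELS:
        raise ValueError(f"randomize requires level in {_RANDOMIZING_LEVELS}")
    validate_simple(g)
    rng = np.random.default_rng(cfg.seed)
    state = _RewireState(g, with_buckets=(cfg.level == 2))
    step = {0: state.step_0k, 1: state.step_1k, 2: state.step_2k}[cfg.level]
    attempts = int(round(cfg.swaps_per_edge * state.m))
    log = ChainLog(attempted=attempts)
    for _ in range(attempts):
        if step(rng):
            log.accepted += 1
    return state.to_graph(), log


class _TargetingState(_RewireState):
    """Restricted-swap state with incremental clustering/H bookkeeping.

    Per-node triangle counts are integers maintained incrementally from
    the <= 4 touched nodes and their common neighbours, so they never
    drift; the derived floating sums are re-synced from the triangle
    counts at every stage boundary.
    """

    def __init__(self, g: nx.Graph, target: ClusteringStats, level: float):
        super().__init__(g, with_buckets=True)
        self.level = level
        self.tri = [0] * self.n
        tri_by_label = nx.triangles(g)
        for i, lab in enumerate(self.labels):
            self.tri[i] = tri_by_label[lab]
        self.inv_pairs = [
            (2.0 / (k * (k - 1)) if k >= 2 else 0.0) for k in self.deg
        ]
        self.target_mean = target.mean_clustering
        self.target_spec = dict(target.by_degree)
        # degree-class counts (degrees are invariant under 2k swaps)
        self.class_count: dict[int, int] = {}
        for k in self.deg:
            if k >= 2:
                self.class_count[k] = self.class_count.get(k, 0) + 1
        self.support = sorted(set(self.class_count) | set(self.target_spec))
        self.csum = 0.0
        self.S: dict[int, float] = {}
        self.term: dict[int, float] = {}
        self.H = 0.0
        self.resync()

    def resync(self) -> None:
        """Recompute floating sums and H exactly from triangle counts."""
        self.csum = 0.0
        self.S = {k: 0.0 for k in self.class_count}
        for i in range(self.n):
            c = self.tri[i] * self.inv_pairs[i]
            self.csum += c
            k = self.deg[i]
            if k >= 2:
                self.S[k] += c
        if self.level == 2.1:
            self.H = abs(self.csum / self.n - self.target_mean)
        else:
            self.term = {}
            for k in self.support:
                cur = self.S[k] / self.class_count[k] if k in self.class_count else 0.0
                self.term[k] = abs(cur - self.target_spec.get(k, 0.0))
            self.H = sum(self.term.values())

    def current_clustering(self) -> ClusteringStats:
        by_degree = {
            k: self.S[k] / self.class_count[k] for k in self.class_count
        }
        return ClusteringStats(
            mean_clustering=self.csum / self.n, by_degree=by_degree
        )

    def _tri_delta_remove(self, u: int, v: int, delta: dict[int, int]) -> None:
        common = self.adj[u] & self.adj[v]
        if common:
            c = len(common)
            delta[u] = delta.get(u, 0) - c
            delta[v] = delta.get(v, 0) - c
            for w in common:
                delta[w] = delta.get(w, 0) - 1
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def _tri_delta_add(self, u: int, v: int, delta: dict[int, int]) -> None:
        common = self.adj[u] & self.adj[v]
        if common:
            c = len(common)
            delta[u] = delta.get(u, 0) + c
            delta[v] = delta.get(v, 0) + c
            for w in common:
                delta[w] = delta.get(w, 0) + 1
        self.adj[u].add(v)
        self.adj[v].add(u)

    def apply_2k(self, e1: int, side1: int, e2: int, side2: int) -> None:
        u1 = self.endpoint(e1, side1)
        v1 = self.endpoint(e1, 1 - side1)
        u2 = self.endpoint(e2, side2)
        v2 = self.endpoint(e2, 1 - side2)
        delta: dict[int, int] = {}
        self._tri_delta_remove(u1, v1, delta)
        self._tri_delta_remove(u2, v2, delta)
        self._tri_delta_add(u1, v2, delta)
        self._tri_delta_add(u2, v1, delta)
        self._set_endpoint(e1, 1 - side1, v2)
        self._set_endpoint(e2, 1 - side2, v1)
        sa = 2 * e1 + (1 - side1)
        sb = 2 * e2 + (1 - side2)
        pa, pb = self.slot_pos[sa], self.slot_pos[sb]
        self.bucket[self.deg[v1]][pa] = sb
        self.bucket[self.deg[v2]][pb] = sa
        self.slot_pos[sa], self.slot_pos[sb] = pb, pa
        # propagate triangle deltas into clustering sums and H
        if self.level == 2.1:
            for node, dt in delta.items():
                if dt:
                    self.tri[node] += dt
                    self.csum += dt * self.inv_pairs[node]
            self.H = abs(self.csum / self.n - self.target_mean)
        else:
            dirty = set()
            for node, dt in delta.items():
                if dt:
                    self.tri[node] += dt
                    dc = dt * self.inv_pairs[node]
                    self.csum += dc
                    k = self.deg[node]
                    if k >= 2:
                        self.S[k] += dc
                        dirty.add(k)
            for k in dirty:
                self.H -= self.term[k]
                new = abs(self.S[k] / self.class_count[k] - self.target_spec.get(k, 0.0))
                self.term[k] = new
                self.H += new

    def annealing_step(self, beta: float, rng: np.random.Generator) -> bool:
        prop = self.propose_2k(rng)
        if prop is None:
            return False
        h_before = self.H
        self.apply_2k(*prop)
        d_h = self.H - h_before
        if d_h <= 0 or rng.random() < math.exp(-beta * d_h):
            return True
        self.apply_2k(*prop)  # involution: undo
        return False


def _default_tolerance(level: float, target: ClusteringStats) -> float:
    support = 1 if level == 2.1 else max(1, len(target.by_degree))
    return 1e-4 * support


def target_rewire(
    g2k: nx.Graph, target: ClusteringStats, cfg: RewiringConfig
) -> tuple[nx.Graph, ChainLog]:
    """2k-preserving rewiring annealed toward a clustering target.

    *g2k* is typically a level-2 randomization of the source network.
    Restricted-swap proposals are accepted with probability
    min(1, exp(-beta * dH)); beta grows by ``cfg.beta_growth`` each
    stage of ``round(swaps_per_edge * M)`` attempts.  The chain stops
    when H <= tolerance, when the stage budget is exhausted, or when the
    best H has plateaued for ``cfg.patience`` stages; the best-H graph
    seen is returned, and ``ChainLog.converged`` records whether the
    tolerance was reached.  The joint degree matrix of the output equals
    the input's exactly in every case.
    """
    if cfg.level not in _TARGETING_LEVELS:
        raise ValueError(f"target_rewire requires level in {_TARGETING_LEVELS}")
    validate_simple(g2k)
    tol = cfg.tolerance if cfg.tolerance is not None else _default_tolerance(cfg.level, target)
    rng = np.random.default_rng(cfg.seed)
    state = _TargetingState(g2k, target, cfg.level)
    log = ChainLog()
    log.H_trace.append((0, state.H))
    best_h = state.H
    best_edges = (list(state.eu), list(state.ev))
    if state.H <= tol:
        log.final_H = state.H
        return state.to_graph(), log

    stage_attempts = max(1, int(round(cfg.swaps_per_edge * state.m)))
    beta = cfg.beta_initial
    stages_since_improvement = 0
    done = False
    for _ in range(cfg.max_stages):
        stage_accepted = 0
        improved = False
        for _ in range(stage_attempts):
            log.attempted += 1
            if state.annealing_step(beta, rng):
                log.accepted += 1
                stage_accepted += 1
                if state.H < best_h - 1e-15:
                    best_h = state.H
                    best_edges = (list(state.eu), list(state.ev))
                    improved = True
                    if best_h <= tol:
                        done = True
                        break
        state.resync()  # shed float drift at stage boundaries
        log.H_trace.append((log.attempted, state.H))
        if done:
            break
        stages_since_improvement = 0 if improved else stages_since_improvement + 1
        if stages_since_improvement >= cfg.patience:
            break
        if stage_accepted == 0 and beta > cfg.beta_initial:
            break  # chain frozen at high beta; no move will ever be accepted
        beta *= cfg.beta_growth

    out = nx.Graph()
    out.add_nodes_from(state.labels)
    lab = state.labels
    eu, ev = best_edges
    out.add_edges_from((lab[eu[e]], lab[ev[e]]) for e in range(state.m))
    log.final_H = best_h
    log.converged = best_h <= tol
    log.H_trace.append((log.attempted, best_h))
    return out, log


def sample_dk_random(
    g: nx.Graph,
    level: float,
    n_samples: int,
    cfg: RewiringConfig | None = None,
) -> tuple[list[nx.Graph], list[ChainLog]]:
    """Draw *n_samples* dk-random graphs with *g*'s level-d statistic.

    For levels 0/1/2 each sample is an independent :func:`randomize` run
    with a seed derived from ``cfg.seed``; for 2.1/2.5 each sample is a
    fresh level-2 randomization followed by :func:`target_rewire` toward
    *g*'s own clustering statistics.  Per-sample chain logs (with
    convergence flags) are returned alongside the graphs.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = cfg if cfg is not None else RewiringConfig(level=level)
    cfg = replace(cfg, level=level)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * n_samples) % (2**31)
    graphs: list[nx.Graph] = []
    logs: list[ChainLog] = []
    if level in _RANDOMIZING_LEVELS:
        for i in range(n_samples):
            gi, li = randomize(g, replace(cfg, seed=int(seeds[2 * i])))
            graphs.append(gi)
            logs.append(li)
        return graphs, logs
    if level not in _TARGETING_LEVELS:
        raise ValueError(f"level must be one of 0, 1, 2, 2.1, 2.5; got {level!r}")
    target = clustering_stats(g)
    cfg2 = replace(cfg, level=2)
    for i in range(n_samples):
        g2, _ = randomize(g, replace(cfg2, seed=int(seeds[2 * i])))
        gi, li = target_rewire(g2, target, replace(cfg, seed=int(seeds[2 * i + 1])))
        graphs.append(gi)
        logs.append(li)
    return graphs, logs
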
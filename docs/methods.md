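# Methods

## dk-distributions

For a simple undirected graph G with N nodes and M edges, the
dk-distribution at level d tallies G's connected subgraphs of size d
with each node labelled by its degree *in G*.  Level 0 is the scalar
average degree 2M/N, level 1 the degree distribution N(k), level 2 the
joint degree distribution m(k₁, k₂) over unordered degree pairs, and
level 3 the degree-labelled tallies of triangles and wedges.

Two conventions matter and are fixed throughout the package:

* **Size-3 subgraphs are connected *induced* subgraphs.**  A triple of
  nodes inducing three edges is one triangle and nothing else — it is
  not additionally counted as three wedges.  This is the only
  convention under which the four-node worked example has exactly three
  size-3 subgraphs (one triangle, two wedges), and the size-4 census
  uses the same induced convention.
* **Mean clustering averages over all nodes.**  The local clustering of
  a node with degree k ≥ 2 is t/C(k, 2), with t its triangle count;
  nodes of degree < 2 contribute 0 to the mean c̄ and are excluded from
  the spectrum c̄(k).  This makes the identity
  c̄ = Σₖ N(k)·c̄(k)/N hold exactly and testable.

The hierarchy is inclusive: the degree distribution determines the
average degree; the joint degree distribution determines the degree
distribution through its marginal identity
Σ_{k'≠k} m(k, k') + 2·m(k, k) = k·N(k); and the labelled 3-subgraph
tallies determine the clustering spectrum exactly.  All three
identities are asserted as tests on generated graphs.

Fractional levels 2.1 and 2.5 denote the 2k statistic augmented with,
respectively, the scalar c̄ or the spectrum c̄(k).  Distances to a
clustering target use the L1 norm: |c̄ − c̄*| at 2.1 and
Σₖ |c̄(k) − c̄*(k)| at 2.5, summed *unweighted* over the union of
degree supports with absent values read as 0.  Whether the 2.5 sum
should be weighted by class size N(k) is genuinely open; unweighted was
chosen because it treats every degree class of the spectrum as an equal
constraint, and because degrees are invariant under the restricted swap
the choice only rescales per-class contributions, not which moves are
favoured.  Degrees present on only one side contribute their full
value — relevant only for degenerate inputs, since 2k-preserving chains
cannot change the degree support.

## Rewiring chains

All chains are Markov chains over simple graphs in which invalid
proposals (self-loop, parallel edge, or a no-op) are *rejected and
counted as steps*, never resampled or restarted.

* **Level 0** deletes a uniformly chosen edge and connects a uniformly
  chosen vacant node pair, keeping N and M (hence k̄) exact.
* **Level 1** is the classical double edge swap
  (u₁,v₁),(u₂,v₂) → (u₁,v₂),(u₂,v₁) on two distinct uniform edges with
  uniform orientation; it preserves every node's degree and is ergodic
  over graphs with a fixed degree sequence.
* **Level 2** is the restricted double edge swap: the two edges must
  carry an endpoint of equal degree (the anchors), and the non-anchor
  endpoints are exchanged, preserving the joint degree matrix exactly.

The restricted-swap proposal distribution is not dictated by the
definition; this implementation picks edge 1 uniformly, one of its two
endpoints uniformly as the anchor, and edge 2 uniformly among all edge
endpoints of the anchor's degree.  Endpoint "slots" are kept in
per-degree buckets that are patched in O(1) per accepted swap, so a
proposal costs O(1) regardless of graph size.  Degrees never change
along a level-2 chain, so bucket keys are static.

Randomizing chains run `round(swaps_per_edge × M)` attempts
(default `swaps_per_edge = 10`); the swap chain's mixing time is of the
order of M, so ten sweeps is a comfortable margin.  Sampling is the
plain swap chain and therefore only approximately uniform over the
level's graph set; the small-instance uniformity test bounds the
deviation at ±25 % relative on an enumerable case rather than claiming
exact uniformity.

### Clustering-targeted annealing (levels 2.1, 2.5)

Starting from a 2k-randomization of the source network, restricted-swap
proposals are accepted with the Metropolis probability
min(1, e^(−βΔH)), where H is the L1 clustering distance above and β an
inverse temperature.  β starts at `beta_initial = 10` and is multiplied
by `beta_growth = 1.5` after every stage of `round(swaps_per_edge × M)`
attempts, up to `max_stages = 200` stages.  Early in the schedule
β·ΔH ≪ 1 and the chain explores almost freely; once β reaches the
scale of a typical per-move ΔH (roughly the inverse of N times the
per-node clustering granularity) descent begins, and at high β the
chain is effectively greedy.

ΔH is computed incrementally: a swap touches four nodes and their
common neighbours, so per-node triangle counts are updated from at most
four set intersections, never by a full recount.  Triangle counts are
integers and cannot drift; the derived floating-point sums (c̄ and the
per-class sums behind c̄(k)) are re-synchronized from the triangle
counts at every stage boundary.  Equality of the incremental state with
a full recount after thousands of accepted moves is unit-tested.

Stopping rules (own design, since reasonable schedules are
underdetermined): the chain stops when H ≤ `tolerance` (default
10⁻⁴ × target support size), when `max_stages` is exhausted, when the
best H has not improved for `patience = 30` consecutive stages, or when
a stage at high β accepts no move at all (the chain is frozen).  The
*best-H* graph encountered — not the last one — is returned, with a
`converged` flag in the chain log; non-convergence is reported, never
raised.  The joint degree matrix of the output equals the input's
bit-for-bit in every case, converged or not.

Ensembles draw per-sample seeds from a master seed via a seed sequence,
so an ensemble is reproducible as a whole and each sample independent.
For levels 2.1/2.5 each sample is a *fresh* 2k-randomization followed
by its own annealing run toward the source's clustering.

## Property battery

Microscopic: degree distribution, average-neighbour-degree curve
k̄nn(k) (mean over degree-k nodes of their mean neighbour degree),
clustering spectrum, and the distribution P(m) of common neighbours
computed over *connected* pairs, i.e. edges (its total mass is M).
Subgraph censuses count connected induced subgraphs of sizes 3 (wedge,
triangle) and 4 (path, star, cycle, tailed triangle, diamond,
complete); concentrations divide by the total connected-induced count
of the same size.  Counting uses the ESU enumeration from igraph, with
the isomorphism-class numbering derived at run time from canonical edge
lists rather than hard-coded; exhaustive brute-force subset
enumeration serves as the oracle in tests.

Mesoscopic: the k-core decomposition (iterative pruning of nodes of
degree < k) and the k-density decomposition of edges: the k_d-core is
the maximal subgraph whose every edge has within-subgraph multiplicity
(common-neighbour count) ≥ k_d − 2, so the k_d-core coincides with the
k_d-truss and every edge of a simple graph has k_d ≥ 2.

Macroscopic: exact Brandes betweenness (raw values over unordered
pairs, endpoints excluded, no (N−1)(N−2) normalization since only
degree-class averages and shapes are compared), the shortest-path
hop-length distribution P(l) with the diameter, and spectral summaries.
Disconnected graphs are handled per component and pooled, with the
number of mutually unreachable pairs reported explicitly.  The Fiedler
value is the *second-smallest* eigenvalue of L = D − A (algebraic
connectivity), which is 0 exactly when the graph is disconnected; the
occasionally seen phrasing "second largest" for the spectral gap is a
slip and is not followed.  Dense symmetric eigensolvers are used up to
1500 nodes and shift-inverted Lanczos beyond.

Ensemble summaries average distribution-valued properties pointwise
over the union support on *normalized probabilities* (absent values
read as 0), matching how mean curves with s.d. error bars are drawn
across graph realizations; s.d. is the population standard deviation,
so a single-sample ensemble reports 0.  The Kolmogorov–Smirnov distance
compares the source's distribution with the pooled ensemble counts.

## Synthetic generator

Test graphs emulate the one robust stylized fact of the real networks
this methodology targets: a heavy-tailed degree distribution.  Degrees
are sampled from P(k) ∝ k^(−γ) on k = 1..k_max (default γ = 2.5,
k_max = N − 1), the sum is made even by decrementing one entry if
needed, stubs are paired as in the configuration model, and self-loops
and parallel edges are then *removed*.  Simplification is used instead
of restart-on-collision because restarting has vanishing success
probability for power-law-ish sequences; the cost is a realized mean
degree slightly below the sampled target (the pre-simplification target
is stored on the graph and tested to agree within 20 %).  The generator
produces plausible heavy-tailed structure with mild hub-induced
clustering; it does not reproduce the strong clustering, community
structure, core–periphery organization, or bimodal global structure of
particular real networks, so ensemble tests demonstrate the machinery's
correctness and convergence behaviour, not claims about any specific
real system.

## Problem sizes and defaults

The test-suite and the acceptance script run on 500-node generated
graphs (≈ 550–600 edges) for chain conservation and targeting, a
300-node graph with 5 samples per level for the ensemble convergence
measurement, and exhaustive enumeration only where the state space is
tiny (all labelled graphs on ≤ 4 nodes; the 70 two-regular graphs on 6
nodes).  These sizes were chosen as the smallest at which every
phenomenon of interest (heavy-tailed degrees, non-trivial clustering
gap after 2k-randomization, KS convergence across levels) is clearly
expressed.  The default ensemble size follows the 20-samples-per-level
protocol and is configurable downward.

## Known limitations

* Swap-chain sampling is only approximately uniform; no importance
  reweighting is applied.
* 3k-targeting rewiring is deliberately not provided — the 3k
  distribution is exposed as a statistic only, because 2k-preserving
  3k-targeting chains are known not to converge in practice and no
  ergodic 3k swap is known.
* The annealing schedule is heuristic; for targets far outside what the
  fixed joint degree matrix can support (e.g. c̄* near 1 on a sparse
  graph), the chain reports non-convergence and returns its best graph.
* Betweenness and the size-4 census are exact and therefore gated by a
  node-count threshold (default 2000) in the ensemble battery.
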
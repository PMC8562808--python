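# Methods

This note documents the models, conventions and numerical choices behind
`trailnets`, in the order the pipeline uses them.

## The vegetation graph and its line graph

A vegetation map is an undirected simple graph of junctions and stems with
physical lengths in cm. Every ordered pair of adjacent stems at a junction
carries a transition index (TI) in {1, 2, 3, 4}: 1 when both stems belong
to the same plant (one forced trajectory, quickly reinforced by pheromone),
up to 4 when the junction links plants through many unstable trajectories.
Each observation day records terminals (nests and food sources), the edges
in use, and ruptured edges; ruptures are cumulative — an edge removed on
day *t* stays unavailable from *t* on.

**Directionality.** Ants tend not to turn around, so analysis is restricted
to outbound paths. Direction is defined relative to one root terminal (the
main nest): a breadth-first ordering from the root on the full map directs
every edge from the endpoint nearer the root (hop count) to the farther
one; edges between equidistant endpoints point toward the lexicographically
larger node-id. The rule is deterministic and idempotent and is recorded in
every output manifest, since the underlying field convention specifies only
"away from the nest", not a tie-break.

**Line graphs.** `to_line_graph` builds the outbound line graph: one
line-node per available stem, one line-edge per outbound transition
(incoming stem, junction, outgoing stem), weighted by TI. Note that a
junction whose stems all point outbound (the root, by construction)
contributes no transitions, so this graph can be disconnected even on a
connected map. Where an algorithm needs a connected transition structure
(the average-TI heuristic, route planting), it uses the undirected
all-adjacent-pairs variant `adjacent_pairs_line_graph`, which joins every
pair of stems sharing a junction (TI = the smaller of the two ordered
records).

**Network transitions.** A trail network's transition set is every
outbound-consistent ordered pair of *used* adjacent edges — not only pairs
along some walk. This matches averaging "all transitions in the network"
and makes the average TI a function of the edge set alone.

## Synthetic vegetation

The generator's defaults are the study conditions; they were calibrated
once against the field maps' summary statistics and are not tuned per run.

* **Topology.** 200 junctions uniform in the unit square, each joined to
  its 3 nearest neighbours (degree ≥ 3 guaranteed, as in the field
  protocol where every mapped node offered a choice of edges); components
  stitched via nearest pairs.
* **Plants.** Connected graph-Voronoi territories grown by multi-source
  BFS from 50 random junctions. A stem belongs to one plant (that of its
  lexicographically first endpoint), so moving between plants costs a
  single cross-plant transition, as in the field where a stem grows from
  one plant and touches another. Same-plant transitions carry TI 1;
  cross-plant transitions draw TI 2/3/4 with probabilities 0.3/0.4/0.3.
  Under these choices the available mean TI across seeds is ≈ 1.49–1.60,
  inside the field colonies' range (1.47–1.88).
* **Lengths.** Log-uniform on [0.5 cm, 150 cm], independent of topology,
  so the observed 100-fold length spread holds by construction.
* **Days.** 10 observation days. Terminal counts are drawn in 3–6; each
  non-root terminal is swapped with probability 0.2 per day. Terminals are
  not uniform over junctions: they are drawn with weight
  exp(−c/2.0), where *c* is the minimum summed TI excess (Σ(TI−1)) of a
  route from the root, and at least 5 hops from the root. This encodes
  that colonies forage where coherent trails can be maintained; with
  uniform terminals no low-TI trail exists to be found and the planted
  pattern collapses.
* **Ruptures.** With probability 0.1 per day, one edge used on day *t*
  ruptures for day *t* + 1 (skipped when it would disconnect the map,
  which the 3-NN topology makes rare). Terminals stranded by a rupture are
  re-drawn.
* **Planted trails.** Each day's "observed" network is the union of
  minimum-transition-cost routes from the root to each terminal: shortest
  paths on the line graph with step cost TI − 1 + 0.05, so TI-1 runs are
  nearly free and a mild per-transition penalty keeps routes compact. On
  top: spur edges with probability 0.05 per trail node (exploration
  noise), and with probability 0.2 per day one two-branch loop (an
  alternative node-disjoint outbound branch between two trail nodes).
  Resulting trails have ≈ 20–40 nodes per day (field: 25–55) and average
  TI well below the random ensembles'.

What the generator does *not* emulate: real 3D geometry and Euclidean
consistency of lengths, plant growth and seasonal change, ant flow rates,
and any behavioural response to ruptures beyond re-routing. Passing tests
on synthetic data therefore show that the *inference machinery* recovers a
planted structure of the field data's kind — not that any particular
biological conclusion transfers.

## Null models

Random networks connect the day's terminals by uniform random walks on the
day's available subgraph (each step uniform over the current junction's
incident stems, both directions traversable, backtracking allowed). A walk
stops the first time it touches the existing network; the stop node is an
*endpoint*. The independent model rebuilds the network from scratch each
day. The dependent model mutates yesterday's network: walks of dropped
terminals are retracted to the suffix beginning at the first endpoint
occurring in the walk (nodes touched only before that point are removed —
this is exactly what keeps surviving terminals connected), and new
terminals attach by fresh walks.

Numerical choices: walks are capped at 10,000 steps and restarted (the cap
only truncates pathological excursions; conditional on absorption the
hitting distribution on a connected graph is unchanged); a walk broken by
an edge rupture is regenerated on the new availability if it served a
current terminal and dropped otherwise, followed by a repair pass that
re-walks any terminal left disconnected. Ensembles are reproducible from a
single seed; members are chained (dependent) or drawn independently per
day (independent). The desk-scale default of 1,000 networks per ensemble
keeps the Monte-Carlo standard error of a percentile below
√(50·50/1000) ≈ 1.6 points; the field-scale preset (100,000) is available
where runtime permits.

## Optimized networks

* **Average edge length** — add edges in increasing length until the
  terminals share a component; drop everything else; then remove edges in
  decreasing length whenever removal lowers the average without
  disconnecting the network. (A cheap edge can be *kept* purely to lower
  the average — that is a property of the objective, verified against the
  exhaustive oracle.)
* **Average TI** — the analogous add-then-remove scheme on transitions.
  The add phase closes over the terminals' component; the removal phase is
  steepest descent on the network's *realized* average TI (the mean over
  all activated transitions, i.e. the quantity networks are scored on):
  at each step remove the edge that lowers the average most, requiring
  terminal coverage and connectivity; removals leaving the average
  unchanged are also taken, since on an integer scale refusing ties would
  preserve every redundant branch of the lowest TI class. On 50 random
  ≤ 7-node instances the result equals the exhaustive optimum ≥ 90% of
  the time and never beats it.
* **Total nodes** — the classic metric-closure (Kou–Markowsky–Berman)
  Steiner-tree 2-approximation with unit hop weights, then non-terminal
  leaf pruning.
* **Total length** — a level-2 density-greedy directed Steiner heuristic
  in the outbound view, rooted at the main nest: repeatedly buy the
  (intermediate vertex, terminal subset) bundle with the lowest length per
  terminal covered, with bought edges free thereafter; falls back to the
  undirected graph (with a warning) when a terminal is outbound-unreachable,
  e.g. after a rupture.

None of the heuristics guarantees global optimality; the exact solvers in
`trailnets.oracles` (exhaustive subsets, guarded by instance-size limits)
provide the reference on small instances, and the NP-completeness of the
average-TI problem — via the minimum average-weight path reduction from
directed Hamiltonian path, with threshold (3+|V|)/(|V|+1) — is verified
mechanically on random digraphs. The average-weight path search is
restricted to simple paths; allowing repeated nodes would let low-mean
cycles drive the infimum to the minimum mean cycle and degenerate the
decision problem.

## Comparison and statistics

Percentiles use 100·|{φ_i ≤ φ_obs}|/n with ties counted. All percentile
arithmetic is in percentage points (50, not 0.50). Networks with no
transitions have undefined average TI and are excluded from TI percentiles
(logged). Day-averaged percentiles per colony enter the test battery, one
value per colony per objective, guarding against pseudoreplication across
days. Total length is excluded from the battery because it is strongly
positively correlated with total nodes (checked and flagged on every run);
the battery is Friedman across {average length, total nodes, average TI}
— implemented directly in its tie-corrected rank form, identical to the
scipy reference where scipy applies — with Conover–Iman rank-sum t post
hocs (Bonferroni over the 3 pairs), in both orientations (objectives as
treatments with colonies as blocks, and vice versa; single-colony runs
fall back to days as blocks and say so in the report). Observed-vs-
optimized comparisons use the paired Wilcoxon signed-rank test on
d_rand = 50 − pct_obs against d_opt = pct_obs − pct_opt; a one-sample
variant is exposed because the underlying procedure can be read either
way.

## Loops and connectivity

A loop is a (source, target) pair joined by two or more internally
node-disjoint outbound used paths (disjointness is a convention choice —
with shared interiors "two paths" is ambiguous). Candidate alternatives
are all simple outbound paths in the available vegetation between the same
endpoints with at most 12 nodes, reflecting the field mapping margin of a
few nodes beyond the trail (configurable). Each observed path's rank among
candidates (ascending objective, average ranks for ties) minus the median
rank (n+1)/2 is its centered rank; per-objective means are tested against
0 with a two-sided one-sample t test.

Connectivity: for every available edge (u, v) with u on the trail and v
off it, the fewest-node path from v back to any trail node, not re-using
the edge (u, v); the count includes v and the rejoining trail node and
excludes u. Edges with no way back are excluded and logged. The value is
averaged over all such edges on all days. The node-count convention shifts
all values consistently, so comparisons across networks remain valid.

## Problem sizes

Default analysis sizes — 200-node maps, 1,000-network ensembles, 10 days,
oracle sweeps on ≤ 7-node instances, 200 reduction instances with ≤ 6
vertices — were chosen so a full pipeline run and the complete validation
suite each finish in a couple of minutes on a single CPU while keeping
percentile Monte-Carlo error under ~2 points; the field-scale ensemble
preset (100,000 networks) changes only runtime, not structure.

## Known limitations

* The outbound orientation tie-break and the connectivity node-count
  convention are package conventions; absolute values depending on them
  are comparable within, not across, conventions.
* The dependent model's behaviour under ruptures (regenerate the affected
  walk) is one of several defensible readings of the field procedure.
* The average-TI heuristic's optimum on these maps is typically a dense
  region of TI-1 transitions, not a trail-like tree: minimizing an average
  rewards padding with cheap elements. The planted trails therefore come
  from the route-union model, which is also the better model of what the
  ants build; the heuristic serves as the optimization baseline.
* Synthetic calibration targets summary statistics (degree floor, TI
  mixture, length spread, terminal turnover), not the spatial layout of
  any particular colony.
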
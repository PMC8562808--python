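# trailnets

Analysis of arboreal ant trail networks on vegetation graphs.

Arboreal turtle ants (*Cephalotes goniodontus*) maintain a routing backbone
of pheromone trails through the tree canopy, connecting nests and ephemeral
food sources. Unlike ground-foraging species, their trails are constrained
to the physical vegetation: a graph *G* = (*V*, *E*) whose nodes are
junctions, whose edges are stems with physical length *w(e)* (cm), and
where every edge–node–edge transition carries a categorical **transition
index** TI ∈ {1, 2, 3, 4} estimating how likely successive ants take — and
thus pheromone-reinforce — the same trajectory through the junction (1 =
one forced trajectory on a single plant, 4 = many wind-perturbed
trajectories). Transitions live naturally on the line graph
*L* = (*V_L*, *E_L*) with *V_L* = *E* and TI as edge weights.

`trailnets` asks which of four objectives a trail network optimizes —
average edge length, total number of nodes, average transition index, and
total edge length — by comparing each observed network against

1. **random-network null ensembles** built from uniform random walks that
   connect the same terminals (a day-to-day *dependent* model that mutates
   the previous day's network when terminals turn over, and a day-to-day
   *independent* model drawn from scratch each day), and
2. **heuristically optimized networks**, one per objective: greedy
   add-then-remove schemes for the two averages, a metric-closure Steiner
   approximation for node count, and a density-greedy directed Steiner
   heuristic for total length. (Minimizing average TI is NP-complete;
   `trailnets.oracles` carries the Hamiltonian-path reduction and exact
   brute-force solvers used to validate the heuristics.)

Similarity is measured by the percentile

&nbsp;&nbsp;&nbsp;&nbsp;pct(φ_obs) = 100 · |{φ_i ≤ φ_obs}| / n

over the *n* random networks' objective values φ_i: 50 % means "as good as
the median random network", lower is better. Statistics follow the
nonparametric route — Friedman across the three uncorrelated objectives
with Conover–Iman post hocs (Bonferroni), Wilcoxon signed-rank tests on the
paired differences (50 − pct_obs) vs (pct_obs − pct_opt), Spearman
correlations among objectives — plus loop centered-rank analysis and a
trail-connectivity metric (fewest-node return path from off-trail nodes).

No machine-readable field maps are publicly deposited, so the package ships
a first-class synthetic generator (`trailnets.synth`) that reproduces the
field maps' statistical structure: ~200 available junctions of degree ≥ 3,
stem lengths spanning 100-fold, plants as connected territories so that
same-plant transitions carry TI 1, available mean TI ≈ 1.5–1.6, 10
observation days with terminal turnover and occasional stem ruptures, and
planted "observed" trails built from minimum-transition-cost routes.

## Worked example

```bash
trails run --scale desk --colonies 1 --seed 1 --out out/
```

generates one synthetic colony, draws 1,000 random networks per day under
both null models, optimizes all four objectives per day, and writes
percentile tables and statistics. `out/mean_percentiles_independent.csv`
(day-averaged observed percentiles, one row per colony):

```
colony,avg_edge_length,avg_ti,total_length,total_nodes
synthetic-1,59.51,17.51,0.06,0.21
```

Read: the planted trails are far better than random at minimizing the
number of nodes (mean percentile 0.2), total length (0.1) and average TI
(17.5), but their average *edge length* is indistinguishable from the
median random network (59.5) — the trail minimizes total length by using
few junctions, not short stems. The Wilcoxon entries in `out/stats.json`
make the same point pairwise: for total nodes the observed networks sit
next to the optimized ones (W = 0, mean d_opt = 0.2 points vs mean d_rand
= 49.8), while for average edge length they sit with the random networks.
`out/connectivity.json` reports the mean fewest-node return path
(2.38 over 600 off-trail edges here; field values run ≈ 2.5–4.5), and
`out/loops.csv` the centered ranks of observed loop branches.

The same stages are available piecewise (`trails simulate`, `nulls`,
`optimize`, `compare`, `loops`, `connectivity`, `oracle`) and as a library
(`trailnets.generate_colony`, `generate_ensemble`, `optimize_all`,
`percentile`, …).

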
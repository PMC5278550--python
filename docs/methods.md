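# Methods

## The optimization problem

`robustcoop` constructs undirected simple networks with a fixed number of
nodes N and links M that trade off two maximized objectives:

* **Attack robustness** `R = (1/N) Σ_{Q=1..N} s(Q)`, where `s(Q)` is the
  fraction of nodes in the largest connected component after `Q` steps of a
  targeted attack that always removes the currently highest-degree node
  (degrees recomputed after every removal).  For connected graphs
  `0 < R ≤ (N−1)/(2N)`, with the complete graph attaining the bound.
* **Cooperation** `f(c)`, the stationary cooperator fraction of an
  evolutionary prisoner's dilemma played on the network (below).

These objectives conflict: homogeneous, assortatively mixed ("onion-like")
structures resist attack, while heterogeneous hub-and-leaf ("star-like")
structures shelter cooperators.  The package therefore treats construction
as a bi-objective problem and returns a Pareto front of candidate networks
rather than a single optimum.

## Structural measures

* Heterogeneity `H = Σ_{i,j} |k_i − k_j| / (2 N² ⟨k⟩)`, a Gini-type index of
  degree inequality in [0, 1]: exactly 0 on regular graphs, larger for
  star-like degree sequences.  This algebraic form was chosen because it has
  every property required of the index (range, zero point, monotonicity in
  degree spread) and is the standard Gini-mean-difference normalization; it
  is a documented design choice of this package.
* Assortativity `r`: Pearson correlation of the degrees at the two ends of
  an edge, computed over all 2M directed endpoint pairs (Newman's degree
  mixing coefficient).  `r` is undefined (and signalled as such) when the
  endpoint-degree variance is zero, e.g. on regular graphs.

## Game dynamics

Strategies are pure cooperate/defect.  Each round every node accumulates
pairwise payoffs against all neighbours from the PD matrix `T > R > P ≥ S`
(defaults: weak dilemma T=2, R=1, P=S=0; payoffs are recomputed from
scratch each round).  The population then updates synchronously: node `i`
picks one uniformly random neighbour `j` and, if `P_i < P_j`, adopts `j`'s
strategy with probability

    W = (P_j − P_i) / ((T − S) · max(k_i, k_j)),

clipped to [0, 1].  The degree normalization keeps W a probability for
accumulated payoffs; dividing by `T` instead of `T − S` is available as a
configuration knob (identical when S = 0).  All-C and all-D are absorbing
for any graph and any payoff ordering; the simulator exits early at their
exact values.

`f(c)` for a network is the cooperator fraction averaged over the
post-transient sampling window and over independent realizations, each
started from a uniformly random placement of ⌈N/2⌉ cooperators.
Convergence is slow: on N=200, ⟨k⟩=4 networks the cooperator fraction keeps
building for several thousand synchronous sweeps, so reported values use a
10 000-sweep transient (measured to be within the realization noise of a
30 000-sweep transient), a 100-sweep sampling window and 30 realizations.
No sliding-window convergence test is used — a fixed budget plus
absorbing-state early exit is simpler and exactly reproducible.

## Rewiring operators

Two move types, both preserving N and M and graph simplicity:

* **relink** — remove a random edge (a, b), add (a, c) to a random
  non-neighbour c: shifts one unit of degree from b to c, reshaping the
  degree distribution (moves H and R).
* **swap** — replace two independent edges (a, b), (c, d) with a
  perfect-matching alternative: preserves every degree (H exactly fixed)
  while moving r.  The pairing with the larger/smaller sum of
  endpoint-degree products steers r up/down (Xulvi-Brunet–Sokolov style).

`hill_climb` greedily accepts strictly improving moves for an objective in
{R, H, r} (or any callable), requires connectivity after every acceptance by
default (disconnected candidates make both objectives degenerate), and
stops after `patience` consecutive rejections.

The robustness-directed **mutation** operator additionally mixes strict
R-improving relinks with assortativity-raising swaps accepted whenever R
does not decrease.  Pure strict relink ascent reliably stalls in robust but
weakly assortative local optima (R ≈ 0.32, r ≈ 0.3 at N=200, M≈400); the
R-neutral assortative drift walks those plateaus towards the onion-like
organisation characteristic of attack-robust networks and in practice also
unlocks further strict gains (probe: R 0.325 → 0.333 while r 0.34 → 0.78).
This plateau drift deliberately lives only in the mutation operator;
`hill_climb` keeps its strict-monotonicity contract.

## The evolutionary algorithm

A standard NSGA-II generational loop (fast non-dominated sorting, crowding
distance, binary tournament via the crowded-comparison operator,
environmental truncation) with three problem-specific elements:

* **H-spread initialization.**  The population is seeded with networks
  hill-climbed towards Ω evenly spaced heterogeneity targets.  H separates
  the objectives, so this cheaply covers both ends of objective space before
  a single game evaluation is spent.  Bounds are auto-estimated by bounded
  H-min/H-max climbs, or given explicitly; the N=200, ⟨k⟩=4 study uses the
  calibrated bounds (0.15, 0.55) — wider spreads push the cooperative end
  into extreme few-hub configurations and starve the mid-front, narrower
  ones starve the robust end.  Each climb starts from the base network or
  from a scale-free reference graph with the same N and M (preferential
  attachment, padded/trimmed to exactly M edges), whichever is closer in H.
  The anchor matters: greedy H-raising climbs from homogeneous bases
  produce either many small hubs or one or two mega-hubs, and neither
  organisation shelters cooperators — what does is a broad tier of medium
  hubs with preferential-attachment wiring (hub core plus leaves attached
  to hubs), which is reachable from the problem's stated constraints (N and
  M) alone.  Every initial member still has exactly the base's node and
  link counts.
* **No crossover.**  Offspring arise by mutation only: with probability
  `operator_mix` (default 0.5) the robustness-directed operator above,
  otherwise up to `mutation_steps` accepted r-lowering swaps
  (cooperation-directed, since disassortative mixing shelters cooperators).
* **External archive (EP).**  Every non-dominated network encountered is
  kept in an unbounded archive; dominated members are evicted on insertion.
  The front reported at the end is the archive, not the final population.

Because f(c) is stochastic, each new network is evaluated once with its own
seed derived from the master seed ("frozen noise") and the value is cached
while the network survives; this keeps dominance relations stable within a
run and makes runs bit-for-bit reproducible from one integer seed (the
archive hypervolume is then exactly non-decreasing).  Frozen noise lets a
fluke estimate evict a genuinely better network from the archive, so after
the run the archive is re-ranked from fresh independent estimates pooled
with the final *and initial* populations — any member lost to estimate
noise during the run, including the initialization's best structures, is a
candidate again under honest values.  (A per-generation running-mean
top-up of archive estimates was evaluated and rejected: with the short
search transient the accumulated means are biased low, so converged
veterans end up systematically displaced by fresh members' upward noise.)
Evaluation is tiered: cheap search estimates (6 realizations, 1 500-sweep
transient) drive selection pressure; finished archives are re-ranked with
independent mid-budget estimates (15 × 5 000); reported endpoint numbers
come from a further fresh batch (30 × 10 000) so that selection noise never
inflates them.  Endpoint extraction itself guards against the winner's
curse: picking the archive member with the largest *estimated* f(c)
systematically picks a noise-lucky one, so `report_endpoints` shortlists
the top candidates, re-estimates each at the reporting budget, selects on
those fresh estimates, and reports yet another independent estimate of the
winner — the reported value is never the estimate that performed the
selection.

Defaults for the desk-scale study: Ω = 30, 60 generations, tournament size
2, `mutation_steps` = 10, patience 20 per step.  A run at N = 200, M ≈ 400
takes a few minutes on one CPU; the original-scale studies (larger Ω,
hundreds of generations, 10³-node networks) are hours-scale and are
deliberately not part of the test suite.

## Endpoint extraction and experiments

From an archive: `G_r` = member with the largest R, `G_l` = largest f(c),
and the balanced `G_m` = member maximizing `min(R/R_max, f(c)/f(c)_max)`
(a concrete rule for "the middle of the front"; ties resolve to the lowest
member index).  `summarize_endpoints` produces the per-model mean ± std
table plus cross-model averages; `attack_comparison` exports node- and
edge-attack disintegration curves for the three endpoints.

The correlation experiment generates a BA network, minimizes R by strict
relink descent to a patience stall, then maximizes R, sampling a network
every 5 % relative R increase (relative to the last sample by default;
cumulative-from-minimum available behind a flag), measures f(c) on every
sample, and reports the pooled Pearson correlation — negative on scale-free
networks, which is what motivates the bi-objective formulation.

## What the generators emulate, and limits

ER / BA / WS initial networks are the standard connected models at
configurable N and ⟨k⟩ (M = N⟨k⟩/2; BA yields M = (N − m)·m, i.e. ⟨k⟩ ≈ 4
means M = 396 at N = 200).  They emulate the topological diversity of real
systems but not weights, direction, temporal rewiring, or community
structure; results on them show the optimizer works from structurally
different starting points, not that any particular real system will exhibit
the same front.  Real networks enter only as user-supplied edge lists.

Known limitations: f(c) at N = 200 is strongly bimodal near the cooperative
end (all-C absorption vs. early extinction), so cooperative-endpoint values
carry realization noise of a few percent even at the reporting budget; the
maximum-R endpoint's assortativity is not pinned down by R maximization
(many near-optimal structures with very different r exist), so its r value
is budget- and path-dependent; the mid-front is the slowest region to fill
— at desk-scale budgets the balanced endpoint tends to sit slightly to the
robust side of where longer runs place it; and greedy acceptance means all
optimized values are lower bounds on what longer budgets reach.
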
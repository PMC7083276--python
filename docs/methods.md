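# Methods

## The measures

Significance scores a partition of an undirected simple graph by
`S = Σ_s C(n_s,2)·D(p_s‖p)`, the number of intra-community vertex pairs
weighted by the binary Kullback–Leibler divergence between the community's
internal density `p_s = m_s/C(n_s,2)` and the global density
`p = m/C(n,2)`.  The multi-resolution form replaces `p` by `p̃ = γ·p`.
All evaluation uses the conventions `0·ln 0 = 0`, singleton communities carry
zero pair weight, and `D ≥ 0` is clamped against round-off.  `γ·p ≥ 1` is
rejected with `ResolutionError` rather than clipped — the log terms are
undefined there.  A complete graph (`p = 1`) is scored only at `γ = 1`, where
every induced density is also 1 and each KL term vanishes in the limit; any
other `γ` on a complete graph is an error, keeping the measure's contract
unambiguous in the degenerate case.

Multi-resolution Modularity uses null-term rescaling,
`Q(γ) = Σ_s [m_s/m − γ(d_s/2m)²]`.  Among the rescaling conventions in
circulation, this one is the convention consistent with the Modularity
critical number `r* = γ(p_i+2p_o)/p_o` used throughout the critical-point
analysis, which is why it was chosen.

Graphs are treated as unweighted and simple; the readers drop duplicate
edges and self-loops with a counted warning, and the scorers ignore
self-loops defensively.

## Optimizer

A Louvain-style multi-level greedy maximizer works for both measures through
one incremental engine (`PartitionState`) whose single-node move deltas touch
only the source and target community terms; supernodes carry their original
vertex count and internal edge count, and the original global density is held
fixed across levels, because Significance depends on original-vertex
statistics and not on the coarse graph alone.  Design choices where the
procedure itself is underdetermined:

- initialization from all singletons; node visitation is a seeded shuffle per
  sweep; a move happens only on strictly positive gain, the largest gain
  wins, first-encountered on ties;
- candidate targets are the communities of neighbors plus a fresh empty
  community (isolation) — without isolation moves the stated local-optimality
  guarantee does not hold for Significance;
- each level alternates supernode moves on the aggregated graph with a
  single-node refinement sweep on the original graph, so single-vertex
  misassignments are corrected before aggregation freezes them;
- after the multi-level loop converges, a split pass re-optimizes the
  interior of every community (global density fixed; external degree mass
  carried as an offset so Modularity terms stay exact) and applies any split
  that raises the total score, then the cycle repeats.  Greedy growth can
  fuse two well-separated blocks into one community that no single-node move
  can take apart; the split pass is the minimal deterministic escape from
  that trap and is what makes planted-loop recovery reliable.  It is plain
  greedy re-optimization, not a stochastic refinement phase;
- a level ends when a sweep makes no move or after `max_sweeps_per_level`
  (default 100); the algorithm ends when neither coarse moves, fine moves,
  nor splits change anything.  A single integer seed drives all shuffles;
  identical seed and input give identical output.  Single-start by default;
  multiple restarts can be scripted over seeds.

`exhaustive_optimum` enumerates all set partitions (restricted-growth
strings) for `n ≤ 12` and serves as the ground-truth oracle in tests; the
greedy optimizer matches it on ~98% of random 8-node two-clique graphs and
never exceeds it.

## Critical-point analysis

`loop_significance` evaluates the expectation-level score of `x`-merged loop
partitions exactly as the theory writes it, with
`p_x = (p_i·x + 2(x−1)p_o)/x²` and `p = (p_i+2p_o)/r`; real-valued `x` is
accepted for smooth curves.  The two typographically possible readings of
`p_x` are algebraically identical.  `potential_well_profile` uses the same
densities, so its `k = 0` and `k = r/2` endpoints coincide with `x = 1` and
`x = 2` exactly; the profile is affine in `k`, which is the no-potential-well
property.

`numeric_critical_r` locates the merge transition without the closed form's
approximations.  It is exact for the networks the loop generator actually
samples: expected internal edges `p_i·C(n_c,2)` per community and expected
spanning edges `p_o·n_c²` per adjacent pair, exact binomial pair counts, the
full `(1−q)ln((1−q)/(1−p̃))` terms, and the exact global density
`p(r) = r(m_in+m_btw)/C(rn_c,2)`.  The transition condition at small `r` can
be positive for the trivial reason that the global density approaches the
block densities, so the root finder brackets the negative-to-positive
crossing (planted partition preferred below, merging preferred above) and
refines it with Brent's method.

The critical point is exponentially sensitive to bookkeeping:
`r* ∝ exp[(2H(p₂)−H(p₁))/p_o]`, so O(1/n_c) differences in how pair counts
are booked move the root by 10–30% at `n_c = 32`.  Against the asymptotic
closed form, the generator-exact root differs by ~8% at
`(p_i, p_o, n_c) = (0.2, 0.02, 32)`; the exact Modularity transition is
`r* = (p_i/p_o)(1 − 1/n_c) + 2`, within 5% of `p_i/p_o + 2` for `n_c ≥ 16`
and converging to the constant offset 2 as `n_c → ∞` (the acceptance script
reads the offset off at `n_c = 512`, deep in the asymptotic regime).

## Benchmark generators

All generators return string-labelled networkx graphs plus ground-truth
partitions per level and are deterministic given one integer seed (a single
RNG stream per call).

**Community loop** — `r ≥ 3` blocks of `n_c` vertices on a ring; every
intra-block pair linked with probability `p_i`, every pair spanning
ring-adjacent blocks with `p_o`, non-adjacent blocks never linked.

**Four-block (FB)** — blocks `[large, large, small, small]` on a ring, the
two small blocks adjacent, consecutive blocks joined by exactly one edge.
Cliques by default — reproducing the classic resolution-limit merge — with
Bernoulli blocks available for the small-size-difference regime.

**Homogeneous hierarchical** — 256 vertices, 16 groups of 16 nested in 4
groups of 64.  The stated quantities are expected per-vertex link counts, not
a wiring algorithm, so links are Bernoulli with expectation-matching pair
probabilities `k_in0/15`, `k_in1/48` and `1/192` (192 vertices lie outside a
node's 64-vertex group, giving exactly one external link in expectation).

**Heterogeneous hierarchical** — 1000 vertices, micro communities of 10–25
nested in macro communities of 50–100 (power-law sizes, exponent 1),
truncated power-law degrees (exponent 2, maximum 50) whose lower cutoff is
solved so the expected mean degree is exactly 20.  Each vertex's degree is
split into cross-macro (`μ₁`, default 0.2), same-macro-cross-micro (`μ₂`,
default 0.3) and within-micro stubs; within-micro stubs are realized by a
randomized degree-faithful (Havel–Hakimi-style) construction and the sparser
scopes by random stub matching with collision reshuffles.  Stubs exceeding a
scope's capacity are promoted one scope outward unless that scope's mixing
fraction is zero, in which case they are dropped — so `μ₁ = 0` yields exactly
disconnected macro blocks.  Parity fixes and matching rejections lose ~1% of
stubs; the realized grand mean degree over seeds is ~19.7–19.8.  The
generator emulates the stated two-level parameters with a degree-corrected
nested planted partition rather than porting a specific external generator;
its blocks are Bernoulli-homogeneous given degrees and do not reproduce
degree–community correlations of any particular published implementation.

**RB-LFR** — an LFR seed graph (networkx's generator, retried over derived
seeds) replicated twice with `c` replicas per stage, giving
`seed_n·(1+c)²` vertices.  Each replica vertex gains one candidate edge to a
uniformly random vertex of its stage's seed copy; candidates are removed
independently with probability `p₁` (stage 1) / `p₂` (stage 2) in the
extended variant, so `p₁ = p₂ = 1` leaves the copies disconnected.  Three
named ground truths are exposed: `Flat` (every copy at community
granularity), `S-R*2` (seed copy fine, each replica copy one block) and
`R*2-S` (replica copies fine, seed copy one block); replica counts and wiring
are parameters with these defaults documented, since the hierarchy admits
several operationalizations.

## Partition metrics

NMI (arithmetic-mean normalization), AMI (permutation-model chance
adjustment, max normalization) and ARI are delegated to scikit-learn behind
the module surface.  `Fr`, the fraction of vertices affected by merging, is
defined here as the fraction of vertices whose ground-truth community is not
reproduced verbatim as a detected vertex set — so pure splits also count; a
merging-only variant (`merging_only=True`) counts only communities strictly
contained in a larger detected community.  `Fr` is directional (truth first)
by design.

## MSS / RWR / MSS+

Module partitions are computed once per γ on a default grid of 8 log-spaced
values in [0.1, 1] (they do not depend on the training genes, so folds reuse
them).  Under each partition a module's score is
`|module ∩ train| / |module|` and every member inherits it; a gene's MSS
score is the mean over the grid (max available as an option).  RWR iterates
`x ← (1−c)Wx + ce` with column-normalized adjacency `W`, uniform restart over
the training genes, `c = 0.7` (the classic restart of this method family),
and an L1 tolerance of 1e-10; mass reaching degree-zero vertices is
redirected to the restart distribution so scores always sum to 1.  MSS+
min-max normalizes both score vectors and adds them with equal weight
(weight exposed).  Cross-validation splits the disease gene set into k
seeded, near-equal folds; AUC ranks held-out genes against genes never
associated with the disease (training genes excluded from the ranked pool by
default; both behaviors exposed), with ties mid-ranked — identical to the
Mann–Whitney U normalization.

The synthetic protein network is a stochastic block model (20 modules of 50,
`p_in = 0.3`, `p_out = 0.01` by default) with 60 disease genes, a fraction
`concentration` of which is sampled from 3 designated modules and the rest
uniformly; every association table must carry ≥ 20 genes.  What passing
tests show: module-concentrated signal is recovered (mean AUC > 0.8 at
concentration 0.8), random scores sit at AUC ≈ 0.5, and the linear
combination does not trail the better of its two inputs by more than 0.02 on
average.  What they do not show: performance on real protein networks —
real interactomes have heavy-tailed degrees, overlapping and nested modules,
study bias in both edges and annotations, none of which the block model
reproduces, so the synthetic AUCs are parameter-recovery checks, not
forecasts.

## Problem sizes and determinism

Statistical tests use desk-scale replicates chosen as the package's own
defaults: 10 seeds for planted-loop recovery (1024 vertices each), 20 seeds
for the heterogeneous generator's degree check, 50 random 8-node graphs for
the enumeration oracle, 1000 randomized moves for the incremental-delta
contract, and 3–10 seeds for the cross-validated AUC properties.  Every
stochastic component (generators, optimizer sweeps, folds) is driven by
explicit integer seeds; `scripts/acceptance.py` derives all of its seeds from
the single `--seed` argument.

## Known limitations

- The optimizer is greedy; the split pass removes the dominant local-optimum
  class on the benchmark families but global optimality is only verified
  against enumeration at `n ≤ 12`.
- Significance here is the unweighted, undirected measure; weighted or
  directed generalizations are out of scope, as is the Surprise measure.
- The closed-form critical numbers are asymptotic; their documented
  tolerance against the exact transition is ~10% in the small-`p` regime and
  degrades as densities grow.
- `exhaustive_optimum` is factorially expensive and refuses `n > 12`.
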
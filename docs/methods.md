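# Methods

## Model

A weighted undirected network on `N` nodes (symmetric non-negative `W`,
zero diagonal) is summarized by a hard assignment `τ` of nodes to `q`
modules and a binary `q × q` image graph `B`.  The null model is the
configuration model: because the diagonal of `W` is zero, the expected
weight of a pair reduces to the rank-one form

    p_ij = (Σ_{k≠i} w_ik)(Σ_{l≠j} w_lj) / Σ_{k≠l} w_kl = d_i d_j / M,

with `d` the weighted degree vector and `M = Σ_{i≠j} w_ij` (twice the edge
weight sum).  The penalty mass identity `Σ_{i,j} p_ij = M` holds exactly and
is asserted to `1e-9·M` in the tests.

Mismatch between network and image graph is

    E(τ, B) = (1/M) Σ_{i≠j} (A_ij − B_{τ_i τ_j})(w_ij − p_ij),

zero exactly when `B` reproduces the adjacency pattern through `τ`.  Because
`A` is fixed, minimizing `E` over `B` decouples: `B_rs = 1` iff
`Q_rs > 0` (strictly; ties at zero give 0), where

    Q = Sᵀ (W − P) S  restricted to i ≠ j,

and `S` is the one-hot form of `τ`.  Substituting the optimal `B` leaves
the single objective

    Q*(τ) = ‖Q‖_L1 / (2M),

reported normalized so that values lie in `[0, 1]` and are comparable
across networks.  All `i = j` terms are excluded once by zeroing the
diagonal of `W − P`; `P` itself is never materialized (products use the
rank-one structure, `O(qN + q·nnz)`), and a dense `P` is only formed on
request for `N ≤ 2000`.

Aggregation obeys the triangle inequality: merging modules never increases
`‖Q‖_L1`, so the identity assignment (`q = N`) maximizes the fitness and
provides the reported upper bound `Σ_{i≠j} |w_ij − p_ij| / (2M)`.

## Conditional-subgradient solver (SG)

The binary constraint set is relaxed to the polytope `γ` of row-stochastic
`N × q` matrices and the problem is written as minimizing
`F(S) = −‖Sᵀ(W − P)S‖_L1`.  `F` is piecewise smooth; wherever an entry
`Q_rs` crosses zero the L1 norm is non-differentiable, so the Frank–Wolfe
linearization uses the subgradient

    ∂F(S) = 2 (P − W) S Q̄,     Q̄_rs = sign(Q_rs), α at Q_rs = 0,

with `α ∈ [−1, 1]` (default 0).  `⟨Q̄, Q⟩ = ‖Q‖_L1` for every `α`, the
defining property of the subgradient of a norm.  Each iteration:

1. compute `∂F(Sᵗ)`;
2. minimize `⟨∂F, S⟩` over `γ` — separable over rows, each node goes wholly
   to the module with the smallest subgradient entry (`O(qN)`; ties to the
   smallest module index).  Stated as a *minimization* of the linearized
   objective: descriptions that select the "largest" entry refer to the
   subgradient of `+‖Q‖_L1`, which is `−∂F`; the two conventions coincide;
3. line-search `F` along the segment to the chosen vertex.  Restricted to
   the segment, every `Q_rs(λ)` is quadratic, so `F(λ)` is evaluated in
   `O(q²)` per trial point from three precomputed matrices.  A uniform grid
   (21 points, endpoints included) is scanned, then a 20-evaluation
   golden-section refinement around the best grid point.  The grid contains
   `λ = 0`, so `F` never increases — an exact breakpoint enumeration of the
   piecewise-quadratic `F` would be possible but buys little at this cost;
4. stop when `|ΔF| + ‖ΔS‖_F < ζ` (`ζ = 1e-6` on the normalized `F` scale)
   or after `max_iter = 500` iterations.

The final relaxed iterate is rounded row-wise (argmax, ties to the smallest
index).  The iteration converges only to local stationary points, so
quality rests on initialization and restarts.  Three seeded initializers
are provided: `random_hard` (uniform module draw, the default), `random_soft`
(Dirichlet(1) rows), and `degree_stripe` (nodes sorted by degree, dealt
round-robin).  On benchmark ensembles `random_hard` restarts dominated the
alternatives, which remain available.

## Local search

Greedy best-improvement single-node reassignment: each pass scans all
(node, target-module) pairs in index order and applies the single best
strictly improving move, repeating until none improves.  The block matrix
is maintained incrementally — moving node `i` from module `a` to `b` is the
rank-two update `Q ← Q + (e_b − e_a)vᵀ + v(e_b − e_a)ᵀ` with
`v_s = Σ_{j≠i, τ_j=s} (W − P)_{ij}` available in `O(q)` from cached
`SᵀW` and `Sᵀd` — so a move costs `O(q + deg i)` to evaluate and apply.
The same engine drives the annealing baseline.

Each subgradient restart is polished by this local search before entering
path generation: a rounded relaxed iterate need not be a local optimum of
the hard problem (occasionally it is even the all-in-one assignment), and
path generation assumes genuinely locally optimal parents.

## Path generation (PG)

Given an initiating solution `x_A` and a guiding solution `x_B` with the
same `q`, the shared contribution of modules `r` (in `x_A`) and `s`
(in `x_B`) is

    S(r, s) = ‖s_ABᵀ(W − P)S_A‖_L1 + ‖s_ABᵀ(W − P)S_B‖_L1,

where `s_AB` indicates the node intersection of the two modules.  The walk
repeatedly selects the unused pair maximizing `S(r, s)` (lexicographic
tie-break), shrinks module `r` of the working solution to exactly that
intersection, re-places each evicted node greedily by fitness change
(keeping the assignment total — the source module is excluded so the shrink
is genuine), polishes by local search, records the best solution seen, and
marks `r` and `s` used.  The guard variable starts at infinity, so the
first overlap is always processed; afterwards the walk stops when the next
best overlap has at most `N_stop` nodes (default 5) or no unused pair
shares nodes.  At most `q` steps run.  The result is never worse than
either parent.

## SGPG driver

`N_set = 10` subgradient restarts (seeds `base_seed + k`), each polished to
a local optimum, are sorted by fitness; path generation then runs over all
`C(N_set, 2)` ordered-by-rank pairs, keeping every improvement.  All-pairs
was preferred to an incumbent-versus-next schedule after measuring both on
random 7-node ensembles against exhaustive enumeration (all-pairs removed
the residual misses; the cheaper schedule remains available via
`all_pairs=False`).  The returned solution is the fitness maximum over all
stage outputs, hence never below the best restart, and identical
configurations reproduce identical assignments bit for bit.

## Simulated-annealing baseline

Metropolis sampling on hard assignments: single-node reassignments
alternating with two-node label swaps every `T_switch` sweeps (a sweep is
`N` attempted moves; both proposals are symmetric), acceptance
`min(1, exp(ΔQ*/T))`, geometric cooling `T ← C_β T` after `T_sweep` sweeps,
stop at `T < T_end`, return the best state visited.  Defaults
(`C_β = 0.99, T_start = 40, T_end = 0.001, T_sweep = 100, T_switch = 20`)
correspond to the slow schedule appropriate for genome-scale networks and
imply roughly a thousand temperature plateaus; desk-scale comparisons in
the tests and the acceptance script use a lighter schedule
(`C_β = 0.9, T_start = 2, T_end = 0.005, T_sweep = 4, T_switch = 8`,
about 57 plateaus) sized by the same arithmetic for 30-node instances.
The precise move mix behind the historical `T_switch` setting is not
standardized; the alternation above is this package's documented choice and
every parameter is overridable.

## Synthetic instances

The generator draws each unordered pair `{i, j}` independently with
probability `density[τ_i][τ_j]` (unit weights, matching binary-adjacency
inputs; `M` is twice the edge count).  Presets: `two_cliques` (identity
image), `bipartite` (zero-diagonal image — the sparse-module signature),
`ring` (cycle image), `star` (hub module).  What the generator emulates is
block-constant edge probability with known labels; it does not model degree
heterogeneity, weighted noise, or overlapping membership, so recovery
results here bound what to expect on real PPI data only loosely.

## Known limitations

* **Ring degeneracy.**  In a `q = 4` cycle image graph, opposite modules
  have identical rows of `B`; merging them preserves `‖Q‖_L1` exactly, so
  the objective cannot distinguish the planted 4-module labeling from its
  2-supermodule coarsening, and finite-sample noise makes unbalanced
  refinements score strictly higher.  Exhaustive enumeration on small ring
  instances confirms the global optimum itself sits near NMI ≈ 0.7 against
  the planted labels.  Partial recovery on ring plants is therefore a
  property of the objective, not of the optimizer.
* **Local optimality only.**  SG converges to stationary points; with
  `N_set = 10` restarts a small fraction of random small instances
  (~1–3 %) still end a few percent to ~25 % below the exact optimum when
  the optimal basin is rare.
* **`q` is an input.**  Module count selection is out of scope; empty
  modules are permitted, so `q` acts as an upper bound.
* Directed, signed, or overlapping-module structures are not modeled.

## Problem sizes

Tests and the acceptance script run at desk scale by design: exact fixtures
(`N ≤ 6`), oracle ensembles (`N = 7`, enumeration cap `q^N ≤ 2·10⁶`),
planted recovery (`N = 60–80`), SA parity (`N = 30`).  The solver itself
scales as `O(qN²)` per SG run and `O(q²N²)` for PG and handles
thousands of nodes; only the dense-`P` convenience accessor and the
brute-force oracle are size-guarded.
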
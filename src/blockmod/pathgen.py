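"""Path generation: recombine two local optima around high-value overlaps.

Given two locally optimal partitions x_A (initiating) and x_B (guiding) with
the same module budget q, path generation repeatedly

1. scores every module pair (r in x_A, s in x_B) by the shared contribution
   of their intersection to the objective,
       S(r, s) = ||s_AB^T (W - P) S_A||_L1 + ||s_AB^T (W - P) S_B||_L1,
   where s_AB indicates the nodes in both modules;
2. picks the unused pair with the largest contribution, shrinks module r of
   the working solution to exactly that intersection (evicted nodes are
   greedily re-placed by best fitness change, keeping the assignment total);
3. polishes with greedy local search, keeps the best solution seen, marks
   r and s as used, and continues from the improved solution.

The first overlap found is always processed (the guard variable starts at
infinity); afterwards the walk stops when no unused pair has a non-empty
intersection or when the next overlap has at most ``n_stop`` nodes.  The
returned solution is never worse than either input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._state import QState
from .assignment import Assignment, Solution
from .exceptions import ValidationError
from .netio import Network
from .objective import NullModel, fitness, xs_product

__all__ = [
    "OverlapRecord",
    "overlap_contribution",
    "best_overlap",
    "local_search",
    "path_generation",
]


@dataclass(frozen=True)
class OverlapRecord:
    """A module pair (r in x_A, s in x_B), its shared nodes and contribution."""

    r_a: int
    s_b: int
    nodes: tuple
    contribution: float


def _indicator(n: int, nodes) -> np.ndarray:
    s = np.zeros(n)
    s[np.asarray(list(nodes), dtype=np.intp)] = 1.0
    return s


def overlap_contribution(net: Network, nm: NullModel, x_a: Solution, x_b: Solution,
                         r: int, s: int) -> float:
    """Shared objective contribution S(r, s) of Over(r, s) = N_r(x_A) ∩ N_s(x_B).

    Zero when the intersection is empty; symmetric under swapping
    (x_A, r) with (x_B, s).
    """
    asg_a, asg_b = x_a.assignment, x_b.assignment
    if not (0 <= r < asg_a.q and 0 <= s < asg_b.q):
        raise ValidationError(f"module pair ({r}, {s}) out of range")
    shared = np.flatnonzero((asg_a.tau == r) & (asg_b.tau == s))
    if shared.size == 0:
        return 0.0
    t = xs_product(net, nm, _indicator(net.n, shared)[:, None])[:, 0]  # X s_AB
    contrib = np.abs(asg_a.S.T @ t).sum() + np.abs(asg_b.S.T @ t).sum()
    return float(contrib)


def best_overlap(net: Network, nm: NullModel, x_a: Solution, x_b: Solution,
                 used_a=(), used_b=()) -> OverlapRecord | None:
    """Most promising unused overlap, or None when none has shared nodes.

    Maximizes S(r, s) over r not in ``used_a``, s not in ``used_b`` with a
    non-empty intersection; ties go to the lexicographically smallest (r, s).
    """
    used_a, used_b = set(used_a), set(used_b)
    tau_a, tau_b = x_a.assignment.tau, x_b.assignment.tau
    qa, qb = x_a.assignment.q, x_b.assignment.q
    # contingency counts to skip empty intersections cheaply
    counts = np.zeros((qa, qb), dtype=np.intp)
    np.add.at(counts, (tau_a, tau_b), 1)
    best: OverlapRecord | None = None
    for r in range(qa):
        if r in used_a:
            continue
        for s in range(qb):
            if s in used_b or counts[r, s] == 0:
                continue
            contrib = overlap_contribution(net, nm, x_a, x_b, r, s)
            if best is None or contrib > best.contribution + 1e-12:
                nodes = tuple(np.flatnonzero((tau_a == r) & (tau_b == s)))
                best = OverlapRecord(r, s, nodes, contrib)
    return best


def local_search(net: Network, nm: NullModel, x) -> Solution:
    """Greedy best-improvement single-node reassignment until a local optimum.

    Each pass scans all (node, target-module) moves in index order and applies
    the single best strictly improving one; the block matrix is updated
    incrementally.  The output fitness is never below the input fitness.
    """
    asg = x.assignment if isinstance(x, Solution) else x
    state = QState(net, nm, asg.tau, asg.q)
    moves = 0
    tol = 1e-9
    while True:
        delta, i, b = state.best_move()
        if i < 0 or delta <= tol:
            break
        state.apply(i, b)
        moves += 1
    out = Assignment(tau=state.tau.copy(), q=asg.q)
    return Solution(assignment=out, fitness=fitness(net, nm, out),
                    meta={"method": "local_search", "moves": moves})


def _greedy_place(state: QState, node: int, forbidden: int) -> None:
    """Re-place an evicted node into its best module other than ``forbidden``."""
    v = state.v(node)
    best_b, best_delta = None, -np.inf
    for b in range(state.q):
        if b == forbidden or b == state.tau[node]:
            continue
        delta = state.delta_l1(node, b, v)
        if delta > best_delta + 1e-12:
            best_b, best_delta = b, delta
    if best_b is not None:
        state.apply(node, best_b)


def path_generation(net: Network, nm: NullModel, x_a: Solution, x_b: Solution,
                    n_stop: int = 5) -> Solution:
    """Generate a path of solutions between x_A and x_B; return the best.

    The first overlap is processed unconditionally (the guard starts at
    infinity); thereafter the walk stops when no unused module pair shares
    nodes or when the next most promising overlap has at most ``n_stop``
    nodes.  At most q steps are taken (each consumes one module on each
    side).  Output fitness >= max of the inputs.
    """
    if x_a.assignment.q != x_b.assignment.q:
        raise ValidationError("path generation requires solutions with equal q")
    if n_stop < 0:
        raise ValidationError("n_stop must be >= 0")
    if x_a.assignment.n != x_b.assignment.n:
        raise ValidationError("solutions must cover the same node set")

    x_best = max((x_a, x_b), key=lambda s: s.fitness)
    used_a: set = set()
    used_b: set = set()
    current = x_a
    steps = 0
    over = best_overlap(net, nm, current, x_b, used_a, used_b)
    # guard variable starts at +infinity: the first overlap found is always
    # processed; later overlaps only while larger than n_stop
    while over is not None and (steps == 0 or len(over.nodes) > n_stop):
        # shrink module r_a of the working solution to exactly the overlap
        state = QState(net, nm, current.assignment.tau, current.assignment.q)
        keep = set(over.nodes)
        evicted = [i for i in np.flatnonzero(state.tau == over.r_a) if i not in keep]
        for node in evicted:
            _greedy_place(state, node, forbidden=over.r_a)
        shrunk = Assignment(tau=state.tau.copy(), q=current.assignment.q)
        improved = local_search(net, nm, shrunk)
        if improved.fitness > x_best.fitness:
            x_best = improved
        used_a.add(over.r_a)
        used_b.add(over.s_b)
        current = improved
        steps += 1
        over = best_overlap(net, nm, current, x_b, used_a, used_b)

    meta = {"method": "path_generation", "steps": steps,
            "inputs": (x_a.meta.get("method"), x_b.meta.get("method"))}
    return Solution(assignment=x_best.assignment, fitness=x_best.fitness,
                    meta={**x_best.meta, **meta})
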
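"""Simulated-annealing baseline for the blockmodel objective.

Metropolis sampling on hard assignments maximizing Q*.  The proposal kinds
alternate every ``t_switch`` sweeps (one sweep = N attempted moves) between
single-node reassignments and two-node label swaps between different
modules; both are symmetric proposals.  A move with fitness change dQ* >= 0
is always accepted, otherwise with probability exp(dQ*/T).  The temperature
cools geometrically, T <- c_beta * T, after every ``t_sweep`` sweeps, and the
run stops once T < t_end, returning the best state ever visited.

The defaults reproduce the slow schedule used for full-scale PPI runs;
desk-scale comparisons should pass a lighter schedule (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._state import QState
from .assignment import Assignment, Solution
from .exceptions import ValidationError
from .netio import Network
from .objective import fitness, null_model

__all__ = ["SaParams", "simulated_annealing"]


@dataclass(frozen=True)
class SaParams:
    """Cooling schedule and move-mix parameters.

    c_beta : geometric cooling factor in (0, 1)
    t_start, t_end : initial/final temperature (on the Q* scale)
    t_sweep : sweeps per temperature (each sweep attempts N moves)
    t_switch : sweeps between alternating proposal kinds
    seed : RNG seed (also seeds the random initial assignment)
    """

    c_beta: float = 0.99
    t_start: float = 40.0
    t_end: float = 0.001
    t_sweep: int = 100
    t_switch: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.c_beta < 1.0:
            raise ValidationError("c_beta must lie in (0, 1)")
        if not self.t_start > self.t_end > 0:
            raise ValidationError("require t_start > t_end > 0")
        if self.t_sweep < 1 or self.t_switch < 1:
            raise ValidationError("t_sweep and t_switch must be >= 1")


def simulated_annealing(net: Network, q: int, params: SaParams | None = None,
                        init_tau=None) -> Solution:
    """Anneal a hard assignment; returns the best-ever solution.

    Reproducible given ``params.seed``; the best-ever fitness trace is kept
    in ``meta['best_trace']`` (one entry per temperature).
    """
    params = params or SaParams()
    if not 1 <= q <= net.n:
        raise ValidationError(f"q must be in [1, N={net.n}], got {q}")
    nm = null_model(net)
    rng = np.random.default_rng(params.seed)
    n = net.n
    if init_tau is None:
        init_tau = rng.integers(0, q, size=n)
    state = QState(net, nm, init_tau, q)
    two_m = 2.0 * nm.M

    best_tau = state.tau.copy()
    best_l1 = state.l1
    best_trace = []
    attempts = accepts = 0

    t = params.t_start
    sweep_count = 0
    while t >= params.t_end and q > 1:
        for _ in range(params.t_sweep):
            swap_kind = (sweep_count // params.t_switch) % 2 == 1
            for _ in range(n):
                attempts += 1
                if swap_kind:
                    i, j = rng.integers(0, n, size=2)
                    a, b = state.tau[i], state.tau[j]
                    if i == j or a == b:
                        continue
                    d1 = state.delta_l1(i, b)
                    state.apply(i, b)
                    d2 = state.delta_l1(j, a)
                    dq = (d1 + d2) / two_m
                    if dq >= 0 or rng.random() < np.exp(dq / t):
                        state.apply(j, a)
                        accepts += 1
                    else:
                        state.apply(i, a)  # revert
                else:
                    i = int(rng.integers(0, n))
                    a = state.tau[i]
                    b = int(rng.integers(0, q - 1))
                    if b >= a:
                        b += 1
                    dq = state.delta_l1(i, b) / two_m
                    if dq >= 0 or rng.random() < np.exp(dq / t):
                        state.apply(i, b)
                        accepts += 1
                if state.l1 > best_l1 + 1e-12:
                    best_l1 = state.l1
                    best_tau = state.tau.copy()
            sweep_count += 1
        best_trace.append(best_l1 / two_m)
        t *= params.c_beta

    asg = Assignment(tau=best_tau, q=q)
    return Solution(assignment=asg, fitness=fitness(net, nm, asg),
                    meta={"method": "sa", "seed": params.seed,
                          "attempts": attempts, "accepts": accepts,
                          "best_trace": best_trace})
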
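"""Conditional-subgradient (Frank-Wolfe) solver on the relaxed assignment polytope.

The combinatorial problem max_tau Q*(tau) is recast as the minimization of
``F(S) = -||S^T (W - P) S||_L1`` over the polytope ``gamma`` of row-stochastic
``N x q`` matrices (the convex hull of the hard assignments).  ``F`` is
non-smooth, so the Frank-Wolfe gradient is replaced by a subgradient built
from the elementwise sign of the block matrix Q:

    dF(S) = 2 (P - W) S Qbar,    Qbar_rs = sign(Q_rs), alpha in [-1, 1] at zeros.

Each iteration solves the linear subproblem min_{S in gamma} <dF, S> — a
row-wise argmin, i.e. a semi-linear assignment in O(qN) — then line-searches
along the segment to the chosen vertex.  The final relaxed iterate is rounded
row-wise to a hard assignment.  The method converges to a local stationary
point; solution quality therefore depends on the initialization, which is why
the driver restarts it from several seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assignment import Assignment, Solution
from .exceptions import ValidationError
from .netio import Network
from .objective import NullModel, fitness, xs_product

__all__ = [
    "SgConfig",
    "SgTrace",
    "sign_matrix",
    "subgrad",
    "linear_subproblem",
    "line_search",
    "round_assignment",
    "init_assignment",
    "run_sg",
]

#: golden-section refinement evaluations per line search
_GOLDEN_EVALS = 20
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SgConfig:
    """Solver configuration.

    zeta : stopping tolerance on |dF| + ||dS||_F (normalized F scale)
    max_iter : iteration cap
    alpha : subgradient value for zero entries of Q, in [-1, 1]
    line_search_grid : number of uniform lambda samples in [0, 1]
    """

    zeta: float = 1e-6
    max_iter: int = 500
    alpha: float = 0.0
    line_search_grid: int = 21

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValidationError("zeta must be positive")
        if not -1.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [-1, 1]")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.line_search_grid < 2:
            raise ValidationError("line_search_grid must be >= 2")


@dataclass
class SgTrace:
    """Per-iteration record of the relaxed objective and step sizes."""

    F: list = field(default_factory=list)
    step: list = field(default_factory=list)
    converged: bool = False


def sign_matrix(Q: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    """Elementwise sign of Q with zeros mapped to ``alpha``.

    Satisfies ||Qbar||_Linf <= 1 and <Qbar, Q> = ||Q||_L1 for any alpha.
    """
    if not -1.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [-1, 1]")
    Q = np.asarray(Q)
    return np.where(Q > 0, 1.0, np.where(Q < 0, -1.0, float(alpha)))


def subgrad(net: Network, nm: NullModel, S: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    """Subgradient dF(S) = 2 (P - W) S Qbar of the relaxed objective.

    The diagonal of W - P is zeroed, consistent with all i != j sums.
    """
    XS = xs_product(net, nm, np.asarray(S, dtype=float))
    Qbar = sign_matrix(np.asarray(S).T @ XS, alpha)
    return -2.0 * XS @ Qbar


def linear_subproblem(dF: np.ndarray) -> np.ndarray:
    """Vertex of the polytope minimizing <dF, S>: row-wise argmin.

    Ties go to the smallest module index.  This is the semi-linear
    assignment step of the Frank-Wolfe iteration, O(qN).
    """
    dF = np.asarray(dF)
    S = np.zeros_like(dF, dtype=float)
    S[np.arange(dF.shape[0]), np.argmin(dF, axis=1)] = 1.0
    return S


def _relaxed_F(net, nm, S):
    """Relaxed objective F(S) = -||Q(S)||_L1 / (2M) (normalized scale)."""
    Q = S.T @ xs_product(net, nm, S)
    return -float(np.abs(Q).sum()) / (2.0 * nm.M)


def line_search(net: Network, nm: NullModel, S_cur: np.ndarray, S_new: np.ndarray,
                grid: int = 21):
    """Minimize F along the segment from S_cur to S_new.

    F restricted to the segment is ``-sum |A0 + lam A1 + lam^2 A2|`` for three
    precomputed q x q matrices, so each trial lambda costs O(q^2).  A uniform
    grid including both endpoints is scanned first, then a golden-section
    refinement around the best grid point.  Returns ``(lam, S, F)`` with
    F <= min(F(S_cur), F(S_new)).
    """
    S_cur = np.asarray(S_cur, dtype=float)
    D = np.asarray(S_new, dtype=float) - S_cur
    XS = xs_product(net, nm, S_cur)
    XD = xs_product(net, nm, D)
    A0 = S_cur.T @ XS
    A1 = D.T @ XS + S_cur.T @ XD
    A2 = D.T @ XD
    two_m = 2.0 * nm.M

    def f(lam):
        return -float(np.abs(A0 + lam * A1 + lam * lam * A2).sum()) / two_m

    lams = np.linspace(0.0, 1.0, grid)
    vals = [f(l) for l in lams]
    k = int(np.argmin(vals))
    best_lam, best_val = float(lams[k]), vals[k]

    lo = float(lams[max(k - 1, 0)])
    hi = float(lams[min(k + 1, grid - 1)])
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(_GOLDEN_EVALS - 2):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
        for lam_t, val_t in ((c, fc), (d, fd)):
            if val_t < best_val:
                best_lam, best_val = float(lam_t), val_t

    return best_lam, S_cur + best_lam * D, best_val


def round_assignment(S: np.ndarray) -> Assignment:
    """Hard assignment by row-wise argmax; ties to the smallest index."""
    S = np.asarray(S)
    return Assignment(tau=np.argmax(S, axis=1), q=S.shape[1])


def init_assignment(net: Network, q: int, method: str = "random_hard",
                    seed: int = 0) -> np.ndarray:
    """Seeded starting point on the relaxed polytope.

    random_hard : each node assigned to a uniform random module (one-hot rows)
    random_soft : rows drawn from a symmetric Dirichlet(1)
    degree_stripe : nodes sorted by decreasing degree, dealt round-robin
    """
    if not 1 <= q <= net.n:
        raise ValidationError(f"q must be in [1, N={net.n}], got {q}")
    rng = np.random.default_rng(seed)
    n = net.n
    if method == "random_hard":
        tau = rng.integers(0, q, size=n)
    elif method == "random_soft":
        return rng.dirichlet(np.ones(q), size=n)
    elif method == "degree_stripe":
        order = np.argsort(-net.degrees, kind="stable")
        tau = np.empty(n, dtype=np.intp)
        tau[order] = np.arange(n) % q
    else:
        raise ValidationError(f"unknown init method {method!r}")
    S = np.zeros((n, q))
    S[np.arange(n), tau] = 1.0
    return S


def run_sg(net: Network, nm: NullModel, q: int, init: np.ndarray,
           cfg: SgConfig | None = None, meta: dict | None = None):
    """Run the conditional-subgradient iteration and round the result.

    Returns ``(Solution, SgTrace)``; the solution's fitness is that of the
    rounded *hard* assignment, while the trace records the (non-increasing)
    relaxed objective F.
    """
    cfg = cfg or SgConfig()
    S = np.asarray(init, dtype=float)
    if S.shape != (net.n, q):
        raise ValidationError(f"init must have shape ({net.n}, {q})")
    if not np.allclose(S.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("init rows must sum to 1")

    trace = SgTrace()
    F = _relaxed_F(net, nm, S)
    for _ in range(cfg.max_iter):
        dF = subgrad(net, nm, S, cfg.alpha)
        S_star = linear_subproblem(dF)
        lam, S_next, F_next = line_search(net, nm, S, S_star, cfg.line_search_grid)
        dS = float(np.linalg.norm(S_next - S))
        delta = abs(F_next - F) + dS
        S, F = S_next, F_next
        trace.F.append(F)
        trace.step.append(lam)
        if delta < cfg.zeta:
            trace.converged = True
            break

    asg = round_assignment(S)
    sol = Solution(
        assignment=asg,
        fitness=fitness(net, nm, asg),
        meta={"method": "sg", "iterations": len(trace.F),
              "converged": trace.converged, **(meta or {})},
    )
    return sol, trace
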
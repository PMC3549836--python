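"""Blockmodel scoring core.

A blockmodel summarizes a network ``G`` by a small *image graph* on ``q``
module nodes: a binary ``q x q`` matrix ``B`` stating which modules interact.
Given a hard assignment ``tau`` of nodes to modules, the quality of the
summary is judged against a configuration-style null model in which the
expected weight between nodes ``i`` and ``j`` is

    p_ij = d_i d_j / M,      d_i = sum_k w_ik,   M = sum_{i != j} w_ij.

The block matrix aggregates observed-minus-expected weight per module pair,

    Q_rs = sum_{i != j} (w_ij - p_ij) [tau_i = r][tau_j = s],

and the optimal image graph follows for free: B_rs = 1 exactly when
Q_rs > 0.  After substituting that optimal B, the objective becomes the
normalized L1 fitness

    Q*(tau) = ||Q||_L1 / (2 M),   ||Q||_L1 = sum_{r,s} |Q_rs|,

which lies in [0, 1] and rewards any consistent interaction pattern — dense
modules (positive diagonal of B) and sparse modules that share external
partners (zero diagonal, positive off-diagonal) alike.

The penalty matrix ``P`` is never materialized densely: it is the rank-one
structure ``d d^T / M``, so products with an ``N x q`` matrix cost
``O(qN + q nnz(W))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assignment import Assignment
from .exceptions import ValidationError
from .netio import Network

__all__ = [
    "NullModel",
    "null_model",
    "block_matrix",
    "fitness",
    "image_graph",
    "mismatch_error",
    "fitness_upper_bound",
]


@dataclass(frozen=True, eq=False)
class NullModel:
    """Configuration null model: rank-one penalty matrix p_ij = d_i d_j / M.

    Attributes
    ----------
    degrees : ndarray, shape (N,)
        Weighted degrees d_i.
    M : float
        Total weight over ordered pairs, sum_{i != j} w_ij.
    """

    degrees: np.ndarray
    M: float

    @property
    def n(self) -> int:
        return self.degrees.size

    def p(self, i: int, j: int) -> float:
        """Single penalty entry p_ij (diagonal included; sums skip it)."""
        return float(self.degrees[i] * self.degrees[j] / self.M)

    def p_row(self, i: int) -> np.ndarray:
        return self.degrees[i] * self.degrees / self.M

    def dense_p(self) -> np.ndarray:
        """Full penalty matrix; refused for large N to protect memory."""
        if self.n > 2000:
            raise ValidationError("dense P is only materialized for N <= 2000")
        return np.outer(self.degrees, self.degrees) / self.M


def null_model(net: Network) -> NullModel:
    """Build the configuration null model for a network.

    Raises
    ------
    ValidationError
        If the network has zero total weight (no edges).
    """
    d = net.degrees
    M = float(d.sum())
    if M <= 0:
        raise ValidationError("zero total weight: the null model is undefined")
    return NullModel(degrees=d, M=M)


def _as_S(asg, q: int | None = None) -> np.ndarray:
    """Coerce an Assignment or an (N, q) matrix to a dense float matrix."""
    if isinstance(asg, Assignment):
        return asg.S
    S = np.asarray(asg, dtype=float)
    if S.ndim != 2:
        raise ValidationError("assignment matrix must be 2-d")
    if q is not None and S.shape[1] != q:
        raise ValidationError(f"expected {q} modules, got {S.shape[1]}")
    return S


def xs_product(net: Network, nm: NullModel, S: np.ndarray) -> np.ndarray:
    """Compute ``X @ S`` where ``X = W - P`` with its diagonal zeroed.

    Because w_ii = 0 the diagonal of ``W - P`` is ``-d_i^2/M``; zeroing it
    adds the correction ``diag(d_i^2/M)``, keeping the product rank-one
    cheap: ``X S = W S - d (d^T S)/M + (d^2/M) * S``.
    """
    d, M = nm.degrees, nm.M
    return net.weights @ S - np.outer(d, d @ S) / M + (d * d / M)[:, None] * S


def block_matrix(net: Network, nm: NullModel, asg) -> np.ndarray:
    """Block matrix Q = S^T (W - P) S with i = j pairs excluded.

    Accepts a hard :class:`Assignment` or any relaxed ``N x q`` matrix with
    rows on the simplex; returns a dense ``q x q`` array (symmetric for
    symmetric inputs).
    """
    S = _as_S(asg)
    if S.shape[0] != net.n:
        raise ValidationError("assignment length does not match network size")
    return S.T @ xs_product(net, nm, S)


def fitness(net: Network, nm: NullModel, asg) -> float:
    """Normalized blockmodel fitness Q* = ||Q||_L1 / (2M)."""
    return float(np.abs(block_matrix(net, nm, asg)).sum() / (2.0 * nm.M))


def image_graph(Q: np.ndarray) -> np.ndarray:
    """Optimal binary image graph: B_rs = 1 iff Q_rs > 0 (strict)."""
    return (np.asarray(Q) > 0).astype(np.int8)


def mismatch_error(net: Network, nm: NullModel, asg: Assignment, B: np.ndarray) -> float:
    """Null-corrected mismatch between the network and an image graph.

    E = (1/M) sum_{i != j} (A_ij - B_{tau_i tau_j}) (w_ij - p_ij), with
    A_ij the unweighted adjacency indicator.  E = 0 whenever B reproduces
    the adjacency pattern exactly through tau.
    """
    B = np.asarray(B)
    if B.shape != (asg.q, asg.q):
        raise ValidationError(f"image graph must be {asg.q} x {asg.q}, got {B.shape}")
    W = net.weights.tocoo()
    # sum over ordered pairs with A_ij = 1 of (w_ij - p_ij); coo has no diagonal
    term_a = float(W.data.sum() - (nm.degrees[W.row] * nm.degrees[W.col]).sum() / nm.M)
    Q = block_matrix(net, nm, asg)
    term_b = float((B * Q).sum())
    return (term_a - term_b) / nm.M


def fitness_upper_bound(net: Network, nm: NullModel) -> float:
    """Fitness of the identity assignment (one node per module).

    Merging modules never increases ||Q||_L1 (triangle inequality), so this
    value, sum_{i != j} |w_ij - p_ij| / (2M), bounds Q*(tau) for every tau.
    Computed in O(nnz) without forming P.
    """
    W = net.weights.tocoo()
    d, M = nm.degrees, nm.M
    p_nz = d[W.row] * d[W.col] / M
    nz_part = float(np.abs(W.data - p_nz).sum())
    # zero-weight off-diagonal pairs contribute p_ij each:
    # sum_{i != j} p_ij - sum_{nonzero} p_ij
    zero_part = float(M - (d * d).sum() / M - p_nz.sum())
    return (nz_part + zero_part) / (2.0 * M)
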
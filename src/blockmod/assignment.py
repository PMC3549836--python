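"""Hard module assignments and scored solutions.

A hard assignment maps each of the ``N`` network nodes to exactly one of
``q`` modules.  It is carried both as a label vector ``tau`` (0-based module
indices) and, on demand, as the one-hot matrix ``S`` whose rows sum to one.
Modules may be empty: ``q`` is an upper bound on the number of occupied
modules, not a promise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


@dataclass(frozen=True, eq=False)
class Assignment:
    """Hard node-to-module map ``tau`` with module count ``q``.

    Parameters
    ----------
    tau : ndarray of int, shape (N,)
        Module index of each node, values in ``[0, q)``.
    q : int
        Number of modules (columns of the one-hot matrix ``S``).
    """

    tau: np.ndarray
    q: int

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=np.intp)
        object.__setattr__(self, "tau", tau)
        if tau.ndim != 1 or tau.size == 0:
            raise ValidationError("tau must be a non-empty 1-d integer array")
        if self.q < 1:
            raise ValidationError(f"q must be >= 1, got {self.q}")
        if tau.min() < 0 or tau.max() >= self.q:
            raise ValidationError("module indices must lie in [0, q)")

    @property
    def n(self) -> int:
        return self.tau.size

    @property
    def S(self) -> np.ndarray:
        """One-hot N x q assignment matrix (float, rows sum to 1)."""
        S = np.zeros((self.n, self.q))
        S[np.arange(self.n), self.tau] = 1.0
        return S

    @classmethod
    def from_matrix(cls, S: np.ndarray) -> "Assignment":
        """Build from a hard one-hot matrix by row-wise argmax."""
        S = np.asarray(S)
        return cls(tau=np.argmax(S, axis=1), q=S.shape[1])

    def module_nodes(self, r: int) -> np.ndarray:
        """Indices of the nodes assigned to module ``r``."""
        if not 0 <= r < self.q:
            raise ValidationError(f"module index {r} out of range for q={self.q}")
        return np.flatnonzero(self.tau == r)

    def module_sizes(self) -> np.ndarray:
        """Occupancy of every module (length q, zeros allowed)."""
        return np.bincount(self.tau, minlength=self.q)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Assignment):
            return NotImplemented
        return self.q == other.q and np.array_equal(self.tau, other.tau)


@dataclass(eq=False)
class Solution:
    """An assignment together with its normalized blockmodel fitness Q*.

    ``fitness`` always equals the fitness recomputed from ``assignment`` on
    the originating network; provenance (seed, method, iteration counts) is
    kept in ``meta``.
    """

    assignment: Assignment
    fitness: float
    meta: dict = field(default_factory=dict)

    @property
    def tau(self) -> np.ndarray:
        return self.assignment.tau

    @property
    def q(self) -> int:
        return self.assignment.q
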
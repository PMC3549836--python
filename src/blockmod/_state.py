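"""Incrementally maintained block matrix under single-node moves.

Shared engine for the greedy local search and the simulated-annealing
baseline.  For a hard assignment tau it keeps

    Q  = S^T X S          (q x q, X = W - P with zero diagonal)
    A  = S^T W            (q x N, sparse-row updates)
    Dm = S^T d            (q,)

Moving node i from module a to b is a rank-two update
``Q <- Q + (e_b - e_a) v^T + v (e_b - e_a)^T`` with
``v_s = sum_{j != i, tau_j = s} X_ij``, obtained in O(q) from A and Dm;
updating A costs O(deg(i)).  The L1 change of a candidate move is evaluated
without applying it.
"""

from __future__ import annotations

import numpy as np

from .objective import xs_product


class QState:
    """Mutable assignment state with O(q + deg) move evaluation/application."""

    def __init__(self, net, nm, tau, q):
        self.net = net
        self.nm = nm
        self.q = int(q)
        self.tau = np.asarray(tau, dtype=np.intp).copy()
        self.d = nm.degrees
        self.M = nm.M
        n = net.n
        S = np.zeros((n, self.q))
        S[np.arange(n), self.tau] = 1.0
        W = net.weights
        self.A = (W.T @ S).T.copy()          # q x N; W symmetric
        self.Dm = S.T @ self.d               # q,
        self.Q = S.T @ xs_product(net, nm, S)
        # per-node sparse neighborhoods for O(deg) updates
        csr = W.tocsr()
        self._indptr = csr.indptr
        self._indices = csr.indices
        self._data = csr.data
        self.l1 = float(np.abs(self.Q).sum())

    # -- geometry ---------------------------------------------------------
    def v(self, i: int) -> np.ndarray:
        """v_s = sum over j != i in module s of X_ij (module profile of node i)."""
        v = self.A[:, i] - self.Dm * (self.d[i] / self.M)
        v[self.tau[i]] += self.d[i] ** 2 / self.M
        return v

    def profile_matrix(self) -> np.ndarray:
        """All v vectors at once: column i is v(i).  O(qN)."""
        V = self.A - np.outer(self.Dm, self.d) / self.M
        V[self.tau, np.arange(self.net.n)] += self.d**2 / self.M
        return V

    # -- move evaluation --------------------------------------------------
    def delta_l1(self, i: int, b: int, v: np.ndarray | None = None) -> float:
        """Change in ||Q||_L1 if node i moved to module b (not applied)."""
        a = self.tau[i]
        if b == a:
            return 0.0
        if v is None:
            v = self.v(i)
        Q = self.Q
        mask = np.ones(self.q, dtype=bool)
        mask[[a, b]] = False
        da = np.abs(Q[a] - v) - np.abs(Q[a])
        db = np.abs(Q[b] + v) - np.abs(Q[b])
        delta = 2.0 * (da[mask].sum() + db[mask].sum())
        delta += abs(Q[a, a] - 2 * v[a]) - abs(Q[a, a])
        delta += abs(Q[b, b] + 2 * v[b]) - abs(Q[b, b])
        delta += 2.0 * (abs(Q[a, b] + v[a] - v[b]) - abs(Q[a, b]))
        return float(delta)

    def apply(self, i: int, b: int) -> None:
        """Move node i to module b, updating Q, A, Dm and the cached L1."""
        a = self.tau[i]
        if b == a:
            return
        v = self.v(i)
        Q = self.Q
        Q[a] -= v
        Q[b] += v
        Q[:, a] -= v
        Q[:, b] += v
        lo, hi = self._indptr[i], self._indptr[i + 1]
        nbr, w = self._indices[lo:hi], self._data[lo:hi]
        self.A[a, nbr] -= w
        self.A[b, nbr] += w
        self.Dm[a] -= self.d[i]
        self.Dm[b] += self.d[i]
        self.tau[i] = b
        self.l1 = float(np.abs(Q).sum())

    def best_move(self):
        """Best single-node move over all (node, module) pairs.

        Returns ``(delta_l1, node, module)``; ties resolved by smallest node
        index then smallest module index (scan order).
        """
        V = self.profile_matrix()
        best = (0.0, -1, -1)
        for i in range(self.net.n):
            a = self.tau[i]
            v = V[:, i]
            Q = self.Q
            da = np.abs(Q[a] - v) - np.abs(Q[a])       # row-a change per column
            E = np.abs(Q + v[None, :]) - np.abs(Q)     # row-b change per (b, s)
            da_sum = da.sum()
            for b in range(self.q):
                if b == a:
                    continue
                delta = 2.0 * (da_sum - da[a] - da[b])
                delta += 2.0 * (E[b].sum() - E[b, a] - E[b, b])
                delta += abs(Q[a, a] - 2 * v[a]) - abs(Q[a, a])
                delta += abs(Q[b, b] + 2 * v[b]) - abs(Q[b, b])
                delta += 2.0 * (abs(Q[a, b] + v[a] - v[b]) - abs(Q[a, b]))
                if delta > best[0]:
                    best = (float(delta), i, b)
        return best

    def fitness(self) -> float:
        """Normalized fitness Q* of the current assignment."""
        return self.l1 / (2.0 * self.M)
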
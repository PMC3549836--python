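"""Planted-blockmodel network generator with ground truth.

Instances are drawn from a stochastic blockmodel: nodes are split into q
modules of given sizes, and each unordered pair {i, j} (i != j) carries a
unit-weight edge independently with probability ``density[tau_i][tau_j]``.
Diagonal densities control within-module wiring, off-diagonal densities the
between-module wiring, so both densely connected modules (positive image-
graph diagonal) and sparsely connected modules sharing external partners
(zero diagonal) can be planted.  Edges have unit weight, matching binary
adjacency inputs, and M equals twice the generated edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assignment import Assignment
from .exceptions import ValidationError
from .netio import Network

__all__ = ["PlantedSpec", "PlantedInstance", "generate", "presets"]

_PRESETS = ("two_cliques", "bipartite", "ring", "star")


@dataclass(frozen=True)
class PlantedSpec:
    """Module sizes, symmetric q x q edge-probability matrix, and a seed."""

    sizes: tuple
    density: np.ndarray
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        D = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", D)
        q = len(sizes)
        if q < 1 or any(s < 1 for s in sizes):
            raise ValidationError("sizes must be a non-empty list of positive ints")
        if D.shape != (q, q):
            raise ValidationError(f"density must be {q} x {q}")
        if (D < 0).any() or (D > 1).any():
            raise ValidationError("densities must lie in [0, 1]")
        if not np.allclose(D, D.T):
            raise ValidationError("density matrix must be symmetric")

    @property
    def q(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True, eq=False)
class PlantedInstance:
    """Generated network plus its ground-truth assignment and spec."""

    network: Network
    truth: Assignment
    spec: PlantedSpec


def generate(spec: PlantedSpec) -> PlantedInstance:
    """Draw a planted-blockmodel instance; reproducible given the seed.

    Isolated nodes are permitted (callers may apply ``largest_component``).
    """
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n, spec.q
    tau = np.repeat(np.arange(q), spec.sizes)
    iu, ju = np.triu_indices(n, k=1)
    p = spec.density[tau[iu], tau[ju]]
    mask = rng.random(p.size) < p
    labels = [f"v{i + 1}" for i in range(n)]
    pairs = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    net = Network.from_edges(labels, pairs, [1.0] * len(pairs))
    return PlantedInstance(network=net, truth=Assignment(tau=tau, q=q), spec=spec)


def _preset_density(name: str, q: int, p_on: float, p_off: float) -> np.ndarray:
    B = np.full((q, q), False)
    if name == "two_cliques":
        if q != 2:
            raise ValidationError("two_cliques requires q = 2")
        np.fill_diagonal(B, True)
    elif name == "bipartite":
        if q != 2:
            raise ValidationError("bipartite requires q = 2")
        B[0, 1] = B[1, 0] = True
    elif name == "ring":
        if q < 3:
            raise ValidationError("ring requires q >= 3")
        for r in range(q):
            B[r, (r + 1) % q] = B[(r + 1) % q, r] = True
    elif name == "star":
        if q < 2:
            raise ValidationError("star requires q >= 2")
        B[0, 1:] = B[1:, 0] = True
    else:
        raise ValidationError(f"unknown preset {name!r}; choose from {_PRESETS}")
    return np.where(B, p_on, p_off)


def presets(name: str, n_per_module: int, q: int, p_on: float, p_off: float = 0.0,
            seed: int = 0) -> PlantedInstance:
    """Named image-graph families: two_cliques, bipartite, ring, star.

    Pairs on image-graph edges get probability ``p_on``, all others
    (including within-module pairs when the image diagonal is zero) ``p_off``.
    """
    density = _preset_density(name, q, p_on, p_off)
    spec = PlantedSpec(sizes=(n_per_module,) * q, density=density, seed=seed)
    return generate(spec)
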
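"""Read, write and canonicalize weighted undirected networks.

Supported inputs are plain-text edge lists: TSV/whitespace files with two or
three columns (``node_a  node_b  [weight]``, missing weight = 1.0, ``#``
comments skipped) and SIF files (``node_a  relation  node_b``, weight 1.0).
Networks are undirected with non-negative weights and no self-loops; node
order is first-appearance order and all matrices are indexed in that order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .assignment import Assignment, Solution
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "read_network",
    "largest_component",
    "write_solution",
    "read_assignment",
]


@dataclass(frozen=True, eq=False)
class Network:
    """Undirected weighted network.

    Attributes
    ----------
    node_labels : tuple of str
        Unique labels, in first-appearance order.
    weights : scipy.sparse.csr_array
        Symmetric non-negative N x N weight matrix with zero diagonal.
    """

    node_labels: tuple
    weights: sp.csr_array

    def __post_init__(self):
        W = sp.csr_array(self.weights, dtype=float)
        W.eliminate_zeros()
        object.__setattr__(self, "weights", W)
        n = len(self.node_labels)
        if W.shape != (n, n):
            raise ValidationError("weight matrix shape does not match labels")
        if len(set(self.node_labels)) != n:
            raise ValidationError("node labels must be unique")
        if W.diagonal().any():
            raise ValidationError("self-loops (non-zero diagonal) are not allowed")
        if (W.data < 0).any():
            raise ValidationError("negative edge weights are not allowed")
        if abs(W - W.T).sum() > 1e-12 * max(1.0, abs(W).sum()):
            raise ValidationError("weight matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def edge_count(self) -> int:
        """Number of unordered pairs with positive weight."""
        return int(self.weights.nnz // 2)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree vector d_i = sum_j w_ij."""
        return np.asarray(self.weights.sum(axis=1)).ravel()

    @property
    def total_weight(self) -> float:
        """M = sum over ordered pairs i != j of w_ij (twice the edge weight sum)."""
        return float(self.degrees.sum())

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown node label {label!r}") from None

    def _label_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.node_labels)}

    @classmethod
    def from_edges(cls, labels, pairs, weights) -> "Network":
        """Build a Network from unordered node-index pairs with weights."""
        n = len(labels)
        if pairs:
            rows = [p[0] for p in pairs] + [p[1] for p in pairs]
            cols = [p[1] for p in pairs] + [p[0] for p in pairs]
            data = list(weights) * 2
        else:
            rows, cols, data = [], [], []
        W = sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()
        return cls(node_labels=tuple(labels), weights=W)

    @classmethod
    def from_dense(cls, W, labels=None) -> "Network":
        W = np.asarray(W, dtype=float)
        if labels is None:
            labels = [f"v{i + 1}" for i in range(W.shape[0])]
        return cls(node_labels=tuple(labels), weights=sp.csr_array(W))

    def induced(self, nodes) -> "Network":
        """Induced subnetwork on a node-index subset (original order kept)."""
        idx = np.sort(np.asarray(nodes, dtype=np.intp))
        W = self.weights[idx][:, idx]
        return Network(node_labels=tuple(self.node_labels[i] for i in idx), weights=W)


def _parse_line(line, lineno, fmt):
    parts = line.split()
    if fmt == "sif":
        if len(parts) != 3:
            raise ParseError(f"line {lineno}: SIF lines need 3 fields, got {len(parts)}")
        return parts[0], parts[2], 1.0
    if len(parts) not in (2, 3):
        raise ParseError(f"line {lineno}: expected 2 or 3 fields, got {len(parts)}")
    w = 1.0
    if len(parts) == 3:
        try:
            w = float(parts[2])
        except ValueError:
            raise ParseError(f"line {lineno}: weight {parts[2]!r} is not a number") from None
        if not np.isfinite(w):
            raise ParseError(f"line {lineno}: weight must be finite")
        if w < 0:
            raise ValidationError(f"line {lineno}: negative weight {w}")
    return parts[0], parts[1], w


def read_network(path, format: str | None = None) -> Network:
    """Read an edge-list network file.

    Duplicate node pairs are merged by summing their weights and self-loops
    are dropped; both trigger one logged warning per file.  Node order is
    first-appearance order.
    """
    path = Path(path)
    fmt = format or ("sif" if path.suffix.lower() == ".sif" else "tsv")
    if fmt not in ("tsv", "sif"):
        raise ValidationError(f"unknown format {fmt!r}")

    order: dict = {}
    accum: dict = {}
    dup = loops = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        a, b, w = _parse_line(line, lineno, fmt)
        for lab in (a, b):
            if lab not in order:
                order[lab] = len(order)
        if a == b:
            loops += 1
            continue
        key = (min(order[a], order[b]), max(order[a], order[b]))
        if key in accum:
            dup += 1
        accum[key] = accum.get(key, 0.0) + w
    if not order:
        raise ValidationError(f"{path}: empty network file")
    if dup:
        logger.warning("%s: merged %d duplicate edge record(s) by summing weights", path, dup)
    if loops:
        logger.warning("%s: dropped %d self-loop(s)", path, loops)
    if len(order) < 2:
        raise ValidationError(f"{path}: fewer than 2 nodes after cleaning")
    labels = sorted(order, key=order.get)
    return Network.from_edges(labels, list(accum), list(accum.values()))


def largest_component(net: Network) -> Network:
    """Induced subnetwork on the largest connected component.

    Size ties are broken in favour of the component containing the smallest
    node index.
    """
    ncomp, comp = connected_components(net.weights, directed=False)
    if ncomp == 1:
        return net
    sizes = np.bincount(comp, minlength=ncomp)
    best = sizes.max()
    # first node (smallest index) whose component has maximal size
    winner = comp[np.flatnonzero(sizes[comp] == best)[0]]
    return net.induced(np.flatnonzero(comp == winner))


def write_solution(sol: Solution, net: Network, out_prefix) -> dict:
    """Write a solution as ``<prefix>.assignment.tsv``, ``<prefix>.image.tsv``
    and ``<prefix>.meta.json``.

    Module ids are written 1-based.  Returns the mapping of artifact kind to
    path.  The assignment/image files round-trip through
    :func:`read_assignment` and plain TSV reading.
    """
    from .objective import block_matrix, image_graph, null_model  # local: avoid cycle

    asg = sol.assignment
    if asg.n != net.n:
        raise ValidationError(
            f"assignment length {asg.n} does not match network size {net.n}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignment": out_prefix.with_suffix(".assignment.tsv"),
        "image": out_prefix.with_suffix(".image.tsv"),
        "meta": out_prefix.with_suffix(".meta.json"),
    }
    lines = [f"#q={asg.q}", "#node\tmodule"]
    lines += [f"{lab}\t{asg.tau[i] + 1}" for i, lab in enumerate(net.node_labels)]
    paths["assignment"].write_text("\n".join(lines) + "\n")

    B = image_graph(block_matrix(net, null_model(net), asg))
    head = "\t".join(["#module"] + [str(r + 1) for r in range(asg.q)])
    rows = [head] + [
        "\t".join([str(r + 1)] + [str(int(B[r, s])) for s in range(asg.q)])
        for r in range(asg.q)
    ]
    paths["image"].write_text("\n".join(rows) + "\n")

    meta = {"q": asg.q, "n": net.n, "fitness": sol.fitness, **sol.meta}
    paths["meta"].write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return paths


def read_assignment(path, net: Network) -> Assignment:
    """Read a ``node<TAB>module`` TSV written by :func:`write_solution`.

    A ``#q=<int>`` header, when present, preserves trailing empty modules so
    that write/read round-trips exactly.
    """
    index = net._label_index()
    tau = np.full(net.n, -1, dtype=np.intp)
    qmax = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#q="):
                qmax = max(qmax, int(line[3:]))
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'node<TAB>module'")
        lab, mod = parts
        if lab not in index:
            raise ValidationError(f"line {lineno}: node {lab!r} not in network")
        try:
            m = int(mod)
        except ValueError:
            raise ParseError(f"line {lineno}: module id {mod!r} is not an integer") from None
        if m < 1:
            raise ValidationError(f"line {lineno}: module ids are 1-based positive")
        tau[index[lab]] = m - 1
        qmax = max(qmax, m)
    if (tau < 0).any():
        missing = [net.node_labels[i] for i in np.flatnonzero(tau < 0)][:5]
        raise ValidationError(f"assignment missing nodes, e.g. {missing}")
    return Assignment(tau=tau, q=qmax)
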
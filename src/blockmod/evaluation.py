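"""Partition-comparison and module-topology metrics.

Covers the sparse-module analyses: per-module interaction density, counting
modules below a density threshold (the signature of sparsely connected
modules), the Watts-Strogatz clustering coefficient of induced subnetworks,
and permutation-invariant partition similarity (NMI / ARI) for planted-
recovery scoring.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .assignment import Assignment
from .exceptions import ValidationError
from .netio import Network

__all__ = [
    "module_density",
    "sparse_module_count",
    "avg_clustering",
    "compare_assignments",
    "module_stats",
]


def _internal_edges(net: Network, nodes: np.ndarray) -> int:
    sub = net.weights[nodes][:, nodes]
    return int(sub.nnz // 2)


def module_density(net: Network, asg: Assignment, r: int) -> float:
    """Internal edge count over C(n_r, 2); singletons have density 0."""
    nodes = asg.module_nodes(r)
    if nodes.size == 0:
        raise ValidationError(f"module {r} is empty")
    if nodes.size == 1:
        return 0.0
    return _internal_edges(net, nodes) / math.comb(nodes.size, 2)


def sparse_module_count(net: Network, asg: Assignment, threshold: float = 0.03) -> int:
    """Number of modules with >= 2 nodes and density strictly below threshold."""
    count = 0
    for r in range(asg.q):
        nodes = asg.module_nodes(r)
        if nodes.size >= 2 and _internal_edges(net, nodes) / math.comb(nodes.size, 2) < threshold:
            count += 1
    return count


def avg_clustering(net: Network, nodes) -> float:
    """Mean Watts-Strogatz local clustering coefficient on an induced subgraph.

    Nodes with induced degree < 2 contribute 0 to the mean.
    """
    nodes = np.asarray(list(nodes), dtype=np.intp)
    if nodes.size == 0:
        raise ValidationError("node subset must be non-empty")
    sub = net.weights[nodes][:, nodes]
    g = nx.from_scipy_sparse_array(sub)
    return float(nx.average_clustering(g))


def compare_assignments(a: Assignment, b: Assignment) -> dict:
    """NMI (arithmetic normalization) and adjusted Rand index.

    Both scores are invariant under module relabeling; NMI is 0 when either
    partition is a single block (zero entropy).
    """
    if a.n != b.n:
        raise ValidationError("assignments must have equal length")
    return {
        "nmi": float(normalized_mutual_info_score(a.tau, b.tau,
                                                  average_method="arithmetic")),
        "ari": float(adjusted_rand_score(a.tau, b.tau)),
    }


def module_stats(net: Network, asg: Assignment, sparse_threshold: float = 0.03) -> dict:
    """Per-module and network-level topology summary.

    Returns per-module size/internal-edge/density records (occupied modules
    only), the over-modules average density, the sparse-module count at the
    threshold, and the average clustering coefficient over all assigned nodes.
    """
    per_module = []
    for r in range(asg.q):
        nodes = asg.module_nodes(r)
        if nodes.size == 0:
            continue
        density = 0.0 if nodes.size < 2 else \
            _internal_edges(net, nodes) / math.comb(nodes.size, 2)
        per_module.append({"module": r, "size": int(nodes.size),
                           "internal_edges": _internal_edges(net, nodes),
                           "density": density})
    densities = [m["density"] for m in per_module]
    return {
        "per_module": per_module,
        "n_modules": len(per_module),
        "avg_density": float(np.mean(densities)) if densities else 0.0,
        "sparse_modules": sparse_module_count(net, asg, sparse_threshold),
        "sparse_threshold": sparse_threshold,
        "avg_clustering": avg_clustering(net, np.arange(net.n)),
    }
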
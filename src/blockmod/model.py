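"""Model/Results facade over the blockmodel machinery.

``BlockModel`` bundles a network with a module budget q; ``fit`` dispatches
to the SGPG pipeline, a single subgradient run, or the simulated-annealing
baseline, and returns a ``BlockModelResults`` carrying the assignment, its
fitness, the derived image graph, diagnostics and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np

from . import netio
from .annealing import SaParams, simulated_annealing
from .assignment import Assignment, Solution
from .driver import SgpgConfig, run_sgpg
from .evaluation import compare_assignments, module_stats
from .exceptions import ValidationError
from .netio import Network
from .objective import (block_matrix, fitness, fitness_upper_bound,
                        image_graph, null_model)
from .subgradient import SgConfig, init_assignment, run_sg

__all__ = ["BlockModel", "BlockModelResults"]


class BlockModel:
    """Blockmodel of a weighted undirected network with q modules.

    Parameters
    ----------
    network : Network
        The observed network (at least one edge).
    q : int
        Number of modules in the image graph (an upper bound; modules may
        come back empty).
    """

    def __init__(self, network: Network, q: int):
        if not 1 <= q <= network.n:
            raise ValidationError(f"q must be in [1, N={network.n}], got {q}")
        self.network = network
        self.q = q
        self.null = null_model(network)

    @classmethod
    def from_edgelist(cls, path, q: int, format: str | None = None,
                      largest_component: bool = False) -> "BlockModel":
        """Build from a TSV/SIF edge-list file."""
        net = netio.read_network(path, format=format)
        if largest_component:
            net = netio.largest_component(net)
        return cls(net, q)

    @classmethod
    def from_dense(cls, weights, q: int, labels=None) -> "BlockModel":
        """Build from a dense symmetric weight matrix."""
        return cls(Network.from_dense(weights, labels), q)

    def score(self, asg: Assignment) -> float:
        """Normalized fitness Q* of an arbitrary assignment."""
        return fitness(self.network, self.null, asg)

    def fit(self, method: str = "sgpg", seed: int = 0, n_set: int = 10,
            n_stop: int = 5, init_method: str = "random_hard",
            sg_config: SgConfig | None = None,
            sa_params: SaParams | None = None) -> "BlockModelResults":
        """Optimize the assignment; method is 'sgpg', 'sg' or 'sa'."""
        if method == "sgpg":
            cfg = SgpgConfig(q=self.q, n_set=n_set, n_stop=n_stop, base_seed=seed,
                             init_method=init_method, sg=sg_config or SgConfig())
            sol, report = run_sgpg(self.network, cfg)
        elif method == "sg":
            init = init_assignment(self.network, self.q, init_method, seed)
            sol, trace = run_sg(self.network, self.null, self.q, init,
                                sg_config or SgConfig(), meta={"seed": seed})
            report = {"q": self.q, "fitness": sol.fitness,
                      "iterations": sol.meta["iterations"],
                      "converged": sol.meta["converged"], "trace": trace}
        elif method == "sa":
            params = sa_params or SaParams(seed=seed)
            sol = simulated_annealing(self.network, self.q, params)
            report = {"q": self.q, "fitness": sol.fitness,
                      "attempts": sol.meta["attempts"]}
        else:
            raise ValidationError(f"unknown method {method!r}")
        return BlockModelResults(self, sol, report, method)


class BlockModelResults:
    """Fitted blockmodel: assignment, fitness, image graph and diagnostics."""

    def __init__(self, model: BlockModel, solution: Solution, report: dict,
                 method: str):
        self.model = model
        self.solution = solution
        self.report = report
        self.method = method

    # -- estimates --------------------------------------------------------
    @property
    def assignment(self) -> Assignment:
        return self.solution.assignment

    @property
    def tau(self) -> np.ndarray:
        return self.solution.tau

    @property
    def fitness(self) -> float:
        """Normalized blockmodel fitness Q* in [0, 1]."""
        return self.solution.fitness

    @property
    def block_matrix(self) -> np.ndarray:
        return block_matrix(self.model.network, self.model.null, self.assignment)

    @property
    def image_graph(self) -> np.ndarray:
        """Derived q x q binary image graph B (B_rs = 1 iff Q_rs > 0)."""
        return image_graph(self.block_matrix)

    def modules(self) -> list:
        """Node labels per occupied module, in module order."""
        labels = self.model.network.node_labels
        return [[labels[i] for i in self.assignment.module_nodes(r)]
                for r in range(self.assignment.q)
                if self.assignment.module_nodes(r).size]

    # -- diagnostics ------------------------------------------------------
    def stats(self, sparse_threshold: float = 0.03) -> dict:
        return module_stats(self.model.network, self.assignment, sparse_threshold)

    def compare_to(self, truth: Assignment) -> dict:
        """NMI/ARI against a reference partition (e.g. planted truth)."""
        return compare_assignments(self.assignment, truth)

    def to_files(self, out_prefix) -> dict:
        return netio.write_solution(self.solution, self.model.network, out_prefix)

    def plot_trace(self, ax=None):
        """Plot the relaxed-objective trace of a single-SG fit."""
        import matplotlib.pyplot as plt

        trace = self.report.get("trace")
        if trace is None:
            raise ValidationError("trace plotting requires method='sg'")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(1, len(trace.F) + 1), trace.F, marker="o")
        ax.set_xlabel("iteration")
        ax.set_ylabel("relaxed objective F")
        return ax

    def plot_image_graph(self, ax=None):
        """Matrix view of the derived image graph."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.matshow(self.image_graph, cmap="Greys", vmin=0, vmax=1)
        ax.set_xlabel("module")
        ax.set_ylabel("module")
        return ax

    def summary(self, sparse_threshold: float = 0.03) -> str:
        """Human-readable fit report."""
        net, asg = self.model.network, self.assignment
        stats = self.stats(sparse_threshold)
        ub = fitness_upper_bound(net, self.model.null)
        B = self.image_graph
        lines = [
            "Blockmodel fit",
            "=" * 46,
            f"nodes                {net.n}",
            f"edges                {net.edge_count}",
            f"method               {self.method}",
            f"q (budget)           {asg.q}",
            f"occupied modules     {stats['n_modules']}",
            f"fitness Q*           {self.fitness:.4f}",
            f"identity upper bound {ub:.4f}",
            f"avg module density   {stats['avg_density']:.4f}",
            f"sparse modules (<{sparse_threshold:.0%}) {stats['sparse_modules']}",
            "",
            "module  size  int.edges  density",
        ]
        for m in stats["per_module"]:
            lines.append(f"{m['module'] + 1:>6}  {m['size']:>4}  "
                         f"{m['internal_edges']:>9}  {m['density']:>7.4f}")
        lines += ["", "image graph B (1 = modules interact):"]
        for r in range(asg.q):
            lines.append("  " + " ".join(str(int(B[r, s])) for s in range(asg.q)))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<BlockModelResults method={self.method!r} q={self.assignment.q} "
                f"fitness={self.fitness:.4f}>")
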
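"""Markov clustering (MCL) of weighted protein-similarity graphs.

Dense from-scratch implementation of the classic flow-simulation algorithm:
column-normalize the (self-looped) adjacency matrix, then alternate expansion
(matrix power), inflation (elementwise power + column renormalization), and
pruning until the matrix stops changing. Clusters are read off the attractor
structure of the converged flow matrix. Intended problem sizes are the
10^2-10^3 transporter sequences typical of comparative-genomics surveys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["MCLConfig", "MCLResult", "mcl_cluster", "mcl_iterate", "cluster_labels"]


class InvalidGraphError(ValueError):
    pass


class NumericalDegeneracyError(ArithmeticError):
    pass


@dataclass
class MCLConfig:
    inflation: float = 2.0
    expansion: int = 2
    self_loop: str | float = "max_edge"  # "max_edge" or a constant weight
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class MCLResult:
    partition: dict[str, int]  # node -> cluster index (0 = largest)
    labels: dict[str, str]  # node -> "MCL1"... / "MCLnull" for singletons
    converged: bool
    n_iterations: int


def _as_matrix(graph, cfg: MCLConfig):
    """Canonically ordered nodes + symmetric weight matrix with self-loops."""
    if isinstance(graph, nx.Graph):
        nodes = sorted(graph.nodes())
        idx = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for u, v, data in graph.edges(data=True):
            w = float(data.get("weight", 1.0))
            if w <= 0 or not np.isfinite(w):
                raise InvalidGraphError(f"non-positive or non-finite weight on ({u}, {v})")
            W[idx[u], idx[v]] = W[idx[v], idx[u]] = w
    else:
        W = np.asarray(graph, dtype=float)
        if W.shape[0] != W.shape[1] or not np.allclose(W, W.T):
            raise InvalidGraphError("matrix input must be square and symmetric")
        if (W < 0).any():
            raise InvalidGraphError("negative weights")
        nodes = [str(i) for i in range(W.shape[0])]
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    if len(nodes) == 0:
        raise InvalidGraphError("empty graph")
    if cfg.self_loop == "max_edge":
        loops = W.max(axis=1)
        loops[loops == 0] = 1.0  # isolated node still needs a loop
    else:
        loops = np.full(len(nodes), float(cfg.self_loop))
    np.fill_diagonal(W, loops)
    return nodes, W


def _normalize(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0)
    if (colsum == 0).any():
        raise NumericalDegeneracyError("column sums to zero after pruning")
    return M / colsum


def mcl_iterate(M: np.ndarray, cfg: MCLConfig | None = None) -> np.ndarray:
    """One expansion + inflation + prune step on a column-stochastic matrix."""
    cfg = cfg or MCLConfig()
    M = np.linalg.matrix_power(M, cfg.expansion)
    M = _normalize(M**cfg.inflation)
    M[M < cfg.prune_threshold] = 0.0
    return _normalize(M)


def mcl_cluster(graph, cfg: MCLConfig | None = None) -> MCLResult:
    """Cluster a similarity graph by Markov flow simulation.

    ``graph`` is a networkx Graph with positive ``weight`` attributes (or a
    symmetric non-negative matrix). Every node is assigned exactly one
    cluster; clusters are indexed by descending size with ties broken by the
    lexicographically smallest member. Non-convergence within
    ``max_iterations`` yields a warning and clusters from the final iterate.
    """
    cfg = cfg or MCLConfig()
    nodes, W = _as_matrix(graph, cfg)
    M = _normalize(W)
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        nxt = mcl_iterate(M, cfg)
        if np.abs(nxt - M).max() < cfg.convergence_tol:
            M = nxt
            converged = True
            break
        M = nxt
    if not converged:
        warnings.warn(
            f"MCL did not converge in {cfg.max_iterations} iterations; "
            "clusters taken from the final iterate",
            RuntimeWarning,
        )
    n = len(nodes)
    eps = max(cfg.prune_threshold, 1e-9)
    attractors = np.nonzero(np.diag(M) > eps)[0]
    # attractor systems: attractors connected through residual flow
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(int(a) for a in attractors)
    for a in attractors:
        for b in attractors:
            if a < b and (M[a, b] > eps or M[b, a] > eps):
                sys_graph.add_edge(int(a), int(b))
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: s[0])
    sys_of_attractor = {a: k for k, s in enumerate(systems) for a in s}
    members: list[set] = [set(s) for s in systems]
    for j in range(n):
        flows = [sys_of_attractor[int(a)] for a in attractors if M[a, j] > eps]
        if not flows:
            # degenerate: attach to the attractor with most inbound flow
            a = int(attractors[np.argmax(M[attractors, j])]) if len(attractors) else j
            flows = [sys_of_attractor.get(a, -1)]
            if flows[0] == -1:
                members.append({j})
                continue
        # overlap: join the larger system, tie-break lexicographic smallest member
        best = min(
            set(flows),
            key=lambda k: (-len(systems[k]), nodes[systems[k][0]]),
        )
        members[best].add(j)
    clusters = [sorted(m) for m in members if m]
    # deduplicate nodes that were already attractor members
    assigned: dict[int, int] = {}
    for k, cl in enumerate(clusters):
        for j in cl:
            assigned.setdefault(j, k)
    cluster_sets: dict[int, set] = {}
    for j, k in assigned.items():
        cluster_sets.setdefault(k, set()).add(j)
    ordered = sorted(
        cluster_sets.values(), key=lambda s: (-len(s), nodes[min(s)])
    )
    partition = {}
    for k, cl in enumerate(ordered):
        for j in cl:
            partition[nodes[j]] = k
    labels = cluster_labels(partition)
    return MCLResult(partition, labels, converged, it)


def cluster_labels(partition: dict[str, int]) -> dict[str, str]:
    """Size-ranked labels "MCL1", "MCL2", ...; singleton clusters -> "MCLnull"."""
    sizes: dict[int, int] = {}
    for k in partition.values():
        sizes[k] = sizes.get(k, 0) + 1
    rank = {}
    nxt = 1
    for k in sorted(sizes, key=lambda k: (-sizes[k], k)):
        if sizes[k] == 1:
            rank[k] = "MCLnull"
        else:
            rank[k] = f"MCL{nxt}"
            nxt += 1
    return {node: rank[k] for node, k in partition.items()}
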
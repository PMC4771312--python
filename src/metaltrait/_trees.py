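"""Array-backed view of a rooted phylogeny for vectorized trait statistics.

dendropy remains the user-facing tree object (parsing, writing, manipulation);
this module flattens a rooted tree into index arrays once so that permutation
and simulation loops (thousands of binary traits on the same topology) run as
numpy operations over a single pass of the node list.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["TreeArrays", "read_trees", "parse_tree"]


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a single rooted Newick string into a dendropy Tree."""
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def read_trees(path) -> list[dendropy.Tree]:
    """Read one or more rooted trees from a Newick file (bootstrap sets allowed)."""
    tl = dendropy.TreeList.get(path=str(path), schema="newick", rooting="force-rooted")
    return list(tl)


class TreeArrays:
    """Flattened rooted tree.

    Nodes are indexed 0..n_nodes-1 in postorder. Tips are additionally given a
    canonical *tip order* sorted by label; every trait vector/matrix passed to
    the statistics below is aligned to ``tip_labels`` (sorted).
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.edge_len = np.zeros(self.n_nodes, dtype=float)
        self.is_tip = np.zeros(self.n_nodes, dtype=bool)
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        labels = {}
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                children[p].append(i)
            el = nd.edge.length
            self.edge_len[i] = 0.0 if el is None else float(el)
            if nd.is_leaf():
                self.is_tip[i] = True
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValueError("tree has an unlabeled tip")
                labels[i] = nd.taxon.label
        self.children = [np.asarray(c, dtype=np.int64) for c in children]
        self.postorder = np.arange(self.n_nodes, dtype=np.int64)  # by construction
        self.root = self.n_nodes - 1
        # canonical tip ordering: sorted by label
        tip_nodes = [i for i in range(self.n_nodes) if self.is_tip[i]]
        self.tip_labels = sorted(labels[i] for i in tip_nodes)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels are not unique")
        lab2node = {labels[i]: i for i in tip_nodes}
        # tip_node[k] = node index of k-th tip in canonical order
        self.tip_node = np.asarray([lab2node[l] for l in self.tip_labels], dtype=np.int64)
        self.n_tips = len(self.tip_node)
        # node -> tip slot (or -1)
        self.tip_slot = np.full(self.n_nodes, -1, dtype=np.int64)
        self.tip_slot[self.tip_node] = np.arange(self.n_tips)
        self._internal = np.asarray(
            [i for i in range(self.n_nodes) if not self.is_tip[i]], dtype=np.int64
        )
        self._depths = None
        self._tipcounts = None

    # ------------------------------------------------------------------ utils
    @classmethod
    def from_newick(cls, newick: str) -> "TreeArrays":
        return cls(parse_tree(newick))

    def preorder(self):
        """Node indices root-first (reverse postorder)."""
        return self.postorder[::-1]

    def node_tip_counts(self) -> np.ndarray:
        """Number of tips descending from (and including) each node."""
        if self._tipcounts is None:
            c = np.where(self.is_tip, 1, 0).astype(np.int64)
            for i in self.postorder:
                if not self.is_tip[i]:
                    c[i] = sum(c[j] for j in self.children[i])
            self._tipcounts = c
        return self._tipcounts

    def mean_tip_depth(self) -> np.ndarray:
        """Mean branch-length distance from each node down to its tips."""
        if self._depths is None:
            counts = self.node_tip_counts()
            total = np.zeros(self.n_nodes)  # summed distances node->its tips
            for i in self.postorder:
                if not self.is_tip[i]:
                    total[i] = sum(
                        total[j] + counts[j] * self.edge_len[j] for j in self.children[i]
                    )
            self._depths = total / counts
        return self._depths

    def root_to_tip(self) -> np.ndarray:
        """Distance from root to each tip, canonical tip order."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + self.edge_len[i]
        return d[self.tip_node]

    # --------------------------------------------------------- trait matrices
    def _as_matrix(self, traits) -> np.ndarray:
        t = np.asarray(traits)
        if t.ndim == 1:
            t = t[:, None]
        if t.shape[0] != self.n_tips:
            raise ValueError(
                f"trait matrix has {t.shape[0]} rows for a {self.n_tips}-tip tree"
            )
        return t

    def sister_difference_sum(self, traits) -> np.ndarray:
        """Sum over internal nodes of absolute child-value deviations.

        Node values are computed tips-to-root as the unweighted mean of child
        values; each internal node contributes the sum of |child - mean(children)|
        (equal to |v1 - v2| for a bifurcation). Vectorized over trait columns.
        """
        t = self._as_matrix(traits).astype(float)
        k = t.shape[1]
        val = np.zeros((self.n_nodes, k))
        val[self.tip_node] = t
        acc = np.zeros(k)
        for i in self.postorder:
            ch = self.children[i]
            if len(ch) == 0:
                continue
            cv = val[ch]  # (n_children, k)
            m = cv.mean(axis=0)
            val[i] = m
            acc += np.abs(cv - m[None, :]).sum(axis=0)
        return acc

    def consentrait_tau(
        self, traits, positive_fraction: float = 0.90, singleton_factor: float = 0.5
    ) -> np.ndarray:
        """consenTRAIT trait depth tau_D for each binary trait column.

        A clade qualifies when the fraction of positive tips is >=
        ``positive_fraction``; maximal qualifying clades (no qualifying
        ancestor) contribute their mean node-to-tip depth. Positive tips
        outside every qualifying clade contribute ``singleton_factor`` times
        their terminal branch length. tau_D is the mean of all contributions.
        Columns with zero positive tips yield NaN.
        """
        t = self._as_matrix(traits)
        tb = t.astype(bool)
        k = tb.shape[1]
        npos = np.zeros((self.n_nodes, k), dtype=np.int64)
        npos[self.tip_node] = tb.astype(np.int64)
        for i in self.postorder:
            ch = self.children[i]
            if len(ch):
                npos[i] = npos[ch].sum(axis=0)
        counts = self.node_tip_counts()
        qual = np.zeros((self.n_nodes, k), dtype=bool)
        internal = self._internal
        qual[internal] = npos[internal] >= positive_fraction * counts[internal, None]
        qual[internal] &= npos[internal] > 0
        # ancestor-qualified flag, preorder propagation
        anc = np.zeros((self.n_nodes, k), dtype=bool)
        for i in self.preorder():
            for j in self.children[i]:
                anc[j] = anc[i] | qual[i]
        maximal = qual & ~anc
        depths = self.mean_tip_depth()
        contrib_sum = (maximal * depths[:, None]).sum(axis=0)
        n_contrib = maximal.sum(axis=0).astype(float)
        # singletons: positive tips under no qualifying clade (and not tips of one)
        tipn = self.tip_node
        singleton = tb & ~(anc[tipn] | qual[tipn])
        term = self.edge_len[tipn]
        contrib_sum += singleton_factor * (singleton * term[:, None]).sum(axis=0)
        n_contrib += singleton.sum(axis=0)
        with np.errstate(invalid="ignore"):
            tau = contrib_sum / n_contrib
        tau[tb.sum(axis=0) == 0] = np.nan
        return tau

    def brownian_tips(self, n_sims: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate Brownian motion along branches; return tip values.

        Root value 0; each branch adds a Normal(0, branch length) increment
        (variance proportional to length). Returns (n_tips, n_sims) aligned to
        the canonical tip order.
        """
        val = np.zeros((self.n_nodes, n_sims))
        sd = np.sqrt(self.edge_len)
        for i in self.preorder():
            p = self.parent[i]
            if p >= 0:
                val[i] = val[p] + sd[i] * rng.standard_normal(n_sims)
        return val[self.tip_node]

    def threshold_at_count(self, values: np.ndarray, n_positive: int) -> np.ndarray:
        """Binarize columns of tip values: top ``n_positive`` tips are positive.

        The threshold is the empirical quantile giving an exact positive count;
        ties are broken by canonical (sorted label) tip order.
        """
        v = np.asarray(values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        n, k = v.shape
        out = np.zeros((n, k), dtype=np.int8)
        slots = np.arange(n)
        for j in range(k):
            order = np.lexsort((slots, -v[:, j]))
            out[order[:n_positive], j] = 1
        return out
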
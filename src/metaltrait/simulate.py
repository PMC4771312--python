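"""Synthetic-data generators for every input the pipeline consumes.

Trees (Yule), binary traits (random / clumped / Brownian-threshold), genome
gene tables with planted transporter loci and upstream regulatory motifs,
planted-partition protein similarity graphs, and two-lineage trait count
matrices with unequal dispersion and a covariate. All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from ._trees import TreeArrays

__all__ = [
    "SimTreeSpec",
    "TraitSimSpec",
    "GenomeSimSpec",
    "GraphSimSpec",
    "gen_tree",
    "gen_traits",
    "gen_genomes",
    "gen_similarity_graph",
    "gen_count_matrix",
]

UPSTREAM_LEN = 300  # fixed upstream window emitted per gene
_BASES = np.array(list("ACGT"))


class InvalidSpecError(ValueError):
    """A simulation spec violates its invariants."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# --------------------------------------------------------------------- trees
@dataclass
class SimTreeSpec:
    n_tips: int
    seed: int = 0
    scale: float = 1.0
    model: str = "yule"

    def __post_init__(self):
        if self.n_tips < 1:
            raise InvalidSpecError("n_tips must be >= 1")
        if self.scale <= 0:
            raise InvalidSpecError("scale must be positive")
        if self.model != "yule":
            raise InvalidSpecError(f"unknown tree model {self.model!r}")


def gen_tree(spec: SimTreeSpec) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` tips labeled t1..tN.

    The birth rate is set so the expected root-to-tip depth equals
    ``spec.scale``. Tips are contemporaneous (the tree is ultrametric) and all
    branch lengths are strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tips
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n == 1:
        tree.seed_node.taxon = taxa.new_taxon("t1")
        tree.seed_node.edge.length = spec.scale
        return tree
    # expected root-to-tip depth at rate 1: growth waits at 2..n-1 lineages
    # plus the final hold at n (the 1-lineage wait precedes the root)
    rate = (sum(1.0 / k for k in range(2, n)) + 1.0 / n) / spec.scale
    active = [tree.seed_node]
    tree.seed_node.edge.length = 0.0
    while len(active) < n:
        k = len(active)
        wait = rng.exponential(1.0 / (k * rate))
        for nd in active:
            nd.edge.length += wait
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            ch = split.new_child()
            ch.edge.length = 0.0
            active.append(ch)
    final = rng.exponential(1.0 / (n * rate))
    for nd in active:
        nd.edge.length += final
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"t{i}")
    return tree


# -------------------------------------------------------------------- traits
@dataclass
class TraitSimSpec:
    model: str = "random"
    prevalence: float = 0.25
    clade_tip: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("random", "clumped", "brownian_threshold"):
            raise InvalidSpecError(f"unknown trait model {self.model!r}")
        if not (0 < self.prevalence <= 1):
            raise InvalidSpecError("prevalence must lie in (0, 1]")


class UnknownTipError(KeyError):
    pass


def gen_traits(tree: dendropy.Tree, spec: TraitSimSpec) -> pd.Series:
    """Simulate one binary trait over the tips of ``tree``.

    random: independent Bernoulli(prevalence) per tip.
    clumped: the smallest clade containing >= round(prevalence * n) tips seeded
        at ``clade_tip``, trimmed to the exact count by dropping the tips
        farthest (patristic distance) from the anchor, ties by label order.
    brownian_threshold: Brownian values simulated along branches, thresholded
        at the empirical quantile so the positive count is exact.

    Returns a 0/1 Series indexed by tip label (sorted).
    """
    ta = TreeArrays(tree)
    n = ta.n_tips
    rng = np.random.default_rng(spec.seed)
    labels = ta.tip_labels
    target = max(1, _round_half_up(spec.prevalence * n))
    if spec.model == "random":
        vals = (rng.random(n) < spec.prevalence).astype(np.int8)
    elif spec.model == "brownian_threshold":
        tipvals = ta.brownian_tips(1, rng)[:, 0]
        vals = ta.threshold_at_count(tipvals, target)[:, 0]
    else:  # clumped
        anchor = spec.clade_tip or labels[int(rng.integers(n))]
        if anchor not in labels:
            raise UnknownTipError(f"clade_tip {anchor!r} not in tree")
        node = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == anchor:
                node = leaf
                break
        while node.parent_node is not None and len(node.leaf_nodes()) < target:
            node = node.parent_node
        members = sorted(lf.taxon.label for lf in node.leaf_nodes())
        pdm = tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in tree.taxon_namespace}
        dist = {m: pdm.patristic_distance(tx[anchor], tx[m]) for m in members}
        members.sort(key=lambda m: (dist[m], m))  # nearest first, label tie-break
        keep = set(members[:target])
        vals = np.asarray([1 if l in keep else 0 for l in labels], dtype=np.int8)
    return pd.Series(vals, index=pd.Index(labels, name="genome_id"), name="trait")


# ------------------------------------------------------------------- genomes
@dataclass
class GenomeSimSpec:
    n_genomes: int = 10
    genes_per_genome: int = 50
    family_pool: list[tuple[str, float]] = field(
        default_factory=lambda: [("hyp", 0.85), ("ABCT", 0.05), ("perm", 0.10)]
    )
    locus_templates: list[tuple[str, tuple[str, ...], float]] = field(
        default_factory=lambda: [
            ("heme", ("TBDT", "hutB", "hmuS"), 0.5),
            ("siderophore", ("TBDT", "fatB", "SIP"), 0.5),
        ]
    )
    motif_plant: tuple[str, int, int] | None = None  # (motif, upstream offset, mismatches)
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1 or self.genes_per_genome < 1:
            raise InvalidSpecError("n_genomes and genes_per_genome must be >= 1")
        longest = max((len(t[1]) for t in self.locus_templates), default=0)
        if longest > self.genes_per_genome:
            raise InvalidSpecError("locus template longer than genome")
        if self.motif_plant is not None:
            motif, offset, _mm = self.motif_plant
            if offset < 0 or offset + len(motif) > UPSTREAM_LEN:
                raise InvalidSpecError("planted motif does not fit the upstream window")


_GENE_LEN = 900
_GENE_STEP = 1000  # leaves a >=100 bp gap between genes


def gen_genomes(spec: GenomeSimSpec) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Simulate genome gene tables with planted transporter loci.

    Returns ``(genes, upstreams, planted)``:

    * ``genes`` — one row per gene: genome_id, contig_id, index, start, end,
      strand, gene_id, families (tuple of family labels, possibly empty).
      Planted loci occupy contiguous runs of gene indices on one contig.
    * ``upstreams`` — gene_id -> 300-bp upstream sequence (gene-strand
      orientation); the planted motif is written at the stated offset in the
      upstream record of the first gene of every planted locus.
    * ``planted`` — ground truth: genome_id, template, start_index, gene_ids.
    """
    rng = np.random.default_rng(spec.seed)
    fam_labels = [f for f, _ in spec.family_pool]
    fam_w = np.asarray([w for _, w in spec.family_pool], dtype=float)
    fam_w = fam_w / fam_w.sum()
    rows = []
    upstreams: dict[str, str] = {}
    planted_rows = []
    for g in range(spec.n_genomes):
        genome = f"g{g + 1:03d}"
        contig = f"{genome}_c1"
        fams: list[tuple[str, ...]] = [
            (str(rng.choice(fam_labels, p=fam_w)),) for _ in range(spec.genes_per_genome)
        ]
        occupied = np.zeros(spec.genes_per_genome, dtype=bool)
        plant_first: dict[int, None] = {}
        for name, template, prob in spec.locus_templates:
            if rng.random() >= prob:
                continue
            L = len(template)
            free = [
                s
                for s in range(spec.genes_per_genome - L + 1)
                if not occupied[s : s + L].any()
            ]
            if not free:
                continue
            s = int(rng.choice(free))
            occupied[s : s + L] = True
            for off, fam in enumerate(template):
                fams[s + off] = (fam,)
            plant_first[s] = None
            planted_rows.append(
                {
                    "genome_id": genome,
                    "template": name,
                    "start_index": s,
                    "gene_ids": tuple(f"{genome}_{s + off + 1:05d}" for off in range(L)),
                }
            )
        strands = rng.choice(["+", "-"], size=spec.genes_per_genome)
        strands[occupied] = "+"  # planted loci on the forward strand
        for i in range(spec.genes_per_genome):
            gene_id = f"{genome}_{i + 1:05d}"
            start = i * _GENE_STEP + UPSTREAM_LEN
            rows.append(
                {
                    "genome_id": genome,
                    "contig_id": contig,
                    "index": i,
                    "start": start,
                    "end": start + _GENE_LEN,
                    "strand": strands[i],
                    "gene_id": gene_id,
                    "families": fams[i],
                }
            )
            seq = rng.choice(_BASES, size=UPSTREAM_LEN)
            if spec.motif_plant is not None and i in plant_first:
                motif, offset, n_mm = spec.motif_plant
                m = np.array(list(motif))
                if n_mm > 0:
                    pos = rng.choice(len(m), size=n_mm, replace=False)
                    for p in pos:
                        alts = [b for b in "ACGT" if b != m[p]]
                        m[p] = alts[int(rng.integers(3))]
                seq[offset : offset + len(m)] = m
            upstreams[gene_id] = "".join(seq)
    genes = pd.DataFrame(rows)
    planted = pd.DataFrame(
        planted_rows, columns=["genome_id", "template", "start_index", "gene_ids"]
    )
    return genes, upstreams, planted


# --------------------------------------------------------------------- graph
@dataclass
class GraphSimSpec:
    cluster_sizes: tuple[int, ...] = (20, 20)
    p_in: float = 0.9
    p_out: float = 0.05
    weight_in: float = 100.0
    weight_out: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 1 for s in self.cluster_sizes):
            raise InvalidSpecError("cluster sizes must be >= 1")
        for p in (self.p_in, self.p_out):
            if not (0 <= p <= 1):
                raise InvalidSpecError("edge probabilities must lie in [0, 1]")
        if self.weight_in <= 0 or self.weight_out <= 0:
            raise InvalidSpecError("edge weight means must be positive")


def gen_similarity_graph(spec: GraphSimSpec) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition weighted similarity graph.

    Within-cluster pairs receive an edge with probability ``p_in`` (mean
    weight ``weight_in``), between-cluster pairs with ``p_out`` (mean
    ``weight_out``); weights are positive with ~15% relative spread. Returns
    the graph and the planted node -> cluster-index labeling.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.cluster_sizes)
    membership = np.concatenate(
        [np.full(s, k, dtype=int) for k, s in enumerate(spec.cluster_sizes)]
    )
    names = [f"n{i + 1:04d}" for i in range(n)]
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            same = membership[i] == membership[j]
            p = spec.p_in if same else spec.p_out
            if rng.random() < p:
                mu = spec.weight_in if same else spec.weight_out
                w = max(0.05 * mu, mu * (1.0 + 0.15 * rng.standard_normal()))
                G.add_edge(names[i], names[j], weight=float(w))
    return G, dict(zip(names, membership.tolist()))


# -------------------------------------------------------------- count matrix
def gen_count_matrix(
    n_per_group: tuple[int, int] = (42, 22),
    n_features: int = 25,
    group_dispersion: tuple[float, float] = (5.0, 1.0),
    covariate_effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-lineage transporter count matrix with unequal dispersion.

    Group 1 (default 42 rows, the dispersed patch-adapted analog) gets
    within-group noise SD ``group_dispersion[0]`` per feature; group 2
    (default 22 rows, the tight streamlined analog) gets
    ``group_dispersion[1]``. A metadata covariate is built as
    ``covariate_effect * standardized(row sum) + Normal(0, 1)`` noise, mimicking
    genome features (GC content, genome size) that track transporter totals.

    Returns ``(counts, metadata)``: counts is genomes x features (ints >= 0),
    metadata has genome_id, lineage, covariate.
    """
    if any(s < 2 for s in n_per_group):
        raise InvalidSpecError("each group needs >= 2 genomes")
    if group_dispersion[0] < 0 or group_dispersion[1] < 0:
        raise InvalidSpecError("dispersions must be non-negative")
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 40, size=n_features)
    offsets = rng.uniform(-3, 3, size=n_features)
    means = {"A": base + offsets, "B": base - offsets}
    rows, meta = [], []
    for gi, (glab, size) in enumerate(zip(("A", "B"), n_per_group)):
        sd = group_dispersion[gi]
        for r in range(size):
            vec = means[glab] + sd * rng.standard_normal(n_features)
            vec = np.clip(np.round(vec), 0, None).astype(int)
            rows.append(vec)
            meta.append({"genome_id": f"{glab}{r + 1:03d}", "lineage": glab})
    counts = pd.DataFrame(
        rows,
        index=[m["genome_id"] for m in meta],
        columns=[f"trait{j + 1:02d}" for j in range(n_features)],
    )
    counts.index.name = "genome_id"
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    z = (totals - totals.mean()) / (totals.std() or 1.0)
    cov = covariate_effect * z + rng.standard_normal(len(z))
    metadata = pd.DataFrame(meta)
    metadata["covariate"] = cov
    return counts, metadata
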
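"""Gene-neighborhood extraction, family enrichment, and locus classification.

Neighborhoods are windows of +/- N genes (default 10) around focal genes
(typically TonB-dependent transporters). Family enrichment inside the pooled
neighborhoods of a focal set is tested with a one-sided Fisher exact
(hypergeometric) test and corrected across all (focal set, family) pairs with
Benjamini-Hochberg. Locus classification applies ordered colocalization
rules — e.g. a TBDT colocated with hutB and hmuS is a heme uptake locus;
with fhuD, a hydroxamate-siderophore locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "LocusRule",
    "LocusRuleSet",
    "LocusCall",
    "DEFAULT_RULES",
    "extract_neighborhood",
    "enrichment_test",
    "classify_locus",
]


class UnknownGeneError(KeyError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    focal_set: str
    family: str
    a: int  # family genes inside neighborhoods
    b: int  # non-family genes inside
    c: int  # family genes outside
    d: int  # non-family genes outside
    odds_ratio: float
    p: float
    q: float = float("nan")


@dataclass(frozen=True)
class LocusRule:
    label: str
    required_families: frozenset
    require_motif: bool = False
    min_present: int | None = None  # None = all required families must fire


@dataclass
class LocusRuleSet:
    rules: list[LocusRule] = field(default_factory=lambda: list(DEFAULT_RULES))
    fallback: str = "ambiguous"


@dataclass(frozen=True)
class LocusCall:
    focal_gene: str
    label: str
    evidence: tuple[str, ...]


DEFAULT_RULES = (
    # first-match-wins; biosynthesis outranks uptake-only calls
    LocusRule("biosynthesis_cluster", frozenset({"entE", "entF"}), min_present=1),
    LocusRule("heme", frozenset({"hutB", "hmuS"})),
    LocusRule("siderophore_catecholate", frozenset({"fatB"})),
    LocusRule("siderophore_hydroxamate", frozenset({"fhuD"})),
    LocusRule("siderophore_unknown", frozenset({"SIP"})),
)


def extract_neighborhood(
    genes: pd.DataFrame, focal_gene: str, window_genes: int = 10
) -> pd.DataFrame:
    """Genes within ``window_genes`` positions of the focal gene on its contig.

    Returns up to 2*window + 1 rows (truncated at contig ends), ordered by
    gene index, with a boolean ``is_focal`` column.
    """
    row = genes[genes["gene_id"] == focal_gene]
    if row.empty:
        raise UnknownGeneError(f"unknown gene {focal_gene!r}")
    row = row.iloc[0]
    contig = genes[genes["contig_id"] == row["contig_id"]]
    lo, hi = row["index"] - window_genes, row["index"] + window_genes
    nb = contig[(contig["index"] >= lo) & (contig["index"] <= hi)].sort_values("index")
    nb = nb.copy()
    nb["is_focal"] = nb["gene_id"] == focal_gene
    return nb


def _families_of(row) -> frozenset:
    fams = row["families"]
    if isinstance(fams, str):
        return frozenset(f for f in fams.split(";") if f)
    return frozenset(fams)


def enrichment_test(
    genes: pd.DataFrame,
    focal_sets: dict[str, list[str]],
    families: list[str],
    window_genes: int = 10,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Fisher enrichment of each family inside each focal set's neighborhoods.

    Neighborhoods of a focal set are unioned before counting, so a gene in
    two overlapping windows counts once. The universe is every gene of every
    supplied genome. For each (set, family): a/b = family/non-family genes
    inside the union, c/d = outside; the one-sided (greater) p-value is the
    hypergeometric upper tail. BH correction is applied jointly across all
    pairs; genes carrying several family labels contribute to each.
    """
    if genes.empty:
        raise ValueError("empty gene universe")
    N = len(genes)
    gene_fams = {g: _families_of(r) for g, r in genes.set_index("gene_id").iterrows()}
    fam_total = {f: sum(1 for fs in gene_fams.values() if f in fs) for f in families}
    raw: list[EnrichmentResult] = []
    for set_name, focal_ids in focal_sets.items():
        inside: set = set()
        for fg in focal_ids:
            inside |= set(extract_neighborhood(genes, fg, window_genes)["gene_id"])
        n_in = len(inside)
        for fam in families:
            a = sum(1 for g in inside if fam in gene_fams[g])
            b = n_in - a
            K = fam_total[fam]
            c = K - a
            d = N - n_in - c
            if alternative == "greater":
                p = float(stats.hypergeom.sf(a - 1, N, K, n_in))
            else:
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            odds = (a * d / (b * c)) if b * c > 0 else float("inf")
            raw.append(EnrichmentResult(set_name, fam, a, b, c, d, odds, p))
    if raw:
        _, q, _, _ = multipletests([r.p for r in raw], method="fdr_bh")
        raw = [
            EnrichmentResult(r.focal_set, r.family, r.a, r.b, r.c, r.d, r.odds_ratio, r.p, float(qi))
            for r, qi in zip(raw, q)
        ]
    return raw


def classify_locus(
    neighborhood: pd.DataFrame,
    motif_hits=None,
    rules: LocusRuleSet | None = None,
) -> LocusCall:
    """Classify a focal-gene neighborhood by its colocalized families.

    Rules are evaluated in order; the first whose required families (all of
    them, or ``min_present`` of them) are present — and whose motif
    requirement, if any, is met — wins. With no match the fallback class
    (``ambiguous``) is returned. Pure function of its inputs.
    """
    rules = rules or LocusRuleSet()
    present: set = set()
    for _, row in neighborhood.iterrows():
        present |= _families_of(row)
    has_motif = bool(motif_hits)
    if "is_focal" in neighborhood.columns and neighborhood["is_focal"].any():
        focal = neighborhood.loc[neighborhood["is_focal"], "gene_id"].iloc[0]
    else:
        focal = ""
    for rule in rules.rules:
        found = rule.required_families & present
        need = rule.min_present if rule.min_present is not None else len(rule.required_families)
        if len(found) >= need and (not rule.require_motif or has_motif):
            ev = tuple(sorted(found)) + (("motif",) if rule.require_motif and has_motif else ())
            return LocusCall(focal, rule.label, ev)
    return LocusCall(focal, rules.fallback, ())
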
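"""Transporter inventory construction from domain-hit tables.

Consumes BLAST-tabular ("outfmt 6"-like) hit tables produced by searching
proteins against conserved-domain models, extended with ``hit_class`` and
``family_label`` columns, and turns them into a genome x transporter-family
count matrix after e-value and bidirectional-reciprocal filtering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "DomainHit",
    "FilterConfig",
    "ParseReport",
    "parse_domain_hits",
    "write_domain_hits",
    "filter_hits",
    "build_inventory",
    "BLAST_COLUMNS",
]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "hit_class", "family_label",
]

HIT_CLASSES = {"specific", "superfamily", "nonspecific"}


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    genome_id: str
    model_id: str
    family_label: str
    evalue: float
    bitscore: float
    hit_class: str
    rank_for_query: int = 0
    superfamily_fallback: bool = False


@dataclass
class FilterConfig:
    evalue_max: float = 1e-5
    require_specific: bool = True
    require_bidirectional: bool = True

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass
class ParseReport:
    n_rows: int = 0
    n_parsed: int = 0
    errors: list = None

    def __post_init__(self):
        if self.errors is None:
            self.errors = []


class MalformedTableError(ValueError):
    pass


class UnknownLabelError(KeyError):
    pass


def _rank(hits: list[DomainHit]) -> list[DomainHit]:
    """Assign rank_for_query per query: descending bitscore, ties by
    ascending evalue then lexicographic model_id (deterministic)."""
    by_query: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for q, group in by_query.items():
        group.sort(key=lambda h: (-h.bitscore, h.evalue, h.model_id))
        for r, h in enumerate(group, start=1):
            out.append(replace(h, rank_for_query=r))
    return out


def parse_domain_hits(
    source,
    genome_map: dict[str, str] | None = None,
    max_error_fraction: float = 0.10,
) -> tuple[list[DomainHit], ParseReport]:
    """Parse an extended BLAST-tabular stream into ranked DomainHits.

    ``source`` is a path or text file object. The genome id is taken from a
    "genome|protein" qseqid prefix, or from ``genome_map`` (protein -> genome)
    when supplied. Malformed rows are collected into the report with their
    line numbers; parsing aborts only if more than ``max_error_fraction`` of
    non-empty rows are malformed.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source, "rt")
        close = True
    else:
        fh = source
    report = ParseReport()
    hits: list[DomainHit] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.n_rows += 1
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                report.errors.append((lineno, f"expected {len(BLAST_COLUMNS)} columns, got {len(parts)}"))
                continue
            rec = dict(zip(BLAST_COLUMNS, parts))
            try:
                evalue = float(rec["evalue"])
                bitscore = float(rec["bitscore"])
                if evalue < 0:
                    raise ValueError("negative evalue")
                hit_class = rec["hit_class"]
                if hit_class not in HIT_CLASSES:
                    raise ValueError(f"unknown hit_class {hit_class!r}")
            except ValueError as exc:
                report.errors.append((lineno, str(exc)))
                continue
            qseqid = rec["qseqid"]
            if genome_map is not None and qseqid in genome_map:
                genome = genome_map[qseqid]
            elif "|" in qseqid:
                genome = qseqid.split("|", 1)[0]
            else:
                report.errors.append((lineno, f"cannot resolve genome for query {qseqid!r}"))
                continue
            hits.append(
                DomainHit(
                    query_id=qseqid,
                    genome_id=genome,
                    model_id=rec["sseqid"],
                    family_label=rec["family_label"],
                    evalue=evalue,
                    bitscore=bitscore,
                    hit_class=hit_class,
                )
            )
            report.n_parsed += 1
    finally:
        if close:
            fh.close()
    if report.n_rows and len(report.errors) > max_error_fraction * report.n_rows:
        raise MalformedTableError(
            f"{len(report.errors)}/{report.n_rows} rows malformed "
            f"(> {max_error_fraction:.0%}); first: {report.errors[0]}"
        )
    return _rank(hits), report


def write_domain_hits(hits: list[DomainHit], path_or_buf) -> None:
    """Write hits back to the extended BLAST-tabular dialect (round-trippable)."""
    rows = []
    for h in hits:
        rows.append(
            [h.query_id, h.model_id, "0", "0", "0", "0", "0", "0", "0", "0",
             repr(h.evalue), repr(h.bitscore), h.hit_class, h.family_label]
        )
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    df.to_csv(path_or_buf, sep="\t", header=False, index=False)


def filter_hits(hits: list[DomainHit], cfg: FilterConfig | None = None) -> list[DomainHit]:
    """Apply the retention rules: e-value threshold, specific-hit requirement
    with superfamily fallback, and the bidirectional-reciprocal rule.

    A hit survives the bidirectional rule iff it is its query's top-ranked
    model AND its query carries the highest bitscore among the same genome's
    queries hitting that model (mutual best within genome; ties broken by
    ascending evalue then query id). Queries whose only surviving hits are
    superfamily-level are retained with ``superfamily_fallback=True`` rather
    than dropped. Filtering is total and idempotent.
    """
    cfg = cfg or FilterConfig()
    surviving = [h for h in hits if h.evalue < cfg.evalue_max and h.hit_class != "nonspecific"]
    if cfg.require_bidirectional:
        best_query: dict[tuple[str, str], str] = {}
        key_of: dict[tuple[str, str], tuple] = {}
        for h in surviving:
            k = (h.genome_id, h.model_id)
            cand = (-h.bitscore, h.evalue, h.query_id)
            if k not in key_of or cand < key_of[k]:
                key_of[k] = cand
                best_query[k] = h.query_id
        surviving = [
            h
            for h in surviving
            if h.rank_for_query == 1 and best_query[(h.genome_id, h.model_id)] == h.query_id
        ]
    else:
        surviving = [h for h in surviving if h.rank_for_query == 1]
    if not cfg.require_specific:
        return surviving
    specific_queries = {h.query_id for h in surviving if h.hit_class == "specific"}
    out = []
    for h in surviving:
        if h.hit_class == "specific":
            out.append(h)
        elif h.query_id not in specific_queries:  # superfamily-only query: tag, keep
            out.append(replace(h, superfamily_fallback=True))
    return out


def build_inventory(
    hits: list[DomainHit],
    genomes: list[str],
    families: list[str],
    per_domain: bool = False,
    superfamily_suffix: str = "_superfamily",
) -> pd.DataFrame:
    """Genome x family count matrix from filtered hits.

    Declared genomes/families appear even when absent from the hits (zero
    rows/columns); a hit referencing an undeclared label raises. By default a
    protein counts once per family regardless of how many of its domains hit
    (``per_domain=True`` counts every hit). Superfamily-fallback hits are
    tallied in separate columns suffixed with ``superfamily_suffix``.
    """
    fam_index = list(families) + [f + superfamily_suffix for f in families]
    table = pd.DataFrame(0, index=pd.Index(genomes, name="genome_id"), columns=fam_index)
    seen = set()
    for h in hits:
        if h.genome_id not in table.index:
            raise UnknownLabelError(f"undeclared genome {h.genome_id!r}")
        if h.family_label not in families:
            raise UnknownLabelError(f"undeclared family {h.family_label!r}")
        col = h.family_label + superfamily_suffix if h.superfamily_fallback else h.family_label
        if not per_domain:
            key = (h.query_id, col)
            if key in seen:
                continue
            seen.add(key)
        table.loc[h.genome_id, col] += 1
    # drop all-zero superfamily columns to keep the grid tidy
    extra = [c for c in table.columns if c.endswith(superfamily_suffix) and table[c].sum() == 0]
    return table.drop(columns=extra)


def binary_view(inventory: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence view of a count inventory."""
    return (inventory > 0).astype(int)
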
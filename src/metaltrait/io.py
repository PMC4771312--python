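"""Readers and writers for the pipeline's on-disk formats.

Gene tables travel as GFF3 (family labels in a ``family`` attribute),
sequences as FASTA (Biopython), trees as Newick (dendropy), matrices and
edge lists as TSV, metadata as CSV. Every table writer prepends a comment
line carrying the package version and a config digest so outputs are
traceable; readers skip ``#`` comments.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

__all__ = [
    "write_gff3", "read_gff3", "write_fasta", "read_fasta",
    "write_table", "read_table", "write_edges", "read_edges",
    "config_digest", "write_manifest",
]

GENE_COLUMNS = ["genome_id", "contig_id", "index", "start", "end", "strand", "gene_id", "families"]


def config_digest(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.md5(blob).hexdigest()[:12]


def _header(digest: str | None) -> str:
    return f"# metaltrait v{__version__}" + (f" config={digest}" if digest else "") + "\n"


def write_table(df: pd.DataFrame, path, digest: str | None = None, index: bool = False) -> None:
    with open(path, "wt") as fh:
        fh.write(_header(digest))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_gff3(genes: pd.DataFrame, path, digest: str | None = None) -> None:
    """Write a gene table as GFF3 (1-based closed coordinates on disk)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header(digest))
        for _, g in genes.iterrows():
            fams = g["families"]
            if not isinstance(fams, str):
                fams = ",".join(fams)
            attrs = (
                f"ID={g['gene_id']};genome={g['genome_id']};gene_index={g['index']}"
                + (f";family={fams}" if fams else "")
            )
            fh.write(
                "\t".join(
                    [
                        str(g["contig_id"]), "metaltrait", "gene",
                        str(int(g["start"]) + 1), str(int(g["end"])),
                        ".", str(g["strand"]), ".", attrs,
                    ]
                )
                + "\n"
            )


class GFFParseError(ValueError):
    def __init__(self, findings):
        self.findings = findings
        super().__init__(f"{len(findings)} malformed GFF3 line(s); first: {findings[0]}")


def read_gff3(path, strict: bool = True):
    """Read a GFF3 gene table back into the in-memory gene DataFrame.

    Returns ``(genes, findings)`` where findings is a list of
    (line number, message) for malformed lines. ``strict=True`` raises when
    findings are present.
    """
    rows, findings = [], []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                findings.append((lineno, f"expected 9 columns, got {len(parts)}"))
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)
                if start_i < 0 or start_i >= end_i:
                    raise ValueError("invalid coordinates")
                if strand not in "+-":
                    raise ValueError(f"invalid strand {strand!r}")
            except ValueError as exc:
                findings.append((lineno, str(exc)))
                continue
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if "ID" not in a:
                findings.append((lineno, "missing ID attribute"))
                continue
            fams = tuple(f for f in a.get("family", "").split(",") if f)
            rows.append(
                {
                    "genome_id": a.get("genome", seqid.rsplit("_", 1)[0]),
                    "contig_id": seqid,
                    "index": int(a.get("gene_index", len(rows))),
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "gene_id": a["ID"],
                    "families": fams,
                }
            )
    if findings and strict:
        raise GFFParseError(findings)
    return pd.DataFrame(rows, columns=GENE_COLUMNS), findings


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_edges(graph, path, digest: str | None = None) -> None:
    """TSV edge list (node_a, node_b, weight), deterministic order."""
    rows = sorted(
        (min(u, v), max(u, v), d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    write_table(df, path, digest)


def read_edges(path):
    import networkx as nx

    df = read_table(path)
    G = nx.Graph()
    for _, r in df.iterrows():
        G.add_edge(str(r["node_a"]), str(r["node_b"]), weight=float(r["weight"]))
    return G


def write_manifest(path, **fields) -> None:
    with open(path, "wt") as fh:
        json.dump({"version": __version__, **fields}, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
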
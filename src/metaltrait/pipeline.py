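"""End-to-end orchestration of the analysis stages from a single config.

Stages run in dependency order: simulate (optional input generation) ->
inventory -> {motifs, neighborhoods, cluster} -> phylosignal -> ordination.
Every stage is individually skippable; a fixed global seed makes the whole
run byte-reproducible. Each stage writes its tables under the output
directory and contributes a row-count/significance tally to the run report.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, simulate
from .inventory import FilterConfig, build_inventory, filter_hits, parse_domain_hits
from .mcl import MCLConfig, mcl_cluster
from .motifs import MotifSpec, assign_hits_to_genes, scan_inverted_repeats, scan_reference_motifs
from .neighborhood import LocusRuleSet, classify_locus, enrichment_test, extract_neighborhood
from .ordination import dispersion_test, envfit, pca
from .phylosignal import ConsentraitConfig, signal_table
from ._trees import read_trees

__all__ = ["load_config", "run_pipeline", "validate_inputs", "STAGE_ORDER"]

STAGE_ORDER = [
    "simulate", "inventory", "motifs", "neighborhoods", "cluster", "phylosignal", "ordination",
]

log = logging.getLogger("metaltrait")


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path, "rt") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", {})
    for name in cfg["stages"]:
        if name not in STAGE_ORDER:
            raise ConfigError(f"stages.{name}: unknown stage")
    return cfg


def _setup_logging(out_dir: Path, level: str = "INFO") -> None:
    log.setLevel(level)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(name)s] %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_pipeline(config, out_dir=None, log_level: str = "INFO") -> dict:
    """Execute all enabled stages; returns the run report (also written as
    report.json). ``config`` is a path to a YAML file or a dict."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    cfg.setdefault("seed", 0)
    out = Path(out_dir or cfg.get("out_dir", "metaltrait_out"))
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, log_level)
    digest = io.config_digest(cfg)
    seed = int(cfg["seed"])
    report: dict = {"version": __version__, "config_digest": digest, "config": cfg, "stages": {}}
    state: dict = {}
    for name in STAGE_ORDER:
        block = cfg.get("stages", {}).get(name)
        if block is None or not block.get("enabled", True):
            continue
        log.info("stage %s: starting", name)
        runner = globals()[f"_stage_{name}"]
        stage_seed = int(block.get("seed", seed))
        report["stages"][name] = runner(block, out, digest, stage_seed, state)
        log.info("stage %s: done", name)
    io.write_manifest(out / "report.json", **report)
    return report


def _resolve(block, key, state, state_key):
    """Path from config, else object produced by an earlier stage."""
    if key in block:
        return block[key], True
    if state_key in state:
        return state[state_key], False
    raise ConfigError(f"stage needs {key!r} (no earlier stage produced it)")


# ----------------------------------------------------------------- stages
def _stage_simulate(block, out, digest, seed, state):
    n_genomes = int(block.get("n_genomes", 20))
    gspec = simulate.GenomeSimSpec(
        n_genomes=n_genomes,
        genes_per_genome=int(block.get("genes_per_genome", 60)),
        motif_plant=tuple(block["motif_plant"]) if "motif_plant" in block else None,
        seed=seed,
    )
    genes, upstreams, planted = simulate.gen_genomes(gspec)
    io.write_gff3(genes, out / "genomes.gff3", digest)
    io.write_fasta(upstreams, out / "upstreams.fasta")
    tree = simulate.gen_tree(simulate.SimTreeSpec(int(block.get("n_tips", 32)), seed=seed))
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    traits = {}
    for model in ("clumped", "random"):
        traits[model] = simulate.gen_traits(
            tree, simulate.TraitSimSpec(model, float(block.get("prevalence", 0.25)), seed=seed)
        )
    trait_df = pd.DataFrame(traits)
    io.write_table(trait_df.reset_index(), out / "traits.tsv", digest)
    graph, membership = simulate.gen_similarity_graph(
        simulate.GraphSimSpec(seed=seed)
    )
    io.write_edges(graph, out / "edges.tsv", digest)
    counts, meta = simulate.gen_count_matrix(seed=seed)
    io.write_table(counts.reset_index(), out / "counts.tsv", digest)
    meta.to_csv(out / "metadata.csv", index=False)
    hits = _hits_from_genes(genes)
    hits.to_csv(out / "hits.tsv", sep="\t", header=False, index=False)
    focal = genes[genes["families"].map(lambda fs: "TBDT" in fs)]
    io.write_table(
        pd.DataFrame({"set_name": "TBDT", "gene_id": focal["gene_id"]}),
        out / "focal_sets.tsv",
        digest,
    )
    io.write_manifest(
        out / "manifest.json", seed=seed, n_genomes=n_genomes,
        planted=planted.to_dict(orient="records"),
    )
    state.update(genes=genes, upstreams=upstreams, tree=tree, trait_df=trait_df,
                 graph=graph, counts=counts, metadata=meta, planted=planted,
                 hits_path=out / "hits.tsv", focal_sets={"TBDT": list(focal["gene_id"])})
    return {"genes": len(genes), "planted_loci": len(planted), "tips": len(trait_df)}


def _hits_from_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Synthetic domain-hit table consistent with the gene families (one
    specific best hit per family-labeled gene). Repeat family occurrences in
    a genome hit distinct related models, as with a real domain database, so
    mutual-best filtering preserves copy number."""
    rows = []
    occ: dict[tuple[str, str], int] = {}
    for _, g in genes.iterrows():
        for fam in g["families"]:
            if fam == "hyp":
                continue
            k = occ[(g["genome_id"], fam)] = occ.get((g["genome_id"], fam), 0) + 1
            rows.append(
                [f"{g['genome_id']}|{g['gene_id']}", f"model_{fam}_{k}", 99.0, 100, 0, 0,
                 1, 100, 1, 100, 1e-20, 200.0, "specific", fam]
            )
    from .inventory import BLAST_COLUMNS

    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def _stage_inventory(block, out, digest, seed, state):
    hits_path, _ = _resolve(block, "hits", state, "hits_path")
    hits, parse_report = parse_domain_hits(str(hits_path))
    fcfg = FilterConfig(
        evalue_max=float(block.get("evalue_max", 1e-5)),
        require_specific=bool(block.get("require_specific", True)),
        require_bidirectional=bool(block.get("require_bidirectional", True)),
    )
    kept = filter_hits(hits, fcfg)
    genomes = block.get("genomes") or sorted({h.genome_id for h in hits})
    families = block.get("families") or sorted({h.family_label for h in hits})
    inv = build_inventory(kept, genomes, families)
    io.write_table(inv.reset_index(), out / "inventory.tsv", digest)
    state["inventory"] = inv
    return {
        "hits_parsed": parse_report.n_parsed,
        "hits_malformed": len(parse_report.errors),
        "hits_retained": len(kept),
        "genomes": len(genomes),
        "families": len(families),
    }


def _stage_motifs(block, out, digest, seed, state):
    if "upstreams" in block:
        records = io.read_fasta(block["upstreams"])
    else:
        records = state.get("upstreams") or {}
    genes = state.get("genes")
    if genes is None and "gff" in block:
        genes, _ = io.read_gff3(block["gff"])
    mspec = block.get("motif", {})
    spec = MotifSpec(
        name=mspec.get("name", "furbox_7_1_7"),
        length=int(mspec.get("length", 15)),
        reference_seqs=tuple(mspec.get("reference_seqs", ())),
        arm_length=mspec.get("arm_length", 7),
        spacer=mspec.get("spacer", 1),
        max_mismatches=int(mspec.get("max_mismatches", 2)),
        min_palindromic_pairs=int(mspec.get("min_palindromic_pairs", 7)),
    )
    if spec.arm_length is not None:
        hits = scan_inverted_repeats(records, spec)
    else:
        hits = scan_reference_motifs(records, spec)
    if genes is not None and len(genes):
        hits = assign_hits_to_genes(
            hits, genes, spec.length,
            window_bp=int(block.get("window_bp", 300)),
            upstream_len=int(block.get("upstream_len", simulate.UPSTREAM_LEN)),
        )
    df = pd.DataFrame(
        [
            {
                "record_id": h.record_id, "start": h.start, "strand": h.strand,
                "mismatches": h.mismatches, "palindromic_pairs": h.palindromic_pairs,
                "assigned_gene": h.assigned_gene or "", "motif_name": h.motif_name,
            }
            for h in hits
        ],
        columns=["record_id", "start", "strand", "mismatches",
                 "palindromic_pairs", "assigned_gene", "motif_name"],
    ).sort_values(["record_id", "start", "strand"], kind="mergesort")
    io.write_table(df, out / "motif_hits.tsv", digest)
    state["motif_hits"] = hits
    return {"hits": len(df), "assigned": int((df["assigned_gene"] != "").sum())}


def _stage_neighborhoods(block, out, digest, seed, state):
    genes = state.get("genes")
    if genes is None:
        genes, _ = io.read_gff3(block["gff"])
    if "focal_sets" in block and isinstance(block["focal_sets"], str):
        fs_df = io.read_table(block["focal_sets"])
        focal_sets = {n: list(g["gene_id"]) for n, g in fs_df.groupby("set_name")}
    else:
        focal_sets = block.get("focal_sets") or state.get("focal_sets")
    if not focal_sets:
        raise ConfigError("neighborhoods stage needs focal sets")
    families = block.get("families") or sorted(
        {f for fs in genes["families"] for f in fs if f != "hyp"}
    )
    window = int(block.get("window_genes", 10))
    results = enrichment_test(genes, focal_sets, families, window)
    enr = pd.DataFrame(
        [
            {"focal_set": r.focal_set, "family": r.family, "a": r.a, "b": r.b,
             "c": r.c, "d": r.d, "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q}
            for r in results
        ]
    ).sort_values(["focal_set", "q", "family"], kind="mergesort")
    io.write_table(enr, out / "enrichment.tsv", digest)
    rules = LocusRuleSet()
    motif_genes = {
        h.assigned_gene for h in state.get("motif_hits", []) if h.assigned_gene
    }
    calls = []
    for set_name, ids in sorted(focal_sets.items()):
        for fg in ids:
            nb = extract_neighborhood(genes, fg, window)
            local_motifs = motif_genes & set(nb["gene_id"])
            call = classify_locus(nb, sorted(local_motifs), rules)
            calls.append(
                {"focal_set": set_name, "focal_gene": fg, "class": call.label,
                 "evidence": ";".join(call.evidence)}
            )
    calls_df = pd.DataFrame(calls, columns=["focal_set", "focal_gene", "class", "evidence"])
    io.write_table(calls_df, out / "locus_calls.tsv", digest)
    state["enrichment"] = enr
    return {
        "tests": len(enr),
        "significant_q05": int((enr["q"] < 0.05).sum()),
        "loci_classified": len(calls_df),
    }


def _stage_cluster(block, out, digest, seed, state):
    graph = state.get("graph")
    if "edges" in block:
        graph = io.read_edges(block["edges"])
    if graph is None:
        raise ConfigError("cluster stage needs an edge list")
    mcfg = MCLConfig(
        inflation=float(block.get("inflation", 2.0)),
        expansion=int(block.get("expansion", 2)),
        prune_threshold=float(block.get("prune_threshold", 1e-5)),
    )
    res = mcl_cluster(graph, mcfg)
    df = pd.DataFrame(
        sorted((n, res.labels[n]) for n in res.partition), columns=["node", "cluster"]
    )
    io.write_table(df, out / "clusters.tsv", digest)
    state["clusters"] = res
    n_clusters = len({c for c in df["cluster"] if c != "MCLnull"})
    return {"nodes": len(df), "clusters": n_clusters, "converged": res.converged}


def _stage_phylosignal(block, out, digest, seed, state):
    if "trees" in block:
        trees = read_trees(block["trees"])
    elif "tree" in state:
        trees = [state["tree"]]
    else:
        raise ConfigError("phylosignal stage needs trees")
    if "traits" in block:
        traits = io.read_table(block["traits"], index_col=0)
    else:
        traits = state.get("trait_df")
    if traits is None:
        raise ConfigError("phylosignal stage needs a trait table")
    ccfg = ConsentraitConfig(
        positive_fraction=float(block.get("positive_fraction", 0.90)),
        n_permutations=int(block.get("n_permutations", 1000)),
        alpha=float(block.get("alpha", 0.1)),
        seed=seed,
    )
    table = signal_table(
        trees, traits, ccfg,
        n_random=int(block.get("n_random", 1000)),
        n_brownian=int(block.get("n_brownian", 1000)),
        seed=seed,
    )
    io.write_table(table, out / "signal.tsv", digest)
    state["signal"] = table
    return {
        "traits": len(table),
        "tau_significant": int(table["tau_significant"].sum()),
        "D_significant": int(table["D_significant"].sum()),
    }


def _stage_ordination(block, out, digest, seed, state):
    counts = (
        io.read_table(block["counts"], index_col=0) if "counts" in block else state.get("counts")
    )
    meta = (
        pd.read_csv(block["metadata"]) if "metadata" in block else state.get("metadata")
    )
    if counts is None:
        raise ConfigError("ordination stage needs a count matrix")
    model = pca(counts, center=True, scale=bool(block.get("scale", False)))
    io.write_table(model.scores.reset_index(), out / "pca_scores.tsv", digest)
    io.write_table(model.loadings.reset_index(), out / "pca_loadings.tsv", digest)
    io.write_table(
        pd.DataFrame({"axis": model.scores.columns, "eigenvalue": model.eigenvalues,
                      "proportion": model.proportion_explained}),
        out / "pca_eigenvalues.tsv", digest,
    )
    report = {"samples": counts.shape[0], "features": counts.shape[1]}
    n_perm = int(block.get("n_permutations", 999))
    if meta is not None:
        meta = meta.set_index("genome_id").loc[counts.index].reset_index()
        fits = []
        for col in meta.columns:
            if col == "genome_id":
                continue
            v = meta[col]
            kind = "vector" if pd.api.types.is_numeric_dtype(v) else "factor"
            try:
                r = envfit(model.scores, v.to_numpy(), kind=kind,
                           n_permutations=n_perm, seed=seed, name=col)
            except ValueError:
                continue
            fits.append(
                {"variable": col, "kind": r.kind, "r_squared": r.r_squared,
                 "p_perm": r.p_perm,
                 "direction": "" if r.direction is None else ",".join(f"{x:.6f}" for x in r.direction)}
            )
        fits_df = pd.DataFrame(fits, columns=["variable", "kind", "r_squared", "p_perm", "direction"])
        io.write_table(fits_df, out / "envfit.tsv", digest)
        report["envfit_significant"] = int((fits_df["p_perm"] < 0.05).sum()) if len(fits_df) else 0
        group_col = block.get("group_column", "lineage")
        if group_col in meta.columns:
            disp = dispersion_test(model.scores.to_numpy()[:, :2], meta[group_col].to_numpy(),
                                   n_permutations=n_perm, seed=seed)
            io.write_table(
                pd.DataFrame([{"F": disp.F, "p_perm": disp.p_perm,
                               **{f"mean_dist_{k}": v for k, v in disp.group_mean_distance.items()}}]),
                out / "dispersion.tsv", digest,
            )
            report["dispersion_p"] = disp.p_perm
    state["pca"] = model
    return report


# --------------------------------------------------------------- validation
def validate_inputs(config) -> list[tuple[str, str]]:
    """Cross-reference checks on configured inputs; returns findings
    (source, message) without mutating anything."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    findings: list[tuple[str, str]] = []
    stages = cfg.get("stages", {})
    genes = None
    if "gff" in stages.get("neighborhoods", {}) or "gff" in stages.get("motifs", {}):
        path = stages.get("neighborhoods", {}).get("gff") or stages["motifs"]["gff"]
        try:
            genes, gff_findings = io.read_gff3(path, strict=False)
            for lineno, msg in gff_findings:
                findings.append((f"{path}:{lineno}", msg))
        except FileNotFoundError:
            findings.append((str(path), "missing input file"))
    mo = stages.get("motifs", {})
    if "upstreams" in mo:
        try:
            records = io.read_fasta(mo["upstreams"])
            if genes is not None and len(genes):
                unknown = set(records) - set(genes["gene_id"]) - set(genes["contig_id"])
                for rid in sorted(unknown):
                    findings.append((mo["upstreams"], f"record {rid} matches no gene or contig"))
        except FileNotFoundError:
            findings.append((mo["upstreams"], "missing input file"))
    ps = stages.get("phylosignal", {})
    if "trees" in ps and "traits" in ps:
        try:
            trees = read_trees(ps["trees"])
            traits = io.read_table(ps["traits"], index_col=0)
            tips = {lf.taxon.label for lf in trees[0].leaf_node_iter()}
            for tip in sorted(tips - set(traits.index)):
                findings.append((ps["trees"], f"tip {tip} absent from trait table"))
            for gid in sorted(set(traits.index) - tips):
                findings.append((ps["traits"], f"genome {gid} absent from tree"))
        except FileNotFoundError as exc:
            findings.append((str(exc.filename), "missing input file"))
    od = stages.get("ordination", {})
    if "counts" in od:
        try:
            counts = io.read_table(od["counts"], index_col=0)
            if counts.isna().any().any():
                findings.append((od["counts"], "count matrix is not rectangular/complete"))
        except FileNotFoundError:
            findings.append((od["counts"], "missing input file"))
    return findings
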
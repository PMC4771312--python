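"""Domain-hit parsing, filtering rules, and inventory construction."""

import io as _io
import itertools

import numpy as np
import pandas as pd
import pytest

from metaltrait.inventory import (
    BLAST_COLUMNS,
    DomainHit,
    FilterConfig,
    MalformedTableError,
    UnknownLabelError,
    build_inventory,
    filter_hits,
    parse_domain_hits,
    write_domain_hits,
)


def _row(q, s, evalue, bits, hclass="specific", fam="fatB"):
    cols = [q, s, "99", "100", "0", "0", "1", "100", "1", "100", str(evalue), str(bits), hclass, fam]
    return "\t".join(cols)


def _hit(q, g, m, e, b, hclass="specific", fam="fatB", rank=1):
    return DomainHit(q, g, m, fam, e, b, hclass, rank)


class TestParse:
    def test_empty_file(self):
        hits, rep = parse_domain_hits(_io.StringIO(""))
        assert hits == [] and rep.errors == []

    def test_rank_by_bitscore(self):
        text = "\n".join([_row("g1|p1", "m1", 1e-10, 50), _row("g1|p1", "m2", 1e-12, 40)])
        hits, _ = parse_domain_hits(_io.StringIO(text))
        ranks = {h.model_id: h.rank_for_query for h in hits}
        assert ranks == {"m1": 1, "m2": 2}

    def test_rank_ties_by_evalue_then_model(self):
        text = "\n".join(
            [
                _row("g1|p1", "mB", 1e-10, 50),
                _row("g1|p1", "mA", 1e-10, 50),
                _row("g1|p1", "mC", 1e-12, 50),
            ]
        )
        hits, _ = parse_domain_hits(_io.StringIO(text))
        order = [h.model_id for h in sorted(hits, key=lambda h: h.rank_for_query)]
        assert order == ["mC", "mA", "mB"]

    def test_malformed_rows_collected_with_line_numbers(self):
        text = "\n".join([_row("g1|p1", "m1", 1e-10, 50)] * 9 + ["bad\trow"])
        hits, rep = parse_domain_hits(_io.StringIO(text))
        assert len(hits) == 9
        assert rep.errors == [(10, rep.errors[0][1])]

    def test_fatal_above_error_fraction(self):
        text = "\n".join(["junk"] * 5 + [_row("g1|p1", "m1", 1e-10, 50)])
        with pytest.raises(MalformedTableError):
            parse_domain_hits(_io.StringIO(text))

    def test_roundtrip_write_parse(self):
        rng = np.random.default_rng(0)
        hits = []
        for i in range(1000):
            hits.append(
                DomainHit(
                    f"g{i % 20}|p{i}", f"g{i % 20}", f"m{rng.integers(50)}", "fatB",
                    float(10.0 ** -rng.integers(6, 30)), float(rng.integers(40, 300)),
                    "specific",
                )
            )
        buf = _io.StringIO()
        write_domain_hits(hits, buf)
        buf.seek(0)
        back, rep = parse_domain_hits(buf)
        assert rep.errors == [] and len(back) == 1000
        key = lambda h: (h.query_id, h.model_id)
        for a, b in zip(sorted(hits, key=key), sorted(back, key=key)):
            assert (a.query_id, a.genome_id, a.model_id, a.evalue, a.bitscore) == (
                b.query_id, b.genome_id, b.model_id, b.evalue, b.bitscore,
            )


def brute_force_bidirectional(hits):
    """Independent statement of the mutual-best rule by direct enumeration."""
    kept = []
    for h in hits:
        same_query = [x for x in hits if x.query_id == h.query_id]
        best_model = min(same_query, key=lambda x: (-x.bitscore, x.evalue, x.model_id))
        same_model = [
            x for x in hits if x.model_id == h.model_id and x.genome_id == h.genome_id
        ]
        best_query = min(same_model, key=lambda x: (-x.bitscore, x.evalue, x.query_id))
        if best_model.model_id == h.model_id and best_query.query_id == h.query_id:
            kept.append(h)
    return kept


class TestFilter:
    def test_evalue_threshold_strict(self):
        hits = [_hit("g|p", "g", "m", 1e-4, 50)]
        assert filter_hits(hits) == []
        hits = [_hit("g|p", "g", "m", 1e-10, 50)]
        assert len(filter_hits(hits)) == 1

    def test_nonspecific_dropped_superfamily_tagged(self):
        hits = [
            _hit("g|p1", "g", "m1", 1e-10, 50, "nonspecific"),
            _hit("g|p2", "g", "m2", 1e-10, 50, "superfamily"),
        ]
        out = filter_hits(hits)
        assert len(out) == 1 and out[0].superfamily_fallback

    def test_superfamily_not_kept_when_specific_survives(self):
        hits = [
            _hit("g|p1", "g", "m1", 1e-10, 60, "specific", rank=1),
            _hit("g|p1", "g", "m2", 1e-10, 50, "superfamily", rank=2),
        ]
        out = filter_hits(hits)
        assert [h.hit_class for h in out] == ["specific"]

    def test_bidirectional_matches_brute_force(self):
        # every bitscore assignment on a 3 queries x 3 models grid
        rng = np.random.default_rng(5)
        for _ in range(200):
            scores = rng.integers(40, 46, size=(3, 3))
            hits = []
            for q, m in itertools.product(range(3), range(3)):
                hits.append(
                    _hit(f"g|p{q}", "g", f"m{m}", 1e-10, float(scores[q, m]))
                )
            ranked = []
            by_q = {}
            for h in hits:
                by_q.setdefault(h.query_id, []).append(h)
            from dataclasses import replace

            for group in by_q.values():
                group.sort(key=lambda h: (-h.bitscore, h.evalue, h.model_id))
                ranked.extend(replace(h, rank_for_query=r) for r, h in enumerate(group, 1))
            got = {(h.query_id, h.model_id) for h in filter_hits(ranked)}
            want = {(h.query_id, h.model_id) for h in brute_force_bidirectional(ranked)}
            assert got == want

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        hits = []
        for q, m in itertools.product(range(4), range(4)):
            hits.append(_hit(f"g|p{q}", "g", f"m{m}", 1e-10, float(rng.integers(40, 80))))
        from metaltrait.inventory import _rank

        ranked = _rank(hits)
        once = filter_hits(ranked)
        assert filter_hits(once) == once


class TestInventory:
    def test_zero_hits_declared_shape(self):
        inv = build_inventory([], ["g1", "g2"], ["fatB", "fhuD"])
        assert inv.shape == (2, 2) and (inv == 0).all().all()

    def test_counts_and_binary(self):
        hits = [
            _hit("g1|p1", "g1", "m1", 1e-10, 50),
            _hit("g1|p2", "g1", "m2", 1e-10, 50),
        ]
        inv = build_inventory(hits, ["g1"], ["fatB"])
        assert inv.loc["g1", "fatB"] == 2

    def test_per_protein_vs_per_domain(self):
        hits = [
            _hit("g1|p1", "g1", "m1", 1e-10, 50),
            _hit("g1|p1", "g1", "m2", 1e-10, 45),
        ]
        assert build_inventory(hits, ["g1"], ["fatB"]).loc["g1", "fatB"] == 1
        assert (
            build_inventory(hits, ["g1"], ["fatB"], per_domain=True).loc["g1", "fatB"] == 2
        )

    def test_unknown_labels_raise(self):
        with pytest.raises(UnknownLabelError):
            build_inventory([_hit("gX|p", "gX", "m", 1e-10, 50)], ["g1"], ["fatB"])

    def test_row_order_invariance_and_count_conservation(self):
        rng = np.random.default_rng(3)
        hits = [
            _hit(f"g{rng.integers(3)}|p{i}", f"g{i % 3}", "m", 1e-10, 50.0,
                 fam=["fatB", "fhuD"][i % 2])
            for i in range(30)
        ]
        genomes, fams = ["g0", "g1", "g2"], ["fatB", "fhuD"]
        inv1 = build_inventory(hits, genomes, fams)
        inv2 = build_inventory(list(reversed(hits)), genomes, fams)
        pd.testing.assert_frame_equal(inv1, inv2)
        assert inv1.to_numpy().sum() == len({(h.query_id, h.family_label) for h in hits})

    def test_planted_scenario_counts_exact(self, small_genes):
        genes, _, _ = small_genes
        from metaltrait.pipeline import _hits_from_genes
        from metaltrait.inventory import _rank

        df = _hits_from_genes(genes)
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", header=False, index=False)
        buf.seek(0)
        hits, _ = parse_domain_hits(buf)
        kept = filter_hits(hits)
        genomes = sorted(genes["genome_id"].unique())
        fams = sorted({f for fs in genes["families"] for f in fs if f != "hyp"})
        inv = build_inventory(kept, genomes, fams)
        for g in genomes:
            sub = genes[genes["genome_id"] == g]
            for fam in fams:
                truth = sum(fam in fs for fs in sub["families"])
                assert inv.loc[g, fam] == truth
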
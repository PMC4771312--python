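"""Fur-box-like regulatory motif detection in upstream regions.

Two detection modes over DNA records:

* reference scan — exhaustive Hamming-distance comparison of every window
  (both strands) against a set of known motif sequences (e.g. 19-bp iron-rhodo
  box motifs), reporting windows within a mismatch budget;
* inverted-repeat scan — structural detection of arm/spacer palindromes such
  as the 15-bp (7-1-7) Fur box, scoring reverse-complement pairing of the arm
  positions.

Hits can then be assigned to the nearest downstream gene within a promoter
window. Coordinates are 0-based half-open; an upstream record inherits the
orientation of its gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotifSpec",
    "MotifHit",
    "scan_reference_motifs",
    "scan_inverted_repeats",
    "assign_hits_to_genes",
    "revcomp",
]

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(table)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifSpec:
    name: str
    length: int
    reference_seqs: tuple[str, ...] = ()
    arm_length: int | None = None
    spacer: int | None = None
    max_mismatches: int = 0
    min_palindromic_pairs: int = 0

    def __post_init__(self):
        if self.arm_length is not None:
            if self.spacer is None or 2 * self.arm_length + self.spacer != self.length:
                raise ValueError("arm_length*2 + spacer must equal length")
        if not (0 <= self.max_mismatches < self.length):
            raise ValueError("max_mismatches must lie in [0, length)")
        for r in self.reference_seqs:
            if len(r) != self.length:
                raise ValueError(f"reference {r!r} is not {self.length} bp")


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    start: int
    strand: str
    mismatches: int
    palindromic_pairs: int
    motif_name: str
    assigned_gene: str | None = None


def _window_matrix(enc: np.ndarray, L: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(enc, L)


def _min_mismatches(windows: np.ndarray, refs: list[np.ndarray]) -> np.ndarray:
    """Per-window minimum Hamming distance to any reference; non-ACGT bases
    always count as mismatches."""
    best = None
    for ref in refs:
        match = (windows == ref[None, :]) & (windows < 4) & (ref[None, :] < 4)
        mm = windows.shape[1] - match.sum(axis=1)
        best = mm if best is None else np.minimum(best, mm)
    return best


def scan_reference_motifs(records: dict[str, str], spec: MotifSpec) -> list[MotifHit]:
    """Hamming scan of every window on both strands against the reference set.

    Each qualifying (record, start, strand) is reported once with its best
    (minimum) mismatch count over all references; overlapping hits are kept.
    A minus-strand hit at forward-coordinate ``start`` means the reverse
    complement of that window matches a reference.
    """
    if not spec.reference_seqs:
        raise ValueError("reference scan requires reference_seqs")
    L = spec.length
    refs_fwd = [_encode(r) for r in spec.reference_seqs]
    refs_rev = [_encode(revcomp(r)) for r in spec.reference_seqs]
    hits = []
    for rid, seq in records.items():
        if len(seq) < L:
            continue
        win = _window_matrix(_encode(seq), L)
        for strand, refs in (("+", refs_fwd), ("-", refs_rev)):
            mm = _min_mismatches(win, refs)
            for pos in np.nonzero(mm <= spec.max_mismatches)[0]:
                hits.append(
                    MotifHit(rid, int(pos), strand, int(mm[pos]), 0, spec.name)
                )
    return hits


def scan_inverted_repeats(records: dict[str, str], spec: MotifSpec) -> list[MotifHit]:
    """Detect arm-spacer-arm inverted repeats (e.g. 7-1-7 Fur boxes).

    A window qualifies when at least ``min_palindromic_pairs`` of its arm
    positions pair as reverse complements (position i against position
    L-1-i), and — if reference sequences are supplied — it also satisfies the
    Hamming criterion against them. Pairing is strand-symmetric, so windows
    are reported once on the forward strand.
    """
    if spec.arm_length is None:
        raise ValueError("inverted-repeat scan requires arm_length/spacer")
    L, A = spec.length, spec.arm_length
    refs = [_encode(r) for r in spec.reference_seqs]
    hits = []
    for rid, seq in records.items():
        if len(seq) < L:
            continue
        win = _window_matrix(_encode(seq), L)
        left = win[:, :A]
        right = win[:, L - A:][:, ::-1]
        pairs = ((_COMP[left] == right) & (left < 4) & (right < 4)).sum(axis=1)
        ok = pairs >= spec.min_palindromic_pairs
        if refs:
            ok &= _min_mismatches(win, refs) <= spec.max_mismatches
            mm = _min_mismatches(win, refs)
        else:
            mm = np.zeros(len(win), dtype=int)
        for pos in np.nonzero(ok)[0]:
            hits.append(
                MotifHit(rid, int(pos), "+", int(mm[pos]), int(pairs[pos]), spec.name)
            )
    return hits


def assign_hits_to_genes(
    hits: list[MotifHit],
    genes: pd.DataFrame,
    motif_length: int,
    window_bp: int = 300,
    upstream_len: int = 300,
) -> list[MotifHit]:
    """Assign each hit to the nearest downstream gene start within ``window_bp``.

    Two addressing modes:

    * hits on per-gene upstream records (record id equals a gene id): the
      record covers the ``upstream_len`` bases immediately 5' of the gene in
      gene orientation, so the distance to the start codon is
      ``upstream_len - (start + motif_length)``;
    * hits on contigs: the nearest gene on the matching strand whose 5' start
      lies downstream of the motif within ``window_bp``.

    Unassignable hits keep ``assigned_gene=None``.
    """
    gene_ids = set(genes["gene_id"])
    by_contig: dict[str, pd.DataFrame] = {
        c: df.sort_values("start") for c, df in genes.groupby("contig_id")
    }
    out = []
    for h in hits:
        if h.record_id in gene_ids:
            dist = upstream_len - (h.start + motif_length)
            gene = h.record_id if 0 <= dist <= window_bp else None
        elif h.record_id in by_contig:
            gene = _nearest_downstream(h, by_contig[h.record_id], motif_length, window_bp)
        else:
            raise KeyError(f"hit references unknown record {h.record_id!r}")
        out.append(
            MotifHit(h.record_id, h.start, h.strand, h.mismatches,
                     h.palindromic_pairs, h.motif_name, gene)
        )
    return out


def _nearest_downstream(h: MotifHit, contig_genes: pd.DataFrame, mlen: int, window_bp: int):
    best, best_dist = None, None
    for _, g in contig_genes.iterrows():
        if g["strand"] != h.strand:
            continue
        if g["strand"] == "+":
            dist = g["start"] - (h.start + mlen)
        else:
            dist = h.start - g["end"]
        if 0 <= dist <= window_bp and (best_dist is None or dist < best_dist):
            best, best_dist = g["gene_id"], dist
    return best
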
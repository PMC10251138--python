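"""Ka/Ks by the Nei–Gojobori method on codon-aligned CDS pairs.

Synonymous/nonsynonymous site fractions are averaged over the two sequences;
for codons differing at several positions the minimal mutational pathways are
weighted equally, dropping pathways that pass through stop codons (if every
pathway is blocked, all are used and steps touching a stop count as
nonsynonymous).  Mutations to stop codons are excluded from the per-position
site denominators, so S + N = 3 x codons exactly.  Proportions are corrected
with the Jukes-Cantor transform d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from statistics import median

from Bio.Data.CodonTable import standard_dna_table

from .model import PaleohexkitError

NUCLEOTIDES = "ACGT"
_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


class CodonError(PaleohexkitError):
    pass


class SaturationWarning(PaleohexkitError):
    pass


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in _STOPS:
        return None
    return _TABLE[codon]


@dataclass
class CodonPair:
    """A gap-free codon alignment of two CDS fragments."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise CodonError("aligned CDS lengths differ")
        if len(self.seq_a) % 3:
            raise CodonError("aligned CDS length is not a multiple of 3")
        for seq, label in ((self.seq_a, "a"), (self.seq_b, "b")):
            for i in range(0, len(seq), 3):
                codon = seq[i:i + 3]
                if any(c not in NUCLEOTIDES for c in codon):
                    raise CodonError(f"non-ACGT codon {codon!r} in seq_{label}")
                if codon in _STOPS:
                    raise CodonError(
                        f"internal stop codon {codon!r} at {i} in seq_{label}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


def make_codon_pair(cds_a: str, cds_b: str, protein_alignment=None,
                    drop_ambiguous: bool = True) -> CodonPair:
    """Build a codon alignment from two CDSs.

    Without a protein alignment the sequences must be equal length and are
    paired positionally.  With one (two equal-length aligned amino-acid
    strings, ``-`` for gaps) gap columns are dropped from both.  Codon columns
    containing ambiguity codes are dropped pairwise when ``drop_ambiguous``.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) % 3 or len(cds_b) % 3:
        raise CodonError("CDS length is not a multiple of 3")
    if protein_alignment is None:
        if len(cds_a) != len(cds_b):
            raise CodonError("CDS lengths differ and no protein alignment given")
        cols = list(zip((cds_a[i:i + 3] for i in range(0, len(cds_a), 3)),
                        (cds_b[i:i + 3] for i in range(0, len(cds_b), 3))))
    else:
        aln_a, aln_b = protein_alignment
        if len(aln_a) != len(aln_b):
            raise CodonError("protein alignment rows differ in length")
        cols = []
        ia = ib = 0
        for ca, cb in zip(aln_a, aln_b):
            codon_a = cds_a[3 * ia:3 * ia + 3] if ca != "-" else None
            codon_b = cds_b[3 * ib:3 * ib + 3] if cb != "-" else None
            if ca != "-":
                if codon_a and codon_a not in _STOPS and \
                        all(c in NUCLEOTIDES for c in codon_a) and \
                        translate_codon(codon_a) != ca:
                    raise CodonError(
                        f"protein alignment does not match translation of cds_a "
                        f"at column with {ca!r}")
                ia += 1
            if cb != "-":
                ib += 1
            if codon_a is not None and codon_b is not None:
                cols.append((codon_a, codon_b))
    kept_a, kept_b = [], []
    for codon_a, codon_b in cols:
        if drop_ambiguous and any(
                c not in NUCLEOTIDES for c in codon_a + codon_b):
            continue
        kept_a.append(codon_a)
        kept_b.append(codon_b)
    return CodonPair("".join(kept_a), "".join(kept_b))


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of a sense codon.

    Per position, the fraction of non-stop single-nucleotide fates that are
    synonymous; contributions sum to exactly 3 over the codon.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        fates = [codon[:pos] + nt + codon[pos + 1:]
                 for nt in NUCLEOTIDES if nt != codon[pos]]
        valid = [f for f in fates if f not in _STOPS]
        if valid:
            syn += sum(1 for f in valid if _TABLE[f] == aa) / len(valid)
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons.

    Equal weighting of the minimal mutational pathways; pathways through stop
    codons are dropped unless all pathways are blocked, in which case all are
    used and steps involving a stop count as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = codon_a
        through_stop = False
        syn = nonsyn = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if cur in _STOPS or nxt in _STOPS:
                through_stop = True
                nonsyn += 1
            elif _TABLE[cur] == _TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((through_stop, syn, nonsyn))
    open_paths = [(s, n) for blocked, s, n in pathways if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in pathways]
    syn = sum(s for s, _ in open_paths) / len(open_paths)
    nonsyn = sum(n for _, n in open_paths) / len(open_paths)
    return syn, nonsyn


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


@dataclass
class KsResult:
    ka: float | None
    ks: float | None
    s_sites: float
    n_sites: float
    status: str = "ok"


def nei_gojobori(pair: CodonPair) -> KsResult:
    """Ka and Ks for a codon pair by Nei-Gojobori (1986)."""
    S = N = Sd = Nd = 0.0
    for codon_a, codon_b in pair.codons():
        sa, na = codon_sites(codon_a)
        sb, nb = codon_sites(codon_b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = codon_differences(codon_a, codon_b)
        Sd += ds
        Nd += dn
    if S <= 0.0:
        return KsResult(None, None, S, N, "no synonymous sites")
    pS, pN = Sd / S, Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    status = "ok"
    if ks is None:
        status = "saturated"
    elif ka is None:
        status = "ka_saturated"
    return KsResult(ka, ks, S, N, status)


def pair_ks(cds_a: str, cds_b: str, protein_alignment=None) -> KsResult:
    return nei_gojobori(make_codon_pair(cds_a, cds_b, protein_alignment))


def annotate_block_ks(block, cds_store: dict[str, str],
                      ks_lookup: dict[tuple[str, str], float] | None = None):
    """Attach per-anchor Ks and the block Ks median.

    Ks comes from ``ks_lookup`` (precomputed pair table, either key order)
    when given, else from Nei-Gojobori on the anchors' CDS.  Anchors with
    undefined (saturated) Ks are excluded from the median; a block whose
    anchors are all undefined gets ``ks_median = None``.
    """
    values = []
    for anchor in block.anchors:
        ks = None
        if ks_lookup is not None:
            ks = ks_lookup.get((anchor.gene_a, anchor.gene_b))
            if ks is None:
                ks = ks_lookup.get((anchor.gene_b, anchor.gene_a))
        elif anchor.gene_a in cds_store and anchor.gene_b in cds_store:
            res = pair_ks(cds_store[anchor.gene_a], cds_store[anchor.gene_b])
            ks = res.ks
        anchor.ks = ks
        if ks is not None and not math.isnan(ks):
            values.append(ks)
    block.ks_median = median(values) if values else None
    return block
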
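"""Collinear block chaining and orthology depth ratios.

Blocks are chains of homologous gene pairs (anchors) strictly monotone in the
first genome's gene order and monotone (increasing = ``same`` orientation, or
decreasing = ``inverted``) in the second, with at most ``max_gap`` intervening
genes between consecutive anchors on either genome.  Chains are found per
chromosome pair by dynamic programming and extracted greedily by anchor count,
so no two blocks of the same chromosome pair share an anchor.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .model import Genome, HomologyHit, PaleohexkitError


@dataclass
class Anchor:
    gene_a: str
    gene_b: str
    order_a: int
    order_b: int
    ks: float | None = None


@dataclass
class SyntenyBlock:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    block_id: int = -1
    event: str | None = None
    ks_median: float | None = None

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        orders = [a.order_a for a in self.anchors]
        return min(orders), max(orders)

    @property
    def span_b(self) -> tuple[int, int]:
        orders = [a.order_b for a in self.anchors]
        return min(orders), max(orders)


def _best_chain(points, max_gap, direction):
    """Longest chain over (oa, ob, idx) points; returns list of idx.

    Strictly increasing in oa; strictly increasing (direction=+1) or strictly
    decreasing (-1) in ob; order gaps on both axes <= max_gap intervening
    genes (index difference <= max_gap + 1).
    """
    if not points:
        return []
    pts = sorted(points, key=lambda p: (p[0], direction * p[1]))
    n = len(pts)
    best = [1] * n
    prev = [-1] * n
    step = max_gap + 1
    for j in range(n):
        oa_j, ob_j, _ = pts[j]
        for i in range(j - 1, -1, -1):
            oa_i, ob_i, _ = pts[i]
            da = oa_j - oa_i
            if da > step:
                break  # sorted by oa: earlier points are even farther
            if da < 1:
                continue
            db = direction * (ob_j - ob_i)
            if db < 1 or db > step:
                continue
            if best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    j = max(range(n), key=lambda k: best[k])
    chain = []
    while j != -1:
        chain.append(pts[j][2])
        j = prev[j]
    chain.reverse()
    return chain


def chain_collinear_blocks(hits, genome_a: Genome, genome_b: Genome,
                           max_gap: int = 50, min_anchors: int = 5):
    """Chain filtered homology hits into collinear synteny blocks.

    For a self-comparison (``genome_a is genome_b`` or equal names) self-pairs
    are ignored and each unordered pair is used once, oriented so the
    lower-coordinate gene is on the A side (avoids mirrored duplicate blocks).
    Cross-genome comparisons are computed with the lexicographically smaller
    genome name on the A side and transposed back, so A-vs-B and B-vs-A give
    exactly transposed blocks even where equal-score chains leave the
    extraction order ambiguous.
    """
    if genome_a.name > genome_b.name:
        swapped = [HomologyHit(h.subject_id, h.query_id, h.evalue, h.score)
                   for h in hits]
        blocks = chain_collinear_blocks(swapped, genome_b, genome_a,
                                        max_gap=max_gap,
                                        min_anchors=min_anchors)
        return [_transpose_block(b) for b in blocks]
    self_cmp = genome_a.name == genome_b.name
    by_pair: dict[tuple[str, str], list] = defaultdict(list)
    seen = set()
    for h in hits:
        q, s = h.query_id, h.subject_id
        if q not in genome_a or s not in genome_b:
            if self_cmp:
                continue
            missing = q if q not in genome_a else s
            raise PaleohexkitError(f"unknown gene id {missing!r} in hits")
        ga, gb = genome_a.get(q), genome_b.get(s)
        if self_cmp:
            if q == s:
                continue
            if (gb.chromosome, gb.order_index) < (ga.chromosome, ga.order_index):
                ga, gb = gb, ga
            key = (ga.id, gb.id)
            if key in seen:
                continue
            seen.add(key)
        by_pair[(ga.chromosome, gb.chromosome)].append(
            (ga.order_index, gb.order_index, (ga.id, gb.id)))

    blocks = []
    for (ca, cb), pts in sorted(by_pair.items()):
        # Deduplicate identical (order, order) points (multiple hit rows).
        pts = list({(oa, ob): (oa, ob, ids) for oa, ob, ids in pts}.values())
        remaining = pts
        while True:
            chains = []
            for direction, orient in ((1, "same"), (-1, "inverted")):
                idxs = _best_chain(
                    [(oa, ob, k) for k, (oa, ob, _) in enumerate(remaining)],
                    max_gap, direction)
                if len(idxs) >= min_anchors:
                    chains.append((len(idxs), orient, idxs))
            if not chains:
                break
            chains.sort(key=lambda c: (-c[0], c[1]))
            _, orient, idxs = chains[0]
            anchors = [Anchor(remaining[k][2][0], remaining[k][2][1],
                              remaining[k][0], remaining[k][1])
                       for k in idxs]
            blocks.append(SyntenyBlock(genome_a.name, genome_b.name, ca, cb,
                                       anchors, orient))
            chosen = set(idxs)
            remaining = [p for k, p in enumerate(remaining) if k not in chosen]
            if len(remaining) < min_anchors:
                break
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def _transpose_block(b: SyntenyBlock) -> SyntenyBlock:
    anchors = [Anchor(a.gene_b, a.gene_a, a.order_b, a.order_a, a.ks)
               for a in b.anchors]
    anchors.sort(key=lambda a: a.order_a)
    return SyntenyBlock(b.genome_b, b.genome_a, b.chrom_b, b.chrom_a,
                        anchors, b.orientation, b.block_id, b.event,
                        b.ks_median)


def coverage_depths(blocks, genome: Genome, side: str) -> dict[str, int]:
    """Per-gene count of blocks whose anchor span covers the gene."""
    depth: Counter = Counter()
    by_chrom = defaultdict(list)
    for b in blocks:
        if side == "a":
            by_chrom[b.chrom_a].append(b.span_a)
        else:
            by_chrom[b.chrom_b].append(b.span_b)
    for chrom, spans in by_chrom.items():
        genes = genome.chromosomes.get(chrom, [])
        for lo, hi in spans:
            for g in genes[lo:hi + 1]:
                depth[g.id] += 1
    return dict(depth)


def block_depth_ratio(blocks, ref_genome: Genome, query_genome: Genome):
    """Orthology depth ratio (d_ref : d_query) of a block set.

    At a typical locus, ``d_ref`` regions of the reference correspond to
    ``d_query`` regions of the query: ``d_query`` is the modal number of
    blocks covering a covered reference gene, ``d_ref`` the modal number
    covering a covered query gene (1:3 for a reference tripled in the
    query).  Returns ``None`` (flagged: no blocks) when the set is empty.
    """
    if not blocks:
        return None
    ref_cov = coverage_depths(blocks, ref_genome, "a")
    query_cov = coverage_depths(blocks, query_genome, "b")
    if not ref_cov or not query_cov:
        return None
    mode = lambda d: Counter(d.values()).most_common(1)[0][0]
    return mode(query_cov), mode(ref_cov)


def blocks_to_frame(blocks) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append((b.block_id, b.genome_a, b.genome_b, b.chrom_a,
                         b.chrom_b, a.gene_a, a.gene_b, a.order_a, a.order_b,
                         b.orientation, b.event or "",
                         "" if a.ks is None else a.ks))
    return pd.DataFrame(rows, columns=[
        "block_id", "genome_a", "genome_b", "chrom_a", "chrom_b", "gene_a",
        "gene_b", "order_a", "order_b", "orientation", "event", "ks"])


def write_blocks(blocks, path) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)


def read_blocks(path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    blocks = []
    for bid, grp in df.groupby("block_id", sort=True):
        first = grp.iloc[0]
        anchors = [Anchor(r.gene_a, r.gene_b, int(r.order_a), int(r.order_b),
                          None if pd.isna(r.ks) else float(r.ks))
                   for r in grp.itertuples()]
        b = SyntenyBlock(first.genome_a, first.genome_b, str(first.chrom_a),
                         str(first.chrom_b), anchors, first.orientation,
                         block_id=int(bid))
        ev = first.event
        if isinstance(ev, str) and ev:
            b.event = ev
        ks_vals = [a.ks for a in anchors if a.ks is not None
                   and not math.isnan(a.ks)]
        if ks_vals:
            b.ks_median = float(pd.Series(ks_vals).median())
        blocks.append(b)
    return blocks
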
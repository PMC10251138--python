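"""Event classification of synteny blocks and the reference-anchored
multigenome alignment table.

The table has one row per reference gene and, per reference panel (one panel
per copy the reference's own hexaploidy produced), one reference column plus
``m_g`` slot columns per target genome, where ``m_g = 3 * 2**N_g`` for a
genome carrying the shared hexaploidy and ``N_g`` later tetraploidies.  A dot
marks an ortholog that is lost or translocated; a side channel distinguishes
the two.  Slots are assigned region-wise: covering blocks are clustered along
the reference and ranked by retention, most-retained region first, so slot 1
tracks the least fractionated subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import Genome, PaleohexkitError

DOT = "."


class LayoutError(PaleohexkitError):
    pass


@dataclass
class EventPeak:
    label: str
    mu: float
    tolerance: float = 0.3


@dataclass
class EventPeakSet:
    peaks: list[EventPeak]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.peaks]
        if len(set(labels)) != len(labels):
            raise ValueError("event labels must be unique")
        if any(p.mu <= 0 for p in self.peaks):
            raise ValueError("event peaks must be positive")


def classify_block_event(block, peaks: EventPeakSet, tie_eps: float = 1e-9):
    """Label a block with the event whose Ks peak its median is closest to.

    Returns the label of the nearest within-tolerance peak, or
    ``"unclassified"`` / ``"unclassified(tie)"``.  The label is also written
    onto ``block.event``.
    """
    if block.ks_median is None:
        raise PaleohexkitError("block has no Ks median; annotate Ks first")
    in_range = [(abs(block.ks_median - p.mu), p.label)
                for p in peaks.peaks if abs(block.ks_median - p.mu) <= p.tolerance]
    if not in_range:
        block.event = "unclassified"
    else:
        in_range.sort()
        if len(in_range) > 1 and in_range[1][0] - in_range[0][0] < tie_eps:
            block.event = "unclassified(tie)"
        else:
            block.event = in_range[0][1]
    return block.event


def count_event_homologs(blocks, event: str) -> tuple[int, int]:
    """(pairs, distinct genes) among anchors of blocks labelled ``event``."""
    n_pairs = 0
    genes = set()
    for b in blocks:
        if b.event != event:
            continue
        n_pairs += len(b.anchors)
        for a in b.anchors:
            genes.add(a.gene_a)
            genes.add(a.gene_b)
    return n_pairs, len(genes)


@dataclass(frozen=True)
class ColumnSpec:
    genome: str
    panel: int  # 1-based reference panel
    slot: int   # 0 = the reference column of the panel; 1..m_g otherwise


@dataclass
class TableLayout:
    reference: str
    columns: list[ColumnSpec]
    slots_per_genome: dict[str, int]
    n_panels: int

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def genome_slot_count(shared_hexaploidy: bool, n_tetraploidies: int) -> int:
    if not shared_hexaploidy:
        raise LayoutError(
            "genome lacking the shared hexaploidy cannot be represented in "
            "this alignment framework")
    return 3 * 2 ** n_tetraploidies


def plan_table_layout(reference: str, genomes: dict[str, tuple[bool, int]],
                      reference_panels: int = 3) -> TableLayout:
    """Column layout for a reference plus target genomes.

    ``genomes`` maps genome name -> (carries shared hexaploidy, number of
    later tetraploidies N_g).  Each of the ``reference_panels`` panels holds
    one reference column and ``m_g = 3 * 2**N_g`` slots per genome, so the
    total is ``panels * (1 + sum m_g)`` columns (30 for a reference plus one
    hexaploid and one hexaploid+tetraploid genome).
    """
    slots = {name: genome_slot_count(hexa, n_tet)
             for name, (hexa, n_tet) in genomes.items()}
    columns = []
    for panel in range(1, reference_panels + 1):
        columns.append(ColumnSpec(reference, panel, 0))
        for name in genomes:
            for s in range(1, slots[name] + 1):
                columns.append(ColumnSpec(name, panel, s))
    return TableLayout(reference, columns, slots, reference_panels)


@dataclass
class Region:
    """A run of reference genes covered by one stable set of blocks."""

    chromosome: str
    start: int  # reference order_index, inclusive
    end: int    # inclusive
    copies: list = field(default_factory=list)  # [(block, retained_in_region)]


def _elementary_regions(blocks, chrom_len):
    """Split [0, chrom_len) at block span boundaries; merge runs with equal
    covering sets."""
    bounds = {0, chrom_len}
    for b in blocks:
        lo, hi = b.span_a
        bounds.add(lo)
        bounds.add(hi + 1)
    cuts = sorted(x for x in bounds if 0 <= x <= chrom_len)
    raw = []
    for lo, hi in zip(cuts, cuts[1:]):
        cover = frozenset(b.block_id for b in blocks
                          if b.span_a[0] <= lo and hi - 1 <= b.span_a[1])
        raw.append((lo, hi - 1, cover))
    merged = []
    for lo, hi, cover in raw:
        if merged and merged[-1][2] == cover:
            prev = merged.pop()
            merged.append((prev[0], hi, cover))
        else:
            merged.append((lo, hi, cover))
    return merged


def build_regions(blocks_by_genome: dict[str, list], ref: Genome,
                  genome: str) -> list[Region]:
    """Cluster one genome's orthologous blocks into reference regions."""
    regions = []
    blocks = blocks_by_genome.get(genome, [])
    by_chrom: dict[str, list] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom_a, []).append(b)
    for chrom, genes in ref.chromosomes.items():
        chrom_blocks = by_chrom.get(chrom, [])
        if not chrom_blocks:
            continue
        index = {b.block_id: b for b in chrom_blocks}
        for lo, hi, cover in _elementary_regions(chrom_blocks, len(genes)):
            if not cover:
                continue
            copies = []
            for bid in cover:
                b = index[bid]
                retained = sum(1 for a in b.anchors if lo <= a.order_a <= hi)
                copies.append((b, retained))
            copies.sort(key=lambda c: (-c[1], c[0].chrom_b, c[0].block_id))
            regions.append(Region(chrom, lo, hi, copies))
    return regions


@dataclass
class AlignmentTable:
    layout: TableLayout
    frame: pd.DataFrame              # rows: reference genes; columns: flat specs
    regions: dict[str, list[Region]]  # per target genome
    overflow: list = field(default_factory=list)
    translocated: set = field(default_factory=set)

    @property
    def n_columns(self) -> int:
        return self.layout.n_columns

    def column_name(self, spec: ColumnSpec) -> str:
        return f"{spec.genome}|p{spec.panel}|s{spec.slot}"

    def column(self, genome: str, panel: int, slot: int) -> pd.Series:
        return self.frame[f"{genome}|p{panel}|s{slot}"]


def fill_table(layout: TableLayout, ref: Genome,
               orthologous_blocks: dict[str, list],
               paralogous_blocks: list | None = None,
               genomes: dict[str, Genome] | None = None) -> AlignmentTable:
    """Assemble the alignment table from classified blocks.

    ``orthologous_blocks`` maps target genome name -> its blocks against the
    reference (reference on the A side).  ``paralogous_blocks`` are
    reference-internal blocks of the reference's own hexaploidy; they fill
    panels 2..n.  Slot assignment is region-wise, so neighbouring genes of a
    block share a slot.  A gene present in the target genome but absent from
    all covering blocks is recorded as translocated; both render as dots.
    """
    ref_rows = [(g.chromosome, g.order_index, g.id) for g in ref.genes()]
    n = len(ref_rows)
    data = {}
    # Reference columns: panel 1 is the gene itself; later panels take the
    # paralog of the gene's hexaploidy copies where known.
    panel_paralogs = _reference_panels(ref, paralogous_blocks,
                                       layout.n_panels)
    for panel in range(1, layout.n_panels + 1):
        name = f"{layout.reference}|p{panel}|s0"
        if panel == 1:
            data[name] = [r[2] for r in ref_rows]
        else:
            data[name] = [panel_paralogs.get((r[2], panel), DOT)
                          for r in ref_rows]

    regions_by_genome = {}
    overflow = []
    translocated = set()
    row_of = {r[2]: i for i, r in enumerate(ref_rows)}
    for genome, m_g in layout.slots_per_genome.items():
        for panel in range(1, layout.n_panels + 1):
            for s in range(1, m_g + 1):
                data[f"{genome}|p{panel}|s{s}"] = [DOT] * n
        regions = build_regions(orthologous_blocks, ref, genome)
        regions_by_genome[genome] = regions
        for region in regions:
            if len(region.copies) > m_g:
                overflow.append((genome, region.chromosome, region.start,
                                 region.end,
                                 [b.block_id for b, _ in region.copies[m_g:]]))
            for slot_idx, (block, _) in enumerate(region.copies[:m_g], start=1):
                anchor_of = {a.gene_a: a.gene_b for a in block.anchors}
                chrom_genes = ref.chromosomes[region.chromosome]
                for g in chrom_genes[region.start:region.end + 1]:
                    cell = anchor_of.get(g.id)
                    if cell is not None:
                        data[f"{genome}|p1|s{slot_idx}"][row_of[g.id]] = cell
        if genomes and genome in genomes:
            present = {gid for gid in (g.id for g in genomes[genome].genes())}
            placed = set()
            for col, cells in data.items():
                if col.startswith(f"{genome}|"):
                    placed.update(c for c in cells if c != DOT)
            # genes syntenically placeable nowhere: translocated candidates
            translocated |= (present - placed)

    frame = pd.DataFrame(data)
    frame.insert(0, "ref_chromosome", [r[0] for r in ref_rows])
    frame.insert(1, "ref_order", [r[1] for r in ref_rows])
    return AlignmentTable(layout, frame, regions_by_genome, overflow,
                          translocated)


def _reference_panels(ref, paralogous_blocks, n_panels):
    """Map (reference gene, panel) -> hexaploidy paralog id from
    reference-internal blocks."""
    out = {}
    if not paralogous_blocks:
        return out
    count = {}
    for b in paralogous_blocks:
        for a in b.anchors:
            k = count.get(a.gene_a, 0)
            if k < n_panels - 1:
                out[(a.gene_a, k + 2)] = a.gene_b
                count[a.gene_a] = k + 1
    return out


def write_table(table: AlignmentTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
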
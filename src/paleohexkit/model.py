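"""Core domain objects: genes, genomes, and homology hits.

Coordinates are stored 0-based half-open internally; the readers in
:mod:`paleohexkit.io` translate from the 1-based inclusive GFF3 convention and
the 0-based half-open BED convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class PaleohexkitError(Exception):
    """Base class for all package errors."""


class DuplicateGeneError(PaleohexkitError):
    pass


class UnknownGeneError(PaleohexkitError):
    pass


@dataclass
class Gene:
    """A gene on a chromosome.

    ``order_index`` is the rank of the gene along its chromosome (0-based,
    contiguous); synteny chaining works entirely in this gene-order space.
    ``family_size`` is the number of homologs genome-wide (the gene itself
    included), used to drop large families before chaining.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    order_index: int = -1
    family_size: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")


@dataclass
class Genome:
    """Ordered genes on named chromosomes.

    ``ploidy_events`` records the polyploidies this genome carries relative to
    the pre-event ancestor as (label, multiplicity) pairs, e.g.
    ``[("ECH", 3)]`` for a paleohexaploid; the product of multiplicities is the
    expected orthology depth against that ancestor.
    """

    name: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)
    ploidy_events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, Gene] = {}
        for genes in self.chromosomes.values():
            for g in genes:
                if g.id in self._index:
                    raise DuplicateGeneError(f"duplicate gene id {g.id!r}")
                self._index[g.id] = g

    @property
    def n_genes(self) -> int:
        return len(self._index)

    def genes(self):
        for genes in self.chromosomes.values():
            yield from genes

    def get(self, gene_id: str) -> Gene:
        try:
            return self._index[gene_id]
        except KeyError:
            raise UnknownGeneError(
                f"unknown gene id {gene_id!r} in genome {self.name!r}"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def orthology_depth(self) -> int:
        depth = 1
        for _, mult in self.ploidy_events:
            depth *= mult
        return depth

    def sort_and_index(self) -> None:
        """Sort genes by start per chromosome and (re)assign order_index."""
        for genes in self.chromosomes.values():
            genes.sort(key=lambda g: (g.start, g.end, g.id))
            for i, g in enumerate(genes):
                g.order_index = i


@dataclass(frozen=True)
class HomologyHit:
    """One row of an all-vs-all protein homology search (self-hits excluded)."""

    query_id: str
    subject_id: str
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.query_id == self.subject_id:
            raise ValueError("self-hit is not a HomologyHit")
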
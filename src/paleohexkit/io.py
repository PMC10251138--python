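"""Readers and writers for the standard formats the pipeline consumes.

GFF3 is read 1-based inclusive (via gffutils), BED 0-based half-open, BLAST
tabular as 12-column outfmt-6 TSV, and CDS FASTA via Biopython.  Unsorted
annotation input is sorted, never rejected; duplicate gene ids are rejected
with the offending id.
"""

from __future__ import annotations

import io as _io
from collections import defaultdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import DuplicateGeneError, Gene, Genome, HomologyHit, PaleohexkitError

BLAST_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "score",
]


class ParseError(PaleohexkitError):
    pass


def _build_genome(name, records, ploidy_events):
    """records: iterable of (gene_id, chrom, start0, end0, strand)."""
    seen = set()
    chroms: dict[str, list[Gene]] = defaultdict(list)
    for gene_id, chrom, start, end, strand in records:
        if gene_id in seen:
            raise DuplicateGeneError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        chroms[chrom].append(Gene(gene_id, chrom, start, end, strand))
    genome = Genome(name=name, chromosomes=dict(chroms),
                    ploidy_events=list(ploidy_events or []))
    genome.sort_and_index()
    return genome


def load_gene_annotations(path, format: str, genome_name: str,
                          ploidy_events=None) -> Genome:
    """Load gene annotations from a GFF3 or BED file into a :class:`Genome`."""
    path = Path(path)
    if format == "bed":
        records = _read_bed(path)
    elif format == "gff3":
        records = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return _build_genome(genome_name, records, ploidy_events)


def _read_bed(path):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED line needs >= 4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) > 5 else "+"
            records.append((name, chrom, int(start), int(end), strand))
    return records


def _read_gff3(path):
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="error", keep_order=True)
    records = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # GFF3 is 1-based inclusive; convert to 0-based half-open.
        records.append((gene_id, feat.seqid, feat.start - 1, feat.end,
                        feat.strand if feat.strand in "+-" else "+"))
    return records


def write_bed(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for gene in genome.genes():
            fh.write(f"{gene.chromosome}\t{gene.start}\t{gene.end}"
                     f"\t{gene.id}\t0\t{gene.strand}\n")


def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genome.genes():
            fh.write(f"{gene.chromosome}\tpaleohexkit\tgene\t{gene.start + 1}"
                     f"\t{gene.end}\t.\t{gene.strand}\t.\tID={gene.id}\n")


def load_cds(path) -> dict[str, str]:
    """Load CDS sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def load_hits(path) -> list[HomologyHit]:
    """Load 12-column BLAST tabular hits; self-pairs are dropped."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                q, s = fields[0], fields[1]
                evalue, score = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if q == s:
                continue
            hits.append(HomologyHit(q, s, evalue, score))
    return hits


def write_hits(hits, path) -> None:
    rows = [(h.query_id, h.subject_id, 100.0, 0, 0, 0, 0, 0, 0, 0,
             h.evalue, h.score) for h in hits]
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(path, sep="\t",
                                                     header=False, index=False)


def compute_family_sizes(hits, genomes, max_evalue: float = 1e-5,
                         within_genome_only: bool = False) -> None:
    """Set ``family_size`` on every gene from the homology-hit graph.

    Family size is 1 + the number of distinct partners a gene has among hits
    passing the E-value cut, pooled across all genomes by default (set
    ``within_genome_only`` to count homologs inside each genome separately).
    """
    owner = {}
    for genome in genomes:
        for gene in genome.genes():
            owner[gene.id] = genome.name
    partners: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.evalue >= max_evalue:
            continue
        if h.query_id not in owner or h.subject_id not in owner:
            continue
        if within_genome_only and owner[h.query_id] != owner[h.subject_id]:
            continue
        partners[h.query_id].add(h.subject_id)
        partners[h.subject_id].add(h.query_id)
    for genome in genomes:
        for gene in genome.genes():
            gene.family_size = 1 + len(partners.get(gene.id, ()))


def filter_hits(hits, genomes, max_evalue: float = 1e-5,
                min_score: float = 100.0, max_family: int = 50,
                recompute_family: bool = True) -> list[HomologyHit]:
    """Quality- and family-filter homology hits.

    Retains hits with ``evalue < max_evalue`` and ``score > min_score``
    (both strict, matching the published cutoffs) whose two genes each belong
    to families of fewer than ``max_family`` members.  E-value/score filtering
    is applied first; family sizes are computed on the E-value-passing graph.
    Idempotent.
    """
    if recompute_family:
        compute_family_sizes(hits, genomes, max_evalue=max_evalue)
    index = {}
    for genome in genomes:
        for gene in genome.genes():
            index[gene.id] = gene
    kept = []
    for h in hits:
        if not (h.evalue < max_evalue and h.score > min_score):
            continue
        gq, gs = index.get(h.query_id), index.get(h.subject_id)
        if gq is None or gs is None:
            continue
        if gq.family_size >= max_family or gs.family_size >= max_family:
            continue
        kept.append(h)
    return kept
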
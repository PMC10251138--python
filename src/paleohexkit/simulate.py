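"""Synthetic paleopolyploid genomes with known truth.

The generator emulates the study design the rest of the package analyses: an
ancestral gene order, an unduplicated outgroup, a shared whole-genome
triplication whose three subgenomes fractionate at biased rates (gene loss in
geometrically distributed runs), optional lineage-specific tetraploidy,
chromosome rearrangements of the four named classes applied through the
karyotype module, homology hits for every surviving homolog pair, and
per-pair Ks drawn from event-specific normal distributions truncated at
zero.  A single seeded generator threads through every step, so one seed
fixes all outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .karyotype import Karyotype, RearrangementEvent, Segment, apply_event
from .ks import NUCLEOTIDES, _STOPS, _TABLE, pair_ks, translate_codon
from .model import Gene, Genome, HomologyHit, PaleohexkitError


class SimulationError(PaleohexkitError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 7
    genes_per_chromosome: int = 200
    outgroup_name: str = "out"
    descendants: tuple = ("dsc1", "dsc2")
    polyploidy_kind: str = "WGT"
    # event Ks distributions (mu, sigma)
    ks_outgroup: tuple = (1.52, 0.08)
    ks_polyploidy: tuple = (0.95, 0.05)
    ks_speciation: tuple = (0.56, 0.05)
    ks_second: tuple = (0.30, 0.04)
    # fractionation: one loss rate per polyploidy subgenome, geometric runs
    subgenome_loss_rates: tuple = (0.2, 0.4, 0.6)
    loss_run_p: float = 0.29
    second_polyploidy_genome: str | None = None
    second_loss_rates: tuple = (0.10, 0.25)
    # rearrangements: "EEJ"/"NCF"/"RCT"/"NCT" or (kind, seg_a, seg_b)
    shared_events: tuple = ()
    lineage_events: dict = field(default_factory=dict)
    rate_multipliers: dict = field(default_factory=dict)
    noise_hit_rate: float = 0.0
    emit_cds_pairs: int = 0
    cds_codons: int = 300
    ka_ks: float = 0.3

    def __post_init__(self) -> None:
        if any(not (0 <= r < 1) for r in self.subgenome_loss_rates):
            raise SimulationError("loss rates must be in [0, 1)")
        if not 0 < self.loss_run_p <= 1:
            raise SimulationError("geometric run parameter must be in (0, 1]")
        if self.polyploidy_kind not in ("WGD", "WGT"):
            raise SimulationError("polyploidy kind must be WGD or WGT")


@dataclass
class TruthTables:
    gene_ancestry: pd.DataFrame   # gene_id, genome, chromosome, ancestral_gene,
                                  # subgenome, wgd_copy
    loss_runs: pd.DataFrame       # genome, chromosome_copy, subgenome, length
    planted_events: list          # (branch, kind, detail)
    segment_maps: dict            # genome -> Karyotype in ancestral segment ids
    pair_events: pd.DataFrame     # gene_a, gene_b, event, ks


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict
    hits: list
    ks_pairs: pd.DataFrame
    cds_pairs: list
    truth: TruthTables


_SG_RE = re.compile(r"\.sg(\d+)")
_WGD_RE = re.compile(r"~(\d+)")


def _base_chrom(seg_id: str) -> str:
    return seg_id.split(".")[0]


def _subgenome_of(seg_id: str) -> int:
    m = _SG_RE.search(seg_id)
    return int(m.group(1)) if m else 0


def _wgd_copy_of(seg_id: str) -> int:
    m = _WGD_RE.search(seg_id)
    return int(m.group(1)) if m else 0


class _Builder:
    """Mutable karyotype + per-segment gene lists for one lineage."""

    def __init__(self, name, karyotype, segment_genes, counter=None):
        self.name = name
        self.karyotype = karyotype
        self.segment_genes = segment_genes  # id -> list of ancestral gene ids
        self._split_counter = counter or [0]

    def copy(self, name):
        return _Builder(name, Karyotype(name, [list(c) for c in
                                               self.karyotype.chromosomes]),
                        {k: list(v) for k, v in self.segment_genes.items()},
                        list(self._split_counter))

    def chrom_of_segment(self, base_id):
        for i, chrom in enumerate(self.karyotype.chromosomes):
            for j, seg in enumerate(chrom):
                if seg.id == base_id or seg.id.startswith(base_id + "/"):
                    return i, j
        raise SimulationError(f"segment {base_id!r} not found")

    def split_segment(self, chrom_idx, seg_idx, gene_offset):
        """Split a segment at an intrinsic gene offset into two segments."""
        chrom = list(self.karyotype.chromosomes[chrom_idx])
        seg = chrom[seg_idx]
        genes = self.segment_genes.pop(seg.id)
        if not 0 < gene_offset < len(genes):
            raise SimulationError("split offset must be internal")
        self._split_counter[0] += 1
        left_id = f"{seg.id}/{self._split_counter[0]}a"
        right_id = f"{seg.id}/{self._split_counter[0]}b"
        self.segment_genes[left_id] = genes[:gene_offset]
        self.segment_genes[right_id] = genes[gene_offset:]
        left = Segment(left_id, seg.orientation, seg.source_chromosome)
        right = Segment(right_id, seg.orientation, seg.source_chromosome)
        pieces = [left, right] if seg.orientation == "+" else [right, left]
        chrom[seg_idx:seg_idx + 1] = pieces
        chroms = list(self.karyotype.chromosomes)
        chroms[chrom_idx] = chrom
        self.karyotype = Karyotype(self.name, chroms)

    def apply(self, event: RearrangementEvent):
        self.karyotype = apply_event(self.karyotype, event)
        if event.kind in ("WGD", "WGT"):
            n = 2 if event.kind == "WGD" else 3
            old = self.segment_genes
            self.segment_genes = {f"{sid}~{k}": list(genes)
                                  for k in range(1, n + 1)
                                  for sid, genes in old.items()}

    def chromosome_genes(self, chrom_idx):
        """(ancestral gene, segment id) in chromosome order."""
        out = []
        for seg in self.karyotype.chromosomes[chrom_idx]:
            genes = self.segment_genes[seg.id]
            ordered = genes if seg.orientation == "+" else list(reversed(genes))
            out.extend((g, seg.id) for g in ordered)
        return out


def _resolve_event(builder, spec, rng):
    """Turn an event spec (kind string or (kind, seg_a, seg_b)) into a
    RearrangementEvent with concrete operands, splitting segments as needed."""
    if isinstance(spec, str):
        kind, target_a, target_b = spec.upper(), None, None
    else:
        kind, target_a, target_b = spec[0].upper(), spec[1], spec[2]
    kary = builder.karyotype
    n = kary.n_chromosomes

    def pick_two():
        if target_a is not None:
            ia = builder.chrom_of_segment(target_a)[0]
            ib = builder.chrom_of_segment(target_b)[0]
            if ia == ib:
                raise SimulationError(
                    f"{kind}: {target_a} and {target_b} are on one chromosome")
            return ia, ib
        ia, ib = rng.choice(n, size=2, replace=False)
        return int(ia), int(ib)

    if kind == "EEJ":
        i, j = pick_two()
        return RearrangementEvent("EEJ", (i, j, False))
    if kind == "NCF":
        host, insert = pick_two()
        chrom = builder.karyotype.chromosomes[host]
        if len(chrom) == 1:
            seg = chrom[0]
            genes = builder.segment_genes[seg.id]
            off = int(rng.integers(1, len(genes)))
            builder.split_segment(host, 0, off)
        breakpoint = int(rng.integers(
            1, len(builder.karyotype.chromosomes[host])))
        return RearrangementEvent("NCF", (host, insert, breakpoint, False))
    if kind in ("RCT", "NCT"):
        i, j = pick_two()
        for c in (i, j):
            chrom = builder.karyotype.chromosomes[c]
            if len(chrom) == 1:
                genes = builder.segment_genes[chrom[0].id]
                builder.split_segment(c, 0, int(rng.integers(1, len(genes))))
        ci = builder.karyotype.chromosomes[i]
        cj = builder.karyotype.chromosomes[j]
        if kind == "RCT":
            return RearrangementEvent(
                "RCT", (i, int(rng.integers(1, len(ci))),
                        j, int(rng.integers(1, len(cj)))))
        start = int(rng.integers(0, len(ci) - 1))
        end = start + 1
        pos = int(rng.integers(0, len(cj) + 1))
        return RearrangementEvent("NCT", (i, start, end, j, pos))
    raise SimulationError(f"unknown planted event kind {kind!r}")


def _place_loss_runs(n, rate, p, rng):
    """Boolean lost mask with geometric(p) run lengths totalling ~rate*n."""
    target = int(round(rate * n))
    lost = np.zeros(n, dtype=bool)
    runs = []
    total = 0
    failures = 0
    while total < target:
        k = min(int(rng.geometric(p)), n, target - total + 3)
        placed = False
        for attempt in range(150):
            start = int(rng.integers(0, n - k + 1))
            # prefer placements not touching an existing run (keeps the run
            # multiset close to the drawn lengths); at dense loss fall back
            # to merely non-overlapping placements
            pad = 1 if attempt < 75 else 0
            lo, hi = max(0, start - pad), min(n, start + k + pad)
            if not lost[lo:hi].any():
                lost[start:start + k] = True
                runs.append(k)
                total += k
                placed = True
                break
        if not placed:
            failures += 1
            if failures > 100:
                raise SimulationError(
                    f"loss rate {rate} too high to place non-overlapping runs")
    if lost.all():
        raise SimulationError("loss emptied a chromosome region")
    return lost, runs


def _draw_ks(mu, sigma, rng):
    for _ in range(1000):
        v = rng.normal(mu, sigma)
        if v >= 0:
            return float(v)
    return 0.0


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate genomes, homology hits, Ks pairs, and truth tables."""
    rng = np.random.default_rng(config.seed)
    n_sub = 3 if config.polyploidy_kind == "WGT" else 2

    anc = {f"chr{c + 1}": [f"a{c + 1}g{i}" for i in
                           range(config.genes_per_chromosome)]
           for c in range(config.n_chromosomes)}

    # outgroup: the ancestral order, unduplicated
    out_builder = _Builder(
        config.outgroup_name,
        Karyotype(config.outgroup_name,
                  [[Segment(f"{c}.sg0")] for c in anc]),
        {f"{c}.sg0": list(genes) for c, genes in anc.items()})

    # ingroup: polyploidy then shared rearrangements; subgenomes are labelled
    # explicitly (sg1..sgN) so loss rates and truth stay readable
    chroms = []
    seg_genes = {}
    for sg in range(1, n_sub + 1):
        for c in anc:
            sid = f"{c}.sg{sg}"
            chroms.append([Segment(sid)])
            seg_genes[sid] = list(anc[c])
    ingroup = _Builder("ingroup", Karyotype("ingroup", chroms), seg_genes)

    planted = []
    for spec in config.shared_events:
        ev = _resolve_event(ingroup, spec, rng)
        junction_before = ingroup.karyotype.n_chromosomes
        ingroup.apply(ev)
        planted.append(("shared", ev.kind, spec if not isinstance(spec, str)
                        else (ev.kind,), junction_before))

    builders = {}
    for name in config.descendants:
        b = ingroup.copy(name)
        for spec in config.lineage_events.get(name, ()):
            ev = _resolve_event(b, spec, rng)
            b.apply(ev)
            planted.append((name, ev.kind, spec if not isinstance(spec, str)
                            else (ev.kind,), None))
        if config.second_polyploidy_genome == name:
            b.apply(RearrangementEvent("WGD"))
        builders[name] = b

    # materialise genomes with loss
    genomes = {}
    ancestry_rows = []
    loss_rows = []
    copies_of: dict[str, list] = {g: [] for genes in anc.values() for g in genes}

    def materialise(builder, name, apply_loss):
        counter = 0
        chrom_map = {}
        for ci in range(builder.karyotype.n_chromosomes):
            chrom_name = f"{name}_c{ci + 1}"
            genes = []
            offset = 0
            for seg in builder.karyotype.chromosomes[ci]:
                seg_list = builder.segment_genes[seg.id]
                ordered = (seg_list if seg.orientation == "+"
                           else list(reversed(seg_list)))
                sg = _subgenome_of(seg.id)
                wgd_copy = _wgd_copy_of(seg.id)
                if apply_loss and ordered:
                    rate = config.subgenome_loss_rates[(sg - 1) % max(1, len(
                        config.subgenome_loss_rates))] if sg else 0.0
                    if wgd_copy:
                        extra = config.second_loss_rates[
                            (wgd_copy - 1) % len(config.second_loss_rates)]
                        rate = 1.0 - (1.0 - rate) * (1.0 - extra)
                    if rate > 0:
                        lost, runs = _place_loss_runs(
                            len(ordered), rate, config.loss_run_p, rng)
                        for k in runs:
                            loss_rows.append((name, chrom_name, f"sg{sg}", k))
                        ordered = [g for g, dead in zip(ordered, lost)
                                   if not dead]
                for g in ordered:
                    genes.append((g, sg, wgd_copy))
                offset += len(ordered)
            gene_objs = []
            for i, (ancg, sg, wgd_copy) in enumerate(genes):
                gid = f"{name}g{counter:05d}"
                counter += 1
                gene_objs.append(Gene(gid, chrom_name, i * 1000,
                                      i * 1000 + 600, "+"))
                ancestry_rows.append((gid, name, chrom_name, ancg,
                                      f"sg{sg}", wgd_copy))
                copies_of[ancg].append((gid, name, sg, wgd_copy))
            chrom_map[chrom_name] = gene_objs
        events = []
        if name in config.descendants:
            events.append((config.polyploidy_kind, n_sub))
            if config.second_polyploidy_genome == name:
                events.append(("WGD", 2))
        genome = Genome(name, chrom_map, events)
        genome.sort_and_index()
        return genome

    genomes[config.outgroup_name] = materialise(
        out_builder, config.outgroup_name, apply_loss=False)
    for name, b in builders.items():
        genomes[name] = materialise(b, name, apply_loss=True)

    # Ks pairs and hits
    mu_sig = {"outgroup_divergence": config.ks_outgroup,
              "polyploidy": config.ks_polyploidy,
              "speciation": config.ks_speciation,
              "second_polyploidy": config.ks_second}
    rates = {name: config.rate_multipliers.get(name, 1.0)
             for name in list(config.descendants) + [config.outgroup_name]}
    pair_rows = []
    hits = []
    for ancg in (g for genes in anc.values() for g in genes):
        copies = copies_of[ancg]
        for x in range(len(copies)):
            for y in range(x + 1, len(copies)):
                gid_a, gen_a, sg_a, wc_a = copies[x]
                gid_b, gen_b, sg_b, wc_b = copies[y]
                if gen_a == gen_b == config.outgroup_name:
                    continue
                if config.outgroup_name in (gen_a, gen_b):
                    event = "outgroup_divergence"
                elif sg_a != sg_b:
                    event = "polyploidy"
                elif gen_a != gen_b:
                    event = "speciation"
                elif wc_a != wc_b:
                    event = "second_polyploidy"
                else:
                    continue
                mu, sigma = mu_sig[event]
                factor = (rates[gen_a] + rates[gen_b]) / 2.0
                ks = _draw_ks(mu * factor, sigma, rng)
                pair_rows.append((gid_a, gid_b, event, ks))
                hits.append(HomologyHit(gid_a, gid_b, 1e-100, 500.0))
                hits.append(HomologyHit(gid_b, gid_a, 1e-100, 500.0))
    ks_pairs = pd.DataFrame(pair_rows,
                            columns=["gene_a", "gene_b", "event", "ks"])

    if config.noise_hit_rate > 0:
        all_genes = [g.id for genome in genomes.values()
                     for g in genome.genes()]
        n_noise = int(config.noise_hit_rate * len(pair_rows))
        for _ in range(n_noise):
            a, b = rng.choice(len(all_genes), size=2, replace=False)
            hits.append(HomologyHit(all_genes[int(a)], all_genes[int(b)],
                                    1e-4, 80.0))

    cds_pairs = []
    if config.emit_cds_pairs:
        take = min(config.emit_cds_pairs, len(pair_rows))
        idx = rng.choice(len(pair_rows), size=take, replace=False)
        for i in sorted(int(j) for j in idx):
            gid_a, gid_b, event, ks = pair_rows[i]
            try:
                a, b = emit_cds(ks, n_codons=config.cds_codons,
                                ka_ks=config.ka_ks, rng=rng)
            except SimulationError:
                continue
            cds_pairs.append((gid_a, gid_b, a, b))

    segment_maps = {}
    for name, b in builders.items():
        chroms = []
        for ci in range(b.karyotype.n_chromosomes):
            segs = []
            for seg in b.karyotype.chromosomes[ci]:
                base = seg.id.split("/")[0].split("~")[0]
                if segs and segs[-1].id == base and \
                        segs[-1].orientation == seg.orientation:
                    continue  # merge split pieces back together
                segs.append(Segment(base, seg.orientation))
            chroms.append(segs)
        segment_maps[name] = Karyotype(name, chroms, strict=False)

    truth = TruthTables(
        gene_ancestry=pd.DataFrame(ancestry_rows, columns=[
            "gene_id", "genome", "chromosome", "ancestral_gene", "subgenome",
            "wgd_copy"]),
        loss_runs=pd.DataFrame(loss_rows, columns=[
            "genome", "chromosome", "subgenome", "length"]),
        planted_events=planted,
        segment_maps=segment_maps,
        pair_events=ks_pairs)
    return SimulationResult(config, genomes, hits, ks_pairs, cds_pairs, truth)


# ---------------------------------------------------------------------------
# CDS emission

_SENSE_CODONS = sorted(set(_TABLE) - _STOPS)
_MAX_TARGET_KS = 2.5  # beyond this the JC transform's granularity on a few
                      # hundred codons exceeds the +-0.05 recovery contract


def _mutation_candidates(codon, synonymous):
    """Single-nucleotide non-stop fates of a codon, synonymous or not."""
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            fate = codon[:pos] + nt + codon[pos + 1:]
            if fate in _STOPS:
                continue
            if (translate_codon(fate) == aa) == synonymous:
                out.append(fate)
    return out


def emit_cds(target_ks: float, n_codons: int = 300, ka_ks: float = 0.0,
             rng=None, cds_a: str | None = None,
             tolerance: float = 0.02) -> tuple[str, str]:
    """A CDS pair whose Nei-Gojobori Ks lands at ``target_ks``.

    Synonymous substitutions are placed iteratively against the Ks engine as
    the oracle until the measured Ks reaches the target; nonsynonymous
    substitutions are added the same way toward ``ka_ks * target_ks``.
    Targets beyond the practical saturation ceiling are rejected.
    """
    if target_ks < 0:
        raise ValueError("target Ks must be >= 0")
    if target_ks > _MAX_TARGET_KS:
        raise SimulationError(
            f"target Ks {target_ks} is beyond saturation (pS approaches 3/4)")
    rng = np.random.default_rng(rng)
    if cds_a is None:
        cds_a = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    codons_b = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]

    def measure():
        return pair_ks(cds_a, "".join(codons_b))

    def top_up(synonymous, target):
        """Place mutations of one class until its rate reaches the target;
        returns True if already satisfied on entry."""
        satisfied = True
        stalls = 0
        while True:
            res = measure()
            value = res.ks if synonymous else res.ka
            if value is None:
                raise SimulationError("saturated while placing mutations")
            if value >= target - tolerance:
                return satisfied
            satisfied = False
            i = int(rng.integers(0, len(codons_b)))
            cands = _mutation_candidates(codons_b[i], synonymous)
            if not cands:
                stalls += 1
                if stalls > 50 * len(codons_b):
                    raise SimulationError("cannot reach target Ks: saturated")
                continue
            codons_b[i] = cands[int(rng.integers(0, len(cands)))]

    # nonsynonymous changes perturb site counts, so alternate until both
    # rates sit at their targets simultaneously
    for _ in range(20):
        done = top_up(True, target_ks)
        if ka_ks * target_ks > 0:
            done = top_up(False, ka_ks * target_ks) and done
        if done:
            break
    return cds_a, "".join(codons_b)


def write_dataset(result: SimulationResult, outdir) -> None:
    """Write the generated data in the formats the loaders read."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, genome in result.genomes.items():
        pio.write_bed(genome, outdir / f"{name}.bed")
    pio.write_hits(result.hits, outdir / "hits.tsv")
    result.ks_pairs.to_csv(outdir / "ks_pairs.tsv", sep="\t", index=False)
    result.truth.gene_ancestry.to_csv(outdir / "truth_ancestry.tsv",
                                      sep="\t", index=False)
    result.truth.loss_runs.to_csv(outdir / "truth_loss_runs.tsv",
                                  sep="\t", index=False)
    if result.cds_pairs:
        seqs = {}
        for gid_a, gid_b, a, b in result.cds_pairs:
            seqs.setdefault(gid_a, a)
            seqs.setdefault(gid_b, b)
        pio.write_fasta(seqs, outdir / "cds.fa")
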
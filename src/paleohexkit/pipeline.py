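"""End-to-end orchestration: load -> synteny -> Ks -> peaks/correction/dating
-> classification -> alignment table -> fractionation/P-index -> karyotype.

Driven by a YAML run configuration; every stage writes its outputs plus a
manifest (parameters, version, seed, content hash) into the output directory,
and a rerun with an unchanged configuration reuses cached stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as pio
from .fractionation import (ChromosomeWindows, assign_subgenomes,
                            fit_geometric, loss_runs, p_index_multi,
                            retention_profile, stitch_subgenomes)
from .karyotype import (Karyotype, Segment, infer_shared_fusions,
                        reconstruct_ancestral_karyotype)
from .model import Genome, PaleohexkitError
from .peaks import Calibration, date_event, fit_gaussian_mixture
from .synteny import chain_collinear_blocks, read_blocks, write_blocks
from .table import (EventPeak, EventPeakSet, classify_block_event, fill_table,
                    plan_table_layout, write_table, DOT)
from .ks import annotate_block_ks

log = logging.getLogger("paleohexkit")


class ConfigError(PaleohexkitError):
    pass


class StageError(PaleohexkitError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class GenomeSpec:
    name: str
    path: str
    format: str = "bed"
    hexaploid: bool = True
    tetraploidies: int = 0


@dataclass
class RunConfig:
    reference: str
    genomes: list[GenomeSpec]
    hits: str
    output: str
    seed: int = 0
    ks_table: str | None = None
    cds: list[str] = field(default_factory=list)
    reference_panels: int = 1
    max_gap: int = 50
    min_anchors: int = 5
    max_evalue: float = 1e-5
    min_score: float = 100.0
    max_family: int = 50
    bandwidth: float = 0.05
    min_r2: float = 0.95
    window: int = 50
    ks_range: tuple = (0.05, 1.8)
    pindex_threshold: float = 0.3
    event_peaks: dict = field(default_factory=dict)  # label -> {mu, tolerance}
    calibration: dict | None = None  # {event, time_mya: [lo, hi], peak_mu}
    min_segment_genes: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            genomes = [GenomeSpec(name=name, **spec)
                       for name, spec in raw.pop("genomes").items()]
            ref = raw.pop("reference")
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid run config: {exc}") from None
        if ref not in {g.name for g in genomes}:
            raise ConfigError(f"reference {ref!r} is not a declared genome")
        params = raw.pop("params", {})
        cfg = cls(reference=ref, genomes=genomes, **raw, **params)
        for g in cfg.genomes:
            if not Path(g.path).exists():
                raise ConfigError(f"annotation file missing: {g.path}")
        if not Path(cfg.hits).exists():
            raise ConfigError(f"hits file missing: {cfg.hits}")
        return cfg

    def digest(self, extra: str = "") -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())},
            sort_keys=True) + extra
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest_path(outdir, stage):
    return Path(outdir) / stage / "manifest.json"


def _stage_cached(outdir, stage, digest):
    mf = _manifest_path(outdir, stage)
    if mf.exists():
        try:
            return json.loads(mf.read_text()).get("digest") == digest
        except json.JSONDecodeError:
            return False
    return False


def _write_manifest(outdir, stage, digest, inputs, params):
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    (d / "manifest.json").write_text(json.dumps({
        "stage": stage, "digest": digest, "inputs": inputs,
        "params": params, "version": __version__}, indent=1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dictionary."""
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "cached_stages": [], "notices": []}
    digest = config.digest()

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # halt with stage name, keep partials
            raise StageError(name, exc) from exc

    # ---- load -------------------------------------------------------------
    def load():
        genomes = {}
        for spec in config.genomes:
            genomes[spec.name] = pio.load_gene_annotations(
                spec.path, spec.format, spec.name)
        hits = pio.load_hits(config.hits)
        hits = pio.filter_hits(hits, genomes.values(),
                               max_evalue=config.max_evalue,
                               min_score=config.min_score,
                               max_family=config.max_family)
        return genomes, hits

    genomes, hits = run_stage("load", load)
    report["genomes"] = {n: g.n_genes for n, g in genomes.items()}
    report["filtered_hits"] = len(hits)

    ref = genomes[config.reference]
    targets = [g for g in config.genomes if g.name != config.reference]

    # ---- synteny + Ks annotation (cached) ---------------------------------
    ks_lookup = None
    cds_store: dict = {}
    if config.ks_table:
        tbl = pd.read_csv(config.ks_table, sep="\t",
                          dtype={"gene_a": str, "gene_b": str})
        ks_lookup = {(r.gene_a, r.gene_b): float(r.ks)
                     for r in tbl.itertuples()}
    for path in config.cds:
        cds_store.update(pio.load_cds(path))

    def synteny_stage():
        blocks_by_genome = {}
        stage_dir = outdir / "synteny"
        cached = _stage_cached(outdir, "synteny", digest)
        for spec in targets:
            out_path = stage_dir / f"{config.reference}_vs_{spec.name}.tsv"
            if cached and out_path.exists():
                blocks_by_genome[spec.name] = read_blocks(out_path)
                continue
            pair_hits = _hits_for_pair(hits, ref, genomes[spec.name])
            blocks = chain_collinear_blocks(
                pair_hits, ref, genomes[spec.name],
                max_gap=config.max_gap, min_anchors=config.min_anchors)
            for b in blocks:
                annotate_block_ks(b, cds_store, ks_lookup)
            stage_dir.mkdir(parents=True, exist_ok=True)
            write_blocks(blocks, out_path)
            blocks_by_genome[spec.name] = blocks
        if cached:
            report["cached_stages"].append("synteny")
        _write_manifest(outdir, "synteny", digest,
                        {"hits": config.hits}, {"max_gap": config.max_gap,
                                                "min_anchors": config.min_anchors})
        return blocks_by_genome

    blocks_by_genome = run_stage("synteny", synteny_stage)
    report["blocks"] = {n: len(b) for n, b in blocks_by_genome.items()}

    # ---- peaks ------------------------------------------------------------
    def peaks_stage():
        out = {}
        for spec in targets:
            med = [b.ks_median for b in blocks_by_genome[spec.name]
                   if b.ks_median is not None]
            med = [m for m in med
                   if config.ks_range[0] <= m <= config.ks_range[1]]
            if len(med) < 5:
                report["notices"].append(
                    f"peaks: too few Ks medians for {spec.name}")
                continue
            model = fit_gaussian_mixture(
                values=med, bandwidth=config.bandwidth,
                min_r2=config.min_r2, ks_ceiling=config.ks_range[1],
                source=f"{config.reference}-{spec.name}")
            out[spec.name] = {
                "components": [{"mu": c.mu, "sigma": c.sigma,
                                "weight": c.weight, "mu_ml": c.mu_ml}
                               for c in model.components],
                "r_squared": model.r_squared, "flagged": model.flagged}
        return out

    report["peaks"] = run_stage("peaks", peaks_stage)

    # ---- dating -----------------------------------------------------------
    if config.calibration:
        def dating_stage():
            cal = Calibration(config.calibration["event"],
                              tuple(config.calibration["time_mya"]),
                              float(config.calibration["peak_mu"]))
            dates = {}
            for name, info in report["peaks"].items():
                for comp in info["components"]:
                    lo, hi = date_event(comp["mu"], cal)
                    dates.setdefault(name, []).append(
                        {"mu": comp["mu"], "mya": [lo, hi]})
            return dates
        report["dates"] = run_stage("dating", dating_stage)
    else:
        report["notices"].append("dating skipped: no calibration configured")

    # ---- classification + table -------------------------------------------
    peak_set = EventPeakSet([
        EventPeak(label, float(spec["mu"]), float(spec.get("tolerance", 0.3)))
        for label, spec in config.event_peaks.items()]) \
        if config.event_peaks else None

    def table_stage():
        ortho = {}
        for spec in targets:
            blocks = blocks_by_genome[spec.name]
            if peak_set is not None:
                for b in blocks:
                    if b.ks_median is not None:
                        classify_block_event(b, peak_set)
                blocks = [b for b in blocks
                          if b.event and not b.event.startswith("unclassified")]
            ortho[spec.name] = blocks
        layout = plan_table_layout(
            config.reference,
            {g.name: (g.hexaploid, g.tetraploidies) for g in targets},
            reference_panels=config.reference_panels)
        table = fill_table(layout, ref, ortho, genomes=genomes)
        write_table(table, outdir / "alignment_table.tsv")
        return table

    table = run_stage("table", table_stage)
    report["table_columns"] = table.n_columns

    # ---- fractionation ----------------------------------------------------
    def fractionation_stage():
        out = {}
        for spec in targets:
            m_g = table.layout.slots_per_genome[spec.name]
            runs_all = []
            chrom_windows = []
            for chrom in ref.chromosomes:
                sel = table.frame[table.frame.ref_chromosome == chrom]
                cols = [list(sel[f"{spec.name}|p1|s{s}"])
                        for s in range(1, m_g + 1)]
                for col in cols:
                    runs_all.append(loss_runs(col))
                prof = retention_profile(cols, chrom, window=config.window,
                                         step=config.window)
                per_copy = {f"s{s}": np.array([w.retained[s - 1]
                                               for w in prof.windows])
                            for s in range(1, m_g + 1)}
                chrom_windows.append((chrom, per_copy))
            merged_runs = sum(runs_all, start=type(runs_all[0])())
            geo = (fit_geometric(merged_runs)
                   if sum(merged_runs.values()) >= 2 else None)
            pindex = p_index_multi(chrom_windows)
            regions = [
                (f"{r.chromosome}:{r.start}-{r.end}",
                 [(b.chrom_b, ret, _chrom_total(table, spec.name, b.chrom_b))
                  for b, ret in r.copies[:m_g]])
                for r in table.regions[spec.name]
                if len(r.copies) >= min(3, m_g)]
            labels, ties = ({}, [])
            if regions and m_g >= 3:
                triplets = [(rid, copies[:3]) for rid, copies in regions]
                labels, ties = assign_subgenomes(triplets)
            out[spec.name] = {
                "geometric_p": None if geo is None else geo.p,
                "geometric_r2": None if geo is None else geo.r_squared,
                "p_index": pindex.value,
                "p_index_call": ("allopolyploid"
                                 if pindex.value > config.pindex_threshold
                                 else "autopolyploid"),
                "subgenome_labels": {rid: lab for rid, lab in labels.items()},
                "label_ties": ties,
            }
        return out

    report["fractionation"] = run_stage("fractionation", fractionation_stage)

    # ---- karyotype --------------------------------------------------------
    def karyotype_stage():
        maps = {}
        for spec in targets:
            labels = report["fractionation"].get(spec.name, {}).get(
                "subgenome_labels", {})
            chrom_label = _labels_by_chromosome(labels, table, spec.name)
            maps[spec.name] = build_segment_map(
                blocks_by_genome[spec.name], genomes[spec.name],
                chrom_labels=chrom_label,
                min_genes=config.min_segment_genes)
        outgroup_map = Karyotype(
            config.reference,
            [[Segment(chrom)] for chrom in ref.chromosomes], strict=False)
        shared = infer_shared_fusions(maps, outgroup_map)
        base = Karyotype(
            "base", [[Segment(sid)] for sid in sorted(
                set().union(*(m.segment_ids() for m in maps.values())))],
            strict=False)
        ancestor, events, warnings = reconstruct_ancestral_karyotype(
            maps, base)
        return {
            "shared_junctions": sorted(map(list, shared.shared)),
            "conflicts": [sorted(p) for p in shared.conflicting],
            "ancestral_chromosomes": ancestor.n_chromosomes,
            "events": [[e.kind, list(map(str, e.operands))] for e in events],
            "warnings": warnings,
        }

    if len(targets) >= 2:
        report["karyotype"] = run_stage("karyotype", karyotype_stage)
    else:
        report["notices"].append(
            "karyotype skipped: needs >= 2 non-reference genomes")

    (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                   default=str))
    return report


def _chrom_total(table, genome, chrom_b):
    total = 0
    for regions in [table.regions[genome]]:
        for r in regions:
            for b, ret in r.copies:
                if b.chrom_b == chrom_b:
                    total += ret
    return total


def _labels_by_chromosome(region_labels, table, genome):
    per_region = {}
    for rid, lab in region_labels.items():
        per_region[rid] = lab
    return stitch_subgenomes(per_region) if per_region else {}


def _hits_for_pair(hits, genome_a: Genome, genome_b: Genome):
    """Select and orient hits for one genome pair."""
    out = []
    for h in hits:
        if h.query_id in genome_a and h.subject_id in genome_b:
            out.append(h)
    return out


def build_segment_map(blocks, genome: Genome, chrom_labels=None,
                      min_genes: int = 10) -> Karyotype:
    """Express a genome's chromosomes as ordered ancestral-segment lists.

    Each synteny block against the reference becomes a segment named after
    its reference chromosome (suffixed with the chromosome's subgenome label
    when given), oriented by the block orientation; blocks shorter than
    ``min_genes`` anchors are ignored and adjacent same-name segments merged.
    """
    by_chrom: dict[str, list] = {}
    for b in blocks:
        if len(b.anchors) < min_genes:
            continue
        by_chrom.setdefault(b.chrom_b, []).append(b)
    chroms = []
    for chrom_name in genome.chromosomes:
        blist = sorted(by_chrom.get(chrom_name, []),
                       key=lambda b: b.span_b[0])
        segs: list[Segment] = []
        for b in blist:
            label = (chrom_labels or {}).get(chrom_name)
            sid = f"{b.chrom_a}.{label}" if label else b.chrom_a
            orient = "+" if b.orientation == "same" else "-"
            if segs and segs[-1].id == sid and segs[-1].orientation == orient:
                continue
            segs.append(Segment(sid, orient))
        if segs:
            chroms.append(segs)
    return Karyotype(genome.name, chroms, strict=False)
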
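"""Rearrangement algebra over karyotypes and ancestral-karyotype inference.

A karyotype is a list of chromosomes, each an ordered list of signed
segments.  The operators are the chromosome-number calculus of paleogenome
repatterning: end-to-end joining (EEJ, -1 chromosome), nested chromosome
fusion (NCF, -1), reciprocal and nonreciprocal translocation (RCT/NCT,
count-neutral), fission (+1), and whole-genome duplication/triplication
(x2/x3).  Ancestral karyotypes are reconstructed by Dollo-style parsimony on
segment junctions: a junction present in every descendant and absent from the
outgroup is assigned to their common ancestor.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from .model import PaleohexkitError


class KaryotypeError(PaleohexkitError):
    pass


@dataclass(frozen=True)
class Segment:
    id: str
    orientation: str = "+"
    source_chromosome: str = ""

    def flipped(self) -> "Segment":
        return replace(self, orientation="-" if self.orientation == "+" else "+")


def _flip(chrom):
    return [seg.flipped() for seg in reversed(chrom)]


@dataclass
class Karyotype:
    """Chromosomes as ordered signed segment lists.

    ``strict`` enforces segment-id uniqueness; descendant segment maps
    expressed in ancestral coordinates (where polyploid copies repeat the
    same ancestral id) are built with ``strict=False``.
    """

    name: str
    chromosomes: list[list[Segment]]
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict:
            ids = [seg.id for chrom in self.chromosomes for seg in chrom]
            dup = [i for i, c in Counter(ids).items() if c > 1]
            if dup:
                raise KaryotypeError(f"segments appear more than once: {dup[:5]}")
        if any(not chrom for chrom in self.chromosomes):
            raise KaryotypeError("empty chromosome")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def segment_ids(self) -> set[str]:
        return {seg.id for chrom in self.chromosomes for seg in chrom}


@dataclass(frozen=True)
class RearrangementEvent:
    """One operation; operands index chromosomes of the karyotype it is
    applied to, breakpoints are positions in the segment list.

    kinds and operands:
      EEJ      (chrom_i, chrom_j, flip_j)   join j after i
      NCF      (host, insert, breakpoint, flip)  breakpoint internal (1..len-1)
      RCT      (chrom_i, pos_i, chrom_j, pos_j)  exchange tails from pos
      NCT      (src, start, end, dest, pos)      move src[start:end] into dest
      FISSION  (chrom, pos)
      WGD/WGT  ()                           copy-suffixed segment ids
    """

    kind: str
    operands: tuple = ()

COUNT_DELTA = {"EEJ": -1, "NCF": -1, "RCT": 0, "NCT": 0, "FISSION": 1}


def apply_event(karyotype: Karyotype, event: RearrangementEvent) -> Karyotype:
    chroms = [list(c) for c in karyotype.chromosomes]
    kind = event.kind.upper()
    if kind == "EEJ":
        i, j, *rest = event.operands
        flip_j = bool(rest[0]) if rest else False
        if i == j:
            raise KaryotypeError("EEJ needs two distinct chromosomes")
        other = _flip(chroms[j]) if flip_j else chroms[j]
        chroms[i] = chroms[i] + other
        del chroms[j]
    elif kind == "NCF":
        host, insert, breakpoint, *rest = event.operands
        flip_ins = bool(rest[0]) if rest else False
        if host == insert:
            raise KaryotypeError("NCF needs two distinct chromosomes")
        if not 0 < breakpoint < len(chroms[host]):
            raise KaryotypeError(
                "NCF breakpoint must be internal (a terminal join is an EEJ)")
        ins = _flip(chroms[insert]) if flip_ins else chroms[insert]
        chroms[host] = chroms[host][:breakpoint] + ins + chroms[host][breakpoint:]
        del chroms[insert]
    elif kind == "RCT":
        i, pos_i, j, pos_j = event.operands
        if i == j:
            raise KaryotypeError("RCT needs two distinct chromosomes")
        for c, p in ((i, pos_i), (j, pos_j)):
            if not 0 < p <= len(chroms[c]):
                raise KaryotypeError("RCT breakpoint outside chromosome")
        chroms[i], chroms[j] = (chroms[i][:pos_i] + chroms[j][pos_j:],
                                chroms[j][:pos_j] + chroms[i][pos_i:])
        if not chroms[i] or not chroms[j]:
            raise KaryotypeError("RCT would empty a chromosome")
    elif kind == "NCT":
        src, start, end, dest, pos = event.operands
        if src == dest:
            raise KaryotypeError("NCT needs two distinct chromosomes")
        if not (0 <= start < end <= len(chroms[src])):
            raise KaryotypeError("NCT segment run crosses chromosome ends")
        if end - start == len(chroms[src]):
            raise KaryotypeError("NCT moving a whole chromosome is a fusion")
        if not 0 <= pos <= len(chroms[dest]):
            raise KaryotypeError("NCT insertion point outside chromosome")
        run = chroms[src][start:end]
        chroms[src] = chroms[src][:start] + chroms[src][end:]
        chroms[dest] = chroms[dest][:pos] + run + chroms[dest][pos:]
    elif kind == "FISSION":
        c, pos = event.operands
        if not 0 < pos < len(chroms[c]):
            raise KaryotypeError("fission point must be internal")
        left, right = chroms[c][:pos], chroms[c][pos:]
        chroms[c] = left
        chroms.insert(c + 1, right)
    elif kind in ("WGD", "WGT"):
        n_copies = 2 if kind == "WGD" else 3
        new = []
        for k in range(1, n_copies + 1):
            for chrom in chroms:
                new.append([replace(seg, id=f"{seg.id}~{k}") for seg in chrom])
        chroms = new
    else:
        raise KaryotypeError(f"unknown event kind {event.kind!r}")
    return Karyotype(karyotype.name, chroms, karyotype.strict)


def chromosome_count_after(initial_count: int, events) -> int:
    """Chromosome count after an event sequence.

    ``events`` is a list of kinds (strings or RearrangementEvents) or
    (kind, count) pairs, applied in order.
    """
    count = initial_count
    for ev in events:
        if isinstance(ev, RearrangementEvent):
            kind, times = ev.kind.upper(), 1
        elif isinstance(ev, str):
            kind, times = ev.upper(), 1
        else:
            kind, times = ev[0].upper(), int(ev[1])
        for _ in range(times):
            if kind == "WGD":
                count *= 2
            elif kind == "WGT":
                count *= 3
            else:
                count += COUNT_DELTA[kind]
            if count < 1:
                raise KaryotypeError("chromosome count dropped below 1")
    return count


def expected_chromosomes(base: int, multipliers) -> int:
    """Chromosome count under polyploidies alone (no fusions): base x prod."""
    if base < 1:
        raise ValueError("base chromosome count must be >= 1")
    count = base
    for m in multipliers:
        if isinstance(m, str):
            m = {"WGD": 2, "WGT": 3}[m.upper()]
        count *= int(m)
    return count


# ---------------------------------------------------------------------------
# Junction parsimony


def canonical_junction(seg_a: Segment, seg_b: Segment):
    """Flip-invariant canonical form of the ordered adjacency seg_a -> seg_b."""
    fwd = (seg_a.id, seg_a.orientation, seg_b.id, seg_b.orientation)
    rev = (seg_b.id, "-" if seg_b.orientation == "+" else "+",
           seg_a.id, "-" if seg_a.orientation == "+" else "+")
    return min(fwd, rev)


_canonical_junction = canonical_junction


def junctions(karyotype: Karyotype) -> set[tuple]:
    """Canonical ordered segment adjacencies of a karyotype.

    A chromosome read backwards is the same chromosome: each adjacency is
    stored in a flip-invariant canonical form.
    """
    out = set()
    for chrom in karyotype.chromosomes:
        for a, b in zip(chrom, chrom[1:]):
            out.add(_canonical_junction(a, b))
    return out


@dataclass
class SharedFusionResult:
    shared: set[tuple]
    conflicting: list[frozenset] = field(default_factory=list)
    per_genome: dict[str, set] = field(default_factory=dict)


def infer_shared_fusions(segment_maps: dict[str, Karyotype],
                         outgroup: Karyotype | None = None) -> SharedFusionResult:
    """Junctions present in every descendant and absent from the outgroup.

    Segment maps express each genome's chromosomes as ordered
    ancestral-segment lists.  A junction whose segment pair occurs in all
    descendants but with inconsistent orientations is excluded and flagged.
    """
    if not segment_maps:
        raise KaryotypeError("no segment maps given")
    per_genome = {name: junctions(k) for name, k in segment_maps.items()}
    shared = set.intersection(*per_genome.values())
    out_j = junctions(outgroup) if outgroup is not None else set()
    shared -= out_j
    # orientation conflicts: same unordered id pair adjacent in all genomes
    # but no single canonical junction shared
    pair_sets = []
    for js in per_genome.values():
        pair_sets.append({frozenset((j[0], j[2])) for j in js})
    common_pairs = set.intersection(*pair_sets)
    out_pairs = {frozenset((j[0], j[2])) for j in out_j}
    shared_pairs = {frozenset((j[0], j[2])) for j in shared}
    conflicting = sorted(
        (common_pairs - out_pairs) - shared_pairs,
        key=lambda s: sorted(s))
    return SharedFusionResult(shared, conflicting, per_genome)


def reconstruct_ancestral_karyotype(segment_maps: dict[str, Karyotype],
                                    outgroup: Karyotype):
    """Ancestor of the mapped genomes by chaining shared junctions.

    The outgroup karyotype provides the pre-fusion chromosome inventory (one
    chromosome per ancestral segment chain); shared junctions (Dollo
    parsimony) are applied to it as fusion events.  A junction pair that
    nests one chromosome inside another (X adjacent to Y on both ends, with a
    Y..X..Y occurrence in some descendant) is classified NCF; remaining
    junctions joining chromosome termini are EEJ.  Junction-graph cycles are
    broken at the junction supported by fewest genomes, with a warning entry.
    Returns (ancestral Karyotype, event list, warnings).
    """
    result = infer_shared_fusions(segment_maps, outgroup)
    shared = set(result.shared)
    warnings = [f"orientation conflict on pair {sorted(p)}"
                for p in result.conflicting]

    support = Counter()
    for j in shared:
        for js in result.per_genome.values():
            if j in js:
                support[j] += 1

    # NCF detection: X adjacent to the same partner id on both sides.
    partner_pairs = defaultdict(list)
    for j in shared:
        a, _, b, _ = j
        partner_pairs[frozenset((a, b))].append(j)
    events = []
    consumed = set()
    nested = {}
    for pair, js in partner_pairs.items():
        if len(js) >= 2 and len(pair) == 2:
            x, y = sorted(pair)
            # which of the two is nested? the one occurring between two
            # copies of the other in some descendant chromosome
            ins = _nested_of(x, y, segment_maps)
            if ins is not None:
                host = y if ins == x else x
                events.append(RearrangementEvent("NCF", (host, ins)))
                nested[ins] = host
                consumed.update(js)
    # EEJ chaining on the rest
    chains = {i: [chrom] for i, chrom in enumerate(outgroup.chromosomes)}
    seg_to_chrom = {}
    for i, chrom in enumerate(outgroup.chromosomes):
        for seg in chrom:
            seg_to_chrom[seg.id] = i
    # fold nested chromosomes into hosts (count -1 each, ends unchanged)
    for ins, host in nested.items():
        ci, ch = seg_to_chrom.get(ins), seg_to_chrom.get(host)
        if ci is None or ch is None or ci == ch:
            continue
        chains[ch] = chains[ch] + chains.pop(ci)
        for cid, members in chains.items():
            for chrom in members:
                for seg in chrom:
                    seg_to_chrom[seg.id] = cid

    used_ends = set()
    for j in sorted(shared - consumed, key=lambda j: -support[j]):
        a_id, a_or, b_id, b_or = j
        ca, cb = seg_to_chrom.get(a_id), seg_to_chrom.get(b_id)
        if ca is None or cb is None:
            continue
        if ca == cb:
            warnings.append(f"junction cycle broken at {j}")
            continue
        end_a = (a_id, "tail" if a_or == "+" else "head")
        end_b = (b_id, "head" if b_or == "+" else "tail")
        if end_a in used_ends or end_b in used_ends:
            warnings.append(f"end reuse, junction skipped: {j}")
            continue
        used_ends.update((end_a, end_b))
        events.append(RearrangementEvent("EEJ", (a_id, b_id)))
        chains[ca] = chains[ca] + chains.pop(cb)
        for cid, members in chains.items():
            for chrom in members:
                for seg in chrom:
                    seg_to_chrom[seg.id] = cid

    ancestral = Karyotype(
        "ancestor", [sum(members, []) for members in chains.values()])
    return ancestral, events, warnings


def _nested_of(x: str, y: str, segment_maps):
    """Return whichever of x, y occurs strictly between two occurrences of the
    other in some descendant chromosome, else None."""
    for k in segment_maps.values():
        for chrom in k.chromosomes:
            ids = [seg.id for seg in chrom]
            for ins, host in ((x, y), (y, x)):
                for i, sid in enumerate(ids[1:-1], start=1):
                    if sid == ins and ids[i - 1] == host and ids[i + 1] == host:
                        return ins
            # host occurrences flanking a run containing ins
            for ins, host in ((x, y), (y, x)):
                positions = [i for i, sid in enumerate(ids) if sid == host]
                if len(positions) >= 2:
                    lo, hi = positions[0], positions[-1]
                    if ins in ids[lo + 1:hi]:
                        return ins
    return None


# ---------------------------------------------------------------------------
# Connection patterns and the two-step test

CP_COLINEAR = "(A)-(B)"
CP_INVERTED = "(A)-(-B)"
CP_UNLINKED = "unlinked"


@dataclass(frozen=True)
class RegionCopy:
    """One homologous copy of an adjacent region pair (A, B)."""

    name: str
    chrom_a: str
    chrom_b: str
    relative_orientation: str = "+"  # of B vs A, from synteny orientation


def connection_pattern(copy: RegionCopy) -> str:
    if copy.chrom_a != copy.chrom_b:
        return CP_UNLINKED
    return CP_COLINEAR if copy.relative_orientation == "+" else CP_INVERTED


def connection_patterns(copies) -> dict[str, str]:
    return {c.name: connection_pattern(c) for c in copies}


@dataclass
class TwoStepResult:
    status: str  # "resolved" | "uninformative" | "uninformative(outgroup)"
    first_step: tuple[str, str] | None = None
    second_step: str | None = None


def two_step_inference(ingroup_cps: dict[str, str], outgroup_cp: str) -> TwoStepResult:
    """Infer the order of a two-step hexaploidy from shared derived patterns.

    Given connection patterns of the three subgenome copies (keyed by
    subgenome label, e.g. LF/MF1/MF2) and the outgroup's ancestral pattern:
    if exactly two copies share a derived pattern (the inversion of the
    outgroup state), those two subgenomes formed the first-step tetraploid
    and the third was added by later hybridisation.
    """
    if outgroup_cp not in (CP_COLINEAR, CP_INVERTED):
        return TwoStepResult("uninformative(outgroup)")
    if len(ingroup_cps) != 3:
        raise KaryotypeError("two-step inference needs exactly 3 subgenome copies")
    derived_cp = CP_INVERTED if outgroup_cp == CP_COLINEAR else CP_COLINEAR
    derived = sorted(lbl for lbl, cp in ingroup_cps.items() if cp == derived_cp)
    if len(derived) != 2:
        return TwoStepResult("uninformative")
    (second,) = [lbl for lbl in ingroup_cps if lbl not in derived]
    return TwoStepResult("resolved", tuple(derived), second)


# ---------------------------------------------------------------------------
# Plain-text karyotype format: one chromosome per line, signed segment ids.


def write_karyotype(karyotype: Karyotype, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#karyotype {karyotype.name}\n")
        for chrom in karyotype.chromosomes:
            fh.write(" ".join(
                ("" if seg.orientation == "+" else "-") + seg.id
                for seg in chrom) + "\n")


def read_karyotype(path, name: str | None = None) -> Karyotype:
    chroms = []
    kname = name or "karyotype"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#karyotype") and name is None:
                    kname = line.split(None, 1)[1]
                continue
            segs = []
            for token in line.split():
                if token.startswith("-"):
                    segs.append(Segment(token[1:], "-"))
                else:
                    segs.append(Segment(token.lstrip("+"), "+"))
            chroms.append(segs)
    return Karyotype(kname, chroms)
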
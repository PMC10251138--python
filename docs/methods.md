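# Methods

This note documents the models behind `paleohexkit`, the conventions and
numerical choices the implementation commits to, and what the synthetic
data generator does and does not emulate.

## Synteny chaining

Homology hits are filtered before chaining: E-value strictly below 1e-5,
bit score strictly above 100, and both genes in families of fewer than 50
members.  Family size is computed as 1 + the number of distinct partners a
gene has in the E-value-passing hit graph, pooled across all genomes
(`within_genome_only` restricts it).  E-value/score filtering is applied
before the family cut, and the filter is idempotent.

Blocks are chains of anchors strictly monotone in the first genome's gene
order and monotone increasing (`same`) or decreasing (`inverted`) in the
second, with at most `max_gap` (default 50) intervening genes between
consecutive anchors on either axis.  Per chromosome pair the longest
admissible chain is found by O(n²) dynamic programming, run for both
orientations; chains are extracted greedily by anchor count (minimum 5,
configurable) and removed, so blocks of one chromosome pair never share an
anchor.  The unit tests verify each extracted chain against an independent
exhaustive longest-chain recursion.  Two determinism conventions: a
self-comparison uses each unordered gene pair once, oriented by coordinate;
a cross-genome comparison is computed with the lexicographically smaller
genome name on the A side and transposed back, which makes A-vs-B and
B-vs-A results exactly transposed even when equal-score chains would
otherwise leave the extraction ambiguous.

The orthology depth ratio reports, at the modal covered locus, how many
regions of each genome correspond: `(1, 3)` means one reference region is
matched by three query regions, the signature of a hexaploid descendant
against an unduplicated reference.

## Nei–Gojobori Ka/Ks

Codon pairs come from positional pairing of equal-length CDSs or from a
protein alignment whose gap columns are dropped; codons containing
ambiguity codes are dropped pairwise, and internal stops are rejected.
Site counting averages over the two sequences; per codon position the
synonymous fraction is taken over the non-stop single-nucleotide fates, so
S + N equals exactly 3 per codon.  For codons differing at several
positions, all orderings of the minimal mutational pathways are weighted
equally and pathways passing through a stop codon are dropped; in the rare
case that every pathway is blocked, all are used and steps touching a stop
count as nonsynonymous.  Proportions are corrected with Jukes–Cantor;
p ≥ 3/4 is reported as saturated (missing) rather than a number.  Only the
universal genetic code is supported.  Other implementations of this
statistic differ in exactly these conventions (stop-fate handling, pathway
weighting), so third-party values can differ in the third decimal; the
package's own convention is frozen by an exhaustive enumeration oracle in
the test suite at 1e-9.

## Ks distributions, peaks, and dating

Block Ks medians (anchors with undefined Ks excluded) are the unit of
distribution analysis.  Density is a Gaussian kernel with a fixed absolute
bandwidth of 0.05 Ks units — deliberately not a data-scaled bandwidth, so
distributions of different dispersion are smoothed identically.  Values
above a ceiling (default 3.0, saturation territory) are excluded.

Mixtures are fitted on the KDE curve by bounded least squares, trying 1, 2,
… components until R² against the curve reaches 0.95 (`min_r2`); the
smallest sufficient component count is kept, and an insufficient fit at
`max_components` is returned flagged.  Initial means come from curve peaks,
falling back to density quantiles.  Because the fit is against the
smoothed curve, fitted component sigmas absorb the kernel width
(σ_fit² ≈ σ_true² + 0.05²); means are unaffected, and means are what the
downstream dating uses.  As a side channel, means can be refined by EM on
the raw values (`mu_ml`, scikit-learn initialised at the curve fit); the
curve-fit mean remains the primary estimate because the curve-fitting
procedure is the one the rest of the analysis is defined against.

Rate correction runs in two rounds.  Round 1 uses each lineage's divergence
peak against a common outgroup.  With the slowest lineage s as benchmark
(λ = 1), the printed alignment rule ((1+λᵢ)/2)·μᵢ = μₛ gives
λᵢ = 2μₛ/μᵢ − 1, and the corrected distribution is (λᵢμᵢ, λᵢ²σᵢ²).  These
two statements are in tension: rescaling the whole distribution by λᵢ moves
the peak to λᵢμᵢ, which equals μₛ only for the benchmark, while the
branch-average quantity ((1+λᵢ)/2)·μᵢ lands on μₛ exactly.  The package
implements both as stated and exposes both (`apply_correction` and
`branch_aligned_peak`) rather than guessing a reconciliation; round-1
idempotence (recomputed λ = 1) holds for the branch-aligned quantity.
λ ≤ 0 (a lineage more than twice as fast as the benchmark implies) is an
error.  Round 2 aligns the shared-polyploidy paralog peaks: both branches
of a paralog pair evolve inside one lineage, so the full scaling is
λ² = μₛ/μᵢ on the round-1-corrected paralog peaks; composed with round 1,
every lineage's polyploidy peak lands on the benchmark exactly.  Relative
lineage rates are recovered by this construction to within sampling error
(the suite checks 5% at 2000 pairs per class).

Dating is linear: T = μ_corrected · (T_cal / μ_cal), applied to both ends
of a calibration interval supplied by the user (no internal molecular-rate
constant is assumed).

## Event classification and the alignment table

A block is assigned to the event whose expected Ks peak is nearest its
median, within a per-event tolerance (default 0.3); equidistant peaks
(within 1e-9) flag the block `unclassified(tie)`.

The alignment table has one row per reference gene.  The reference's own
hexaploidy defines 3 panels; within each panel every target genome owns
m = 3·2^N columns (N = number of tetraploidies after the shared
hexaploidy), giving 3·(1 + Σ m) columns in total — 30 for a reference plus
one hexaploid and one hexaploid + tetraploid genome.  A genome without the
shared hexaploidy is not representable and is rejected.  Slots are
assigned region-wise: block spans partition each reference chromosome into
elementary regions with a stable covering-block set; within a region,
covering blocks are ranked by anchors retained (most-retained first), so
slot 1 tracks the least-fractionated subgenome and neighbouring genes of a
block share a slot.  More covering regions than slots raises an overflow
flag listing the extras.  Dots mark missing orthologs; genes present in
the target genome but placeable in no block are additionally recorded as
translocation candidates in a side channel, since "lost" and "translocated"
render identically in the table.

## Fractionation statistics

Retention profiles count non-dot cells per slot in sliding windows
(default 50 genes, step = window/2 for profiles; the P-index uses
non-overlapping windows).  A chromosome shorter than one window yields a
single truncated, flagged window.

Runs of consecutively lost genes (maximal dot runs, broken at chromosome
boundaries) are modelled as geometric: f(k|p) = (1−p)^(k−1)·p.  p is
estimated by least squares of the empirical run-length frequencies against
the model over k = 1..k_max (zero-filled), cross-checkable against the
closed-form MLE 1/mean; single-length or tiny (< 20 runs) inputs fall back
to the MLE, flagged.  The quoted F statistic is the regression F of the
one-parameter geometric fit against the intercept-only model on the
frequency table — the model-utility test, chosen because the original
formulation does not specify its F test.

Subgenome labels LF/MF1/MF2 rank the three homologous copies of each
reference region by retained ortholog count; ties break by total retained
genes on the copy's chromosome, then lexicographically, with tied regions
logged.  Genome-wide subgenomes are stitched by majority vote over the
regions sharing a chromosome.  Retention divergence between copies is
tested by χ² goodness of fit against equal retention (df = copies − 1),
with an exact multinomial fallback (flagged) when expected counts drop
below 5 and the total is small enough to enumerate.

The P-index follows the windowed-asymmetry formula: per chromosome,
sign(Aᵢ−Bᵢ) summed over divergent windows, normalised by the count of
non-tied windows, in absolute value; chromosomes are combined with weights
proportional to their window counts (w_c = N_c/ΣN_c).  A window is
divergent when |Aᵢ−Bᵢ| ≥ 1 (configurable minimum difference); tied windows
contribute nothing and all-tied chromosomes are excluded with weights
renormalised.  With more than two subgenome copies the index is computed
over all copy pairs and averaged.  The index lies in [0,1], is invariant
to copy swapping and chromosome order, and the published decision rule
reads > 0.3 as paleoallopolyploid, < 0.3 as paleoautopolyploid.

## Karyotype algebra and ancestral reconstruction

Karyotypes are lists of chromosomes, each an ordered list of signed
segments.  Operators and their chromosome-count effects: EEJ (−1), NCF
(−1; a terminal "insertion" is rejected as being an EEJ), RCT (0), NCT (0;
moving a whole chromosome is rejected as a fusion), fission (+1), WGD/WGT
(×2/×3 with copy-suffixed segment ids).  Segment multisets are conserved by
everything except WGD/WGT.  `chromosome_count_after` is the pure
arithmetic; a property test checks it against actually applying 1000
random event sequences.

Junctions (ordered segment adjacencies) are stored in a flip-invariant
canonical form — a chromosome read backwards is the same chromosome.
Ancestral inference is Dollo-style parsimony: a junction present in every
descendant's segment map and absent from the outgroup is assigned to the
common ancestor; junction pairs adjacent in all descendants but with
irreconcilable orientations are excluded and flagged.  No allowance is
made for convergent fusions.  Reconstruction starts from the outgroup's
chromosome inventory, detects nested patterns (X adjacent to the same
partner on both sides, with a Y‥X‥Y occurrence in a descendant) as NCF,
chains the remaining junctions as EEJ with union-find, breaks junction
cycles at the weakest support with a warning, and emits the event list.
Segment maps derived from synteny drop segments shorter than a
configurable anchor count (default 10 genes), the "ignore small inversions
and deletions" rule; descendant maps repeat ancestral ids across polyploid
copies and are therefore built without the uniqueness invariant.

Connection patterns classify each homologous copy of an adjacent region
pair (A, B) as `(A)-(B)`, `(A)-(-B)` (B inverted relative to A), or
`unlinked` (different chromosomes).  The two-step test: with the outgroup
fixing the ancestral pattern, if exactly two of the three subgenome copies
share the derived (inverted) pattern, those two formed the first-step
tetraploid and the third subgenome was added by later hybridisation; zero
or three derived copies, or an ambiguous outgroup, are uninformative.

## The synthetic-data generator

The generator emulates the study design the package analyses: an ancestral
gene order (default 7 chromosomes × 200 genes); an unduplicated outgroup;
a shared triplication whose three subgenomes fractionate at biased rates —
default loss rates (0.2, 0.4, 0.6), i.e. retention 2 : 1.5 : 1 — with loss
placed as geometric(p = 0.29) runs at non-overlapping positions (dense
loss falls back to merely non-overlapping placement, and a region that
would empty is an error); optional lineage-specific tetraploidy with its
own per-copy loss; shared and lineage-specific EEJ/NCF/RCT/NCT events
applied through the karyotype module (with segment splitting at random
internal breakpoints); homology hits for every surviving homolog pair plus
optional sub-threshold noise hits; and per-pair Ks drawn from
event-specific normals truncated at zero — defaults μ = 1.52 (outgroup
divergence), 0.95 (shared hexaploidy), 0.56 (ingroup speciation), 0.30
(later tetraploidy), matching the Ks regimes such analyses encounter, with
per-lineage rate multipliers entering as the mean of the two branch rates.
One seeded generator threads through all steps; a seed fixes every output
bit for bit.

CDS pairs are emitted against the Ks engine as oracle: synonymous
single-nucleotide changes are placed randomly until measured Ks reaches the
target, alternating with nonsynonymous placement toward a configurable
Ka/Ks (default 0.3) until both sit at their targets.  Targets above Ks 2.5
are rejected as saturated: near p = 3/4 the Jukes–Cantor transform's
per-site granularity on a few hundred codons exceeds the ±0.05 recovery
contract.

What the generator does **not** emulate: nucleotide-level neutral
evolution (Ks values are drawn, not evolved, except in emitted CDS pairs),
tandem duplication, gene family expansion beyond polyploidy (so the
family-size filter is exercised only lightly), transposable elements and
intergenic sequence, and gradual rediploidization.  Passing recovery tests
therefore demonstrate that the pipeline inverts its own generative model at
realistic signal strengths, not that it is robust to every artefact of
real assemblies.

## Problem sizes and runtimes

The test suite runs desk-scale configurations: the end-to-end scenario uses
a 7 × 200-gene ancestor (4200 post-triplication gene slots, two descendant
genomes, one with a further tetraploidy), which chains, tabulates, labels
subgenomes, and reconstructs the ancestral karyotype in a few seconds;
distribution-level checks use 5000 Ks draws and 10⁴ geometric runs.  The
acceptance script's P-index scenarios use 10 chromosomes × 50 windows × 50
genes per subgenome copy.

## Known limitations

- The O(n²) chain DP is sized for gene-order data (hundreds to thousands of
  hits per chromosome pair), not raw nucleotide anchors.
- Slot identity in the alignment table may switch between adjacent regions
  when covering-block sets change; fractionation statistics are computed
  per region precisely to be robust to this.
- Ancestral reconstruction reports, but does not resolve, ties among
  equally parsimonious junction chainings, and cannot recover a junction
  destroyed in any one descendant (strict presence-in-all rule).
- Subgenome labels for a genome with a second polyploidy rank its top
  three retained copies directly; pairing tetraploidy copies into
  hexaploidy subgenomes before ranking is left to the caller.
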
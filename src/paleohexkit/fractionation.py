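"""Subgenome retention/loss statistics: sliding-window retention profiles,
geometric loss-run model, LF/MF1/MF2 assignment, and the P-index.

The loss-run model treats each maximal run of consecutively lost genes as a
draw from a geometric distribution f(k | p) = (1 - p)^(k-1) p; p is fitted by
least squares of the empirical run-length frequencies against the model and
cross-checkable against the closed-form MLE 1/mean.  The P-index summarises
window-level retention asymmetry between two subgenome copies; published
usage reads P-index > 0.3 as paleoallopolyploidy and < 0.3 as
paleoautopolyploidy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .model import PaleohexkitError
from .table import DOT


@dataclass
class Window:
    start: int
    end: int  # exclusive, in reference gene-order units
    retained: list[int]  # one count per subgenome slot


@dataclass
class RetentionProfile:
    chromosome: str
    window_size: int
    step: int
    windows: list[Window]
    truncated: bool = False


def retention_profile(columns, chromosome: str, window: int = 50,
                      step: int | None = None) -> RetentionProfile:
    """Sliding-window retained (non-dot) counts over aligned slot columns.

    ``columns`` is a list of equal-length cell sequences (one per subgenome
    slot) in reference gene order for one chromosome.  Default step is
    window/2.  A chromosome shorter than one window yields a single truncated
    window, flagged.
    """
    if step is None:
        step = max(1, window // 2)
    n = len(columns[0])
    if any(len(c) != n for c in columns):
        raise PaleohexkitError("slot columns differ in length")
    masks = [np.asarray([cell != DOT for cell in col]) for col in columns]
    windows = []
    truncated = n < window
    if truncated:
        windows.append(Window(0, n, [int(m.sum()) for m in masks]))
    else:
        for start in range(0, n - window + 1, step):
            end = start + window
            windows.append(Window(start, end,
                                  [int(m[start:end].sum()) for m in masks]))
    return RetentionProfile(chromosome, window, step, windows, truncated)


def loss_runs(column) -> Counter:
    """Multiset of maximal consecutive-dot run lengths in one slot column."""
    runs: Counter = Counter()
    length = 0
    for cell in column:
        if cell == DOT:
            length += 1
        elif length:
            runs[length] += 1
            length = 0
    if length:
        runs[length] += 1
    return runs


def loss_percentage(lost: int, total: int, digits: int = 1) -> float:
    """Percentage of reference genes lost, rounded as printed reports do."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * lost / total, digits)


@dataclass
class GeometricLossModel:
    p: float
    run_lengths: Counter
    r_squared: float
    f_test_p: float
    mle_p: float
    flagged: bool = False

    def pmf(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return (1.0 - self.p) ** (k - 1.0) * self.p


def geometric_mle(run_lengths: Counter) -> float:
    n = sum(run_lengths.values())
    total = sum(k * c for k, c in run_lengths.items())
    return n / total


def fit_geometric(run_lengths: Counter, min_runs: int = 20) -> GeometricLossModel:
    """Least-squares fit of run-length frequencies to the geometric model.

    Minimises sum_k (freq_k - (1-p)^(k-1) p)^2 over observed k (zero-count
    lengths up to the maximum included).  Degenerate single-length data falls
    back to the closed-form MLE 1/mean, flagged.  The F test compares the
    one-parameter fit against the intercept-only (constant-frequency) model.
    """
    run_lengths = Counter(run_lengths)
    if not run_lengths:
        raise PaleohexkitError("no loss runs to fit")
    n_runs = sum(run_lengths.values())
    mle = geometric_mle(run_lengths)
    kmax = max(run_lengths)
    ks = np.arange(1, kmax + 1, dtype=float)
    freqs = np.array([run_lengths.get(int(k), 0) / n_runs for k in ks])

    if len(run_lengths) == 1 or n_runs < min_runs:
        return GeometricLossModel(mle, run_lengths, 1.0 if kmax == 1 else
                                  float("nan"), float("nan"), mle, flagged=True)

    def sse(p):
        model = (1.0 - p) ** (ks - 1.0) * p
        return float(np.sum((freqs - model) ** 2))

    res = minimize_scalar(sse, bounds=(1e-9, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    p_hat = float(res.x)
    model = (1.0 - p_hat) ** (ks - 1.0) * p_hat
    ss_res = float(np.sum((freqs - model) ** 2))
    ss_tot = float(np.sum((freqs - freqs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(ks) - 2
    if dof > 0 and ss_res > 0:
        f_stat = (ss_tot - ss_res) / (ss_res / dof)
        f_p = float(stats.f.sf(f_stat, 1, dof))
    else:
        f_p = 0.0
    return GeometricLossModel(p_hat, run_lengths, r2, f_p, mle)


def assign_subgenomes(region_retention, labels=("LF", "MF1", "MF2")):
    """Rank homologous copies of each region by retention into LF/MF1/MF2.

    ``region_retention`` is a list of records
    ``(region_id, [(copy_id, retained, chromosome_total), ...])`` with one
    entry per subgenome copy; ``chromosome_total`` (retained genes on the
    copy's harbouring chromosome) breaks ties, then copy id lexicographic.
    Returns ``{region_id: {copy_id: label}}`` plus the list of regions where a
    tie path was taken.
    """
    out = {}
    tie_log = []
    for region_id, copies in region_retention:
        if len(copies) != len(labels):
            raise PaleohexkitError(
                f"region {region_id}: expected {len(labels)} copies, got "
                f"{len(copies)}")
        counts = [c[1] for c in copies]
        if len(set(counts)) < len(counts):
            tie_log.append(region_id)
        ranked = sorted(copies, key=lambda c: (-c[1], -c[2], str(c[0])))
        out[region_id] = {copy_id: label
                          for (copy_id, _, _), label in zip(ranked, labels)}
    return out, tie_log


def stitch_subgenomes(region_labels):
    """Majority-vote label per copy id (chromosome context) across regions."""
    votes: dict[str, Counter] = {}
    for labels in region_labels.values():
        for copy_id, label in labels.items():
            votes.setdefault(copy_id, Counter())[label] += 1
    return {cid: c.most_common(1)[0][0] for cid, c in votes.items()}


def retention_divergence_test(counts, exact_limit: int = 60):
    """Goodness-of-fit of retained counts against equal retention per copy.

    Chi-square with df = copies - 1; falls back to an exact multinomial test
    (flagged) when any expected count is below 5 and the total is small.
    Returns (p_value, flagged).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2 or counts.sum() <= 0:
        raise PaleohexkitError("need >= 2 copies with positive total")
    total = counts.sum()
    expected = total / counts.size
    if expected < 5 and total <= exact_limit:
        return _exact_multinomial(counts.astype(int)), True
    stat, p = stats.chisquare(counts)
    return float(p), False


def _exact_multinomial(counts):
    k = len(counts)
    n = int(counts.sum())
    probs = np.full(k, 1.0 / k)
    observed_p = stats.multinomial.pmf(counts, n, probs)
    total = 0.0
    # enumerate all compositions of n into k parts
    def rec(prefix, remaining, slots):
        nonlocal total
        if slots == 1:
            comp = prefix + [remaining]
            p = stats.multinomial.pmf(comp, n, probs)
            if p <= observed_p + 1e-12:
                total += p
            return
        for x in range(remaining + 1):
            rec(prefix + [x], remaining - x, slots - 1)
    rec([], n, k)
    return float(min(1.0, total))


@dataclass
class ChromosomeWindows:
    chromosome: str
    a: np.ndarray  # retained counts, copy A, one per window
    b: np.ndarray  # retained counts, copy B


@dataclass
class PIndexInputs:
    chromosomes: list[ChromosomeWindows]
    min_difference: int = 1  # |A - B| >= this counts as divergent


@dataclass
class PIndexResult:
    value: float
    per_chromosome: dict[str, float]
    excluded: list[str] = field(default_factory=list)


def p_index(inputs: PIndexInputs) -> PIndexResult:
    """Windowed between-subgenome retention asymmetry.

    Per chromosome: the signed indicator of which copy retained more, summed
    over divergent windows and normalised by the non-tied window count, in
    absolute value; chromosomes are combined with weights proportional to
    their window counts.  Tied windows contribute nothing and all-tied
    chromosomes are excluded with weights renormalised.
    """
    terms = {}
    weights = {}
    excluded = []
    for cw in inputs.chromosomes:
        a = np.asarray(cw.a, dtype=float)
        b = np.asarray(cw.b, dtype=float)
        if a.shape != b.shape:
            raise PaleohexkitError(
                f"{cw.chromosome}: window counts differ between copies")
        diff = a - b
        divergent = np.abs(diff) >= inputs.min_difference
        n_c = len(a)
        n_tied = int((~divergent).sum())
        if n_c == n_tied:
            excluded.append(cw.chromosome)
            continue
        signed = np.sign(diff[divergent]).sum()
        terms[cw.chromosome] = abs(signed) / (n_c - n_tied)
        weights[cw.chromosome] = n_c
    if not terms:
        return PIndexResult(0.0, {}, excluded)
    total_w = sum(weights.values())
    value = sum(weights[c] / total_w * t for c, t in terms.items())
    return PIndexResult(float(value), terms, excluded)


def p_index_multi(copy_windows: dict[str, list[ChromosomeWindows]] | list,
                  min_difference: int = 1) -> PIndexResult:
    """P-index over >2 subgenome copies: all copy pairs, averaged.

    ``copy_windows`` is a list of per-copy window-count arrays grouped as
    ``[(chromosome, {copy: counts})...]``.
    """
    pair_results = []
    chroms = copy_windows
    copy_ids = sorted({cid for _, per_copy in chroms for cid in per_copy})
    for ca, cb in combinations(copy_ids, 2):
        cws = [ChromosomeWindows(chrom, per_copy[ca], per_copy[cb])
               for chrom, per_copy in chroms
               if ca in per_copy and cb in per_copy]
        if cws:
            pair_results.append(p_index(PIndexInputs(cws, min_difference)))
    if not pair_results:
        raise PaleohexkitError("no comparable copy pairs")
    value = float(np.mean([r.value for r in pair_results]))
    merged: dict[str, float] = {}
    for r in pair_results:
        for c, t in r.per_chromosome.items():
            merged[c] = merged.get(c, 0.0) + t / len(pair_results)
    return PIndexResult(value, merged)


def simulate_retention_windows(loss_rate_a: float, loss_rate_b: float,
                               n_chromosomes: int = 10, n_windows: int = 50,
                               genes_per_window: int = 50,
                               rng=None) -> PIndexInputs:
    """Binomial per-window retained counts for two subgenome copies.

    Each window of ``genes_per_window`` ancestral genes retains each gene
    independently with probability 1 - loss rate; equal rates emulate an
    autopolyploid, unequal rates a biased allopolyploid.
    """
    rng = np.random.default_rng(rng)
    chroms = []
    for c in range(n_chromosomes):
        a = rng.binomial(genes_per_window, 1.0 - loss_rate_a, size=n_windows)
        b = rng.binomial(genes_per_window, 1.0 - loss_rate_b, size=n_windows)
        chroms.append(ChromosomeWindows(f"chr{c + 1}", a, b))
    return PIndexInputs(chroms)
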
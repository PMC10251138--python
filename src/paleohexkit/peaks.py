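"""Ks-distribution peak fitting, lineage-rate correction, and event dating.

The density of Ks values (or block Ks medians) is estimated with a Gaussian
kernel of fixed absolute width (default 0.05), then fitted with the fewest
Gaussian components reaching a target R-squared (default 0.95) by least
squares on the density curve.  Peaks feed a two-round rate correction: round
one aligns each lineage's divergence peak against the slowest lineage via the
branch-average rule ((1 + lambda_i)/2) * mu_i = mu_s, round two aligns the
shared-polyploidy paralog peaks via lambda^2 = mu_s / mu_i (both branches of a
paralog pair evolve in the same lineage).  Corrected peaks are dated linearly
against a user-supplied calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .model import PaleohexkitError


class PeakFitError(PaleohexkitError):
    pass


@dataclass
class GaussianComponent:
    mu: float
    sigma: float
    weight: float
    mu_ml: float | None = None  # side-channel: EM-refined mean


@dataclass
class KsPeakModel:
    components: list[GaussianComponent]
    r_squared: float
    source: str = ""
    flagged: bool = False

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if total > 0:
            for c in self.components:
                c.weight /= total

    @property
    def mus(self) -> list[float]:
        return [c.mu for c in self.components]


@dataclass
class CorrectionCoefficient:
    lineage: str
    lambda_: float
    mu_i: float
    sigma_i: float
    mu_s: float
    round: int = 1


@dataclass
class Calibration:
    event: str
    time_mya: tuple[float, float]  # (low, high); pass (t, t) for a point
    corrected_mu: float

    def __post_init__(self) -> None:
        if isinstance(self.time_mya, (int, float)):
            self.time_mya = (float(self.time_mya), float(self.time_mya))
        if min(self.time_mya) <= 0 or self.corrected_mu <= 0:
            raise ValueError("calibration time and Ks peak must be positive")


def kde_density(ks_values, bandwidth: float = 0.05, grid=None,
                grid_points: int = 512):
    """Gaussian kernel density of Ks values on a grid.

    The bandwidth is the absolute kernel standard deviation in Ks units
    (not a data-scaled factor).  Returns (grid, density).
    """
    values = np.asarray(ks_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise PeakFitError("need at least 2 Ks values for a density estimate")
    if grid is None:
        lo = max(0.0, values.min() - 4 * bandwidth)
        hi = values.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, grid_points)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        values.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, density


def _mixture_curve(x, *params):
    y = np.zeros_like(x)
    for j in range(0, len(params), 3):
        mu, sigma, w = params[j:j + 3]
        y = y + w / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - mu) / sigma) ** 2)
    return y


def _r_squared(y, fit):
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _initial_mus(grid, density, k):
    idx, _ = find_peaks(density)
    idx = sorted(idx, key=lambda i: -density[i])[:k]
    mus = sorted(grid[i] for i in idx)
    while len(mus) < k:  # fall back to quantile spread
        q = (len(mus) + 1) / (k + 1)
        cdf = np.cumsum(density)
        cdf /= cdf[-1]
        mus.append(float(grid[np.searchsorted(cdf, q)]))
        mus.sort()
    return mus


def fit_gaussian_mixture(values=None, density=None, grid=None,
                         max_components: int = 4, min_r2: float = 0.95,
                         bandwidth: float = 0.05, ks_ceiling: float = 3.0,
                         refine_ml: bool = True, source: str = "") -> KsPeakModel:
    """Fit the fewest Gaussian components reaching ``min_r2`` on the KDE curve.

    Accepts raw Ks values (KDE computed here; values above ``ks_ceiling``
    are excluded as saturated) or a precomputed (grid, density) curve.  When
    ``min_r2`` is unreachable at ``max_components`` the best fit is returned
    flagged.  With raw values and ``refine_ml``, component means are also
    refined by EM on the raw values and exposed as ``mu_ml``.
    """
    if density is None:
        if values is None:
            raise PeakFitError("provide Ks values or a density curve")
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values) & (values <= ks_ceiling)]
        grid, density = kde_density(values, bandwidth=bandwidth)
    else:
        if grid is None:
            raise PeakFitError("a density curve needs its grid")
        grid = np.asarray(grid, dtype=float)
        density = np.asarray(density, dtype=float)

    span = grid.max() - grid.min()
    best = None
    for k in range(1, max_components + 1):
        mus0 = _initial_mus(grid, density, k)
        p0, lo, hi = [], [], []
        for mu in mus0:
            p0 += [mu, max(bandwidth, span / (6 * k)), 1.0 / k]
            lo += [grid.min(), 1e-4, 0.0]
            hi += [grid.max(), span, 10.0]
        try:
            popt, _ = curve_fit(_mixture_curve, grid, density, p0=p0,
                                bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        r2 = _r_squared(density, _mixture_curve(grid, *popt))
        comps = sorted(
            (GaussianComponent(float(popt[j]), float(popt[j + 1]),
                               float(popt[j + 2]))
             for j in range(0, len(popt), 3)), key=lambda c: c.mu)
        model = KsPeakModel(comps, r2, source=source)
        if best is None or r2 > best.r_squared:
            best = model
        if r2 >= min_r2:
            best = model
            break
    if best is None:
        raise PeakFitError("mixture fit failed at every component count")
    best.flagged = best.r_squared < min_r2
    if refine_ml and values is not None and len(best.components) >= 1:
        _refine_means_ml(best, values)
    return best


def _refine_means_ml(model: KsPeakModel, values) -> None:
    from sklearn.mixture import GaussianMixture

    k = len(model.components)
    gm = GaussianMixture(
        n_components=k,
        weights_init=np.array([c.weight for c in model.components]),
        means_init=np.array([[c.mu] for c in model.components]),
        precisions_init=np.array([[[1.0 / c.sigma ** 2]]
                                  for c in model.components]),
        max_iter=200, random_state=0)
    gm.fit(np.asarray(values, dtype=float).reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    for comp, mean in zip(model.components, gm.means_.ravel()[order]):
        comp.mu_ml = float(mean)


def correction_coefficient(mu_i: float, mu_s: float) -> float:
    """Round-1 rate-correction coefficient: lambda_i = 2 mu_s / mu_i - 1.

    Derived from aligning divergence peaks through the branch average,
    ((1 + lambda_i)/2) mu_i = mu_s.  The slowest lineage gets lambda = 1.
    """
    if mu_i <= 0 or mu_s <= 0:
        raise ValueError("Ks peaks must be positive")
    lam = 2.0 * mu_s / mu_i - 1.0
    if lam <= 0:
        raise PeakFitError(
            f"inconsistent correction: mu_i={mu_i} is more than twice the "
            f"benchmark mu_s={mu_s}")
    return lam


def apply_correction(peak: tuple[float, float], lambda_: float):
    """Rescale a (mu, sigma) peak: corrected distribution (lambda mu, lambda^2 sigma^2).

    Note the corrected peak lambda*mu differs from the benchmark mu_s unless
    lambda = 1; the branch-average alignment quantity is
    ``branch_aligned_peak``.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    mu, sigma = peak
    return lambda_ * mu, lambda_ * sigma


def branch_aligned_peak(mu_i: float, lambda_: float) -> float:
    """The branch-average aligned peak ((1 + lambda)/2) mu_i."""
    return (1.0 + lambda_) / 2.0 * mu_i


def first_round_correction(divergence_peaks: dict[str, tuple[float, float]],
                           benchmark: str | None = None):
    """Round-1 coefficients from per-lineage divergence peaks vs the outgroup.

    ``divergence_peaks`` maps lineage -> (mu_i, sigma_i) of its divergence
    peak against the shared outgroup.  The benchmark (slowest) lineage is the
    one with the smallest mu unless named explicitly; it gets lambda = 1.
    """
    if not divergence_peaks:
        raise PeakFitError("no divergence peaks given")
    if benchmark is None:
        benchmark = min(divergence_peaks, key=lambda k: divergence_peaks[k][0])
    mu_s = divergence_peaks[benchmark][0]
    out = {}
    for lineage, (mu_i, sigma_i) in divergence_peaks.items():
        lam = 1.0 if lineage == benchmark else correction_coefficient(mu_i, mu_s)
        out[lineage] = CorrectionCoefficient(lineage, lam, mu_i, sigma_i,
                                             mu_s, round=1)
    return out


def second_round_correction(ach_paralog_peaks: dict[str, tuple[float, float]],
                            round1: dict[str, CorrectionCoefficient],
                            benchmark: str | None = None):
    """Round-2 coefficients aligning shared-polyploidy paralog peaks.

    Paralog-pair branches both lie inside one lineage, so the full scaling is
    lambda^2 = mu_s / mu_i on the round-1-corrected paralog peaks.  Returns
    (coefficients, composed) where ``composed`` maps lineage -> overall
    lambda^2 (round-1 lambda times round-2 lambda) such that
    composed * raw paralog mu lands every lineage on the benchmark peak.
    Lineages with no paralog peak are skipped (flagged by absence).
    """
    corrected = {}
    for lineage, (mu_i, sigma_i) in ach_paralog_peaks.items():
        lam1 = round1[lineage].lambda_ if lineage in round1 else 1.0
        corrected[lineage] = (lam1 * mu_i, lam1 * sigma_i)
    if benchmark is None:
        benchmark = min(corrected, key=lambda k: corrected[k][0])
    mu_s = corrected[benchmark][0]
    coeffs = {}
    composed = {}
    for lineage, (mu_c, sigma_c) in corrected.items():
        lam_sq = mu_s / mu_c
        coeffs[lineage] = CorrectionCoefficient(
            lineage, lam_sq, mu_c, sigma_c, mu_s, round=2)
        lam1 = round1[lineage].lambda_ if lineage in round1 else 1.0
        composed[lineage] = lam1 * lam_sq
    return coeffs, composed


def date_event(corrected_mu: float, calibration: Calibration):
    """Linear Ks -> time scaling: T = corrected_mu * (T_cal / mu_cal), per endpoint."""
    lo, hi = calibration.time_mya
    scale = corrected_mu / calibration.corrected_mu
    return scale * lo, scale * hi
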
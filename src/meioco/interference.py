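"""Crossover interference: gamma model and coefficient of coincidence.

Two complementary interference statistics:

* **Gamma fit.**  On SCs carrying exactly two MLH1 foci, the inter-focus
  distance is treated as a draw from a Gamma(γ, rate) law and γ is
  estimated by maximum likelihood.  γ = 1 is the no-interference
  (Poisson) null; larger γ means more evenly spaced, more strongly
  interfering crossovers.  Distances are pooled in µm by default: under a
  constant per-µm CO intensity the gap law is identical on every SC, so
  µm pooling compares like with like, whereas normalizing by SC length
  turns the pool into a scale mixture across the 17–130 µm karyotype
  (the normalized mode is kept behind a flag).

* **CoC curve.**  Every chromosome arm is scaled to unit length and cut
  into ``n_intervals`` segments.  For each segment pair (i, j) the
  observed fraction of arms with a CO in both segments is divided by the
  product of the single-segment frequencies; the ratio, averaged over
  pairs of equal separation, is the coefficient of coincidence.  CoC = 1
  means independence; CoC < 1, interference.  The interference distance
  is the separation at which the curve first climbs back to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .model import (
    Dataset,
    DegenerateFitError,
    EmptySelectionError,
    InsufficientDataError,
    MeiocoError,
)

__all__ = [
    "GammaFit",
    "CoCCurve",
    "inter_focus_distances",
    "fit_gamma_ml",
    "arm_occupancy",
    "coc_from_occupancy",
    "coc_curve",
    "interference_distance",
]


@dataclass(frozen=True)
class GammaFit:
    """ML estimate of the gamma interference parameter.

    ``shape`` is γ; ``rate`` shares the distance units (µm⁻¹ or
    dimensionless); ``shape_ci`` is the asymptotic (observed-information)
    95% interval.
    """

    shape: float
    rate: float
    loglik: float
    n: int
    shape_ci: Optional[tuple] = None

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise MeiocoError("gamma parameters must be positive")


@dataclass(frozen=True)
class CoCCurve:
    """Coefficient of coincidence per inter-interval separation."""

    separations: tuple   # (j - i) / n_intervals, strictly increasing
    coc: tuple
    n_pairs: tuple       # segment pairs contributing at each separation
    n_intervals: int
    n_arms: int = 0
    n_degenerate_pairs: int = 0  # pairs skipped because expected == 0

    def __post_init__(self):
        if not (len(self.separations) == len(self.coc) == len(self.n_pairs)):
            raise MeiocoError("CoC curve fields must have equal length")
        if any(b <= a for a, b in zip(self.separations, self.separations[1:])):
            raise MeiocoError("separations must be strictly increasing")

    def mean_coc(self) -> float:
        return float(np.mean(self.coc))


def inter_focus_distances(
    dataset: Dataset,
    temperature: Optional[float] = None,
    normalize: bool = False,
    cross_centromere: bool = True,
) -> np.ndarray:
    """Distances between the two foci of every two-focus SC.

    Only SCs bearing exactly two MLH1 foci contribute (the classical
    harvesting rule for cytological gamma fits); SCs with one or ≥3 foci
    are ignored.  ``normalize=True`` divides each distance by its SC
    length before pooling.  ``cross_centromere=False`` drops metacentric
    SCs whose two foci straddle the centromere: when the p and q arms
    recombine independently, a straddling distance is a sum of two
    unrelated arm residuals rather than an inter-crossover gap, so
    excluding them is the model-consistent harvest for interference
    estimation (they are included by default because whole-SC scoring is
    the classical convention).
    """
    cells = dataset.pachytene_cells(temperature)
    if not cells:
        raise EmptySelectionError(f"no pachytene cells for temperature={temperature!r}")
    out = []
    for cell in cells:
        for sc in cell.scs:
            if sc.n_foci != 2:
                continue
            a, b = sc.foci_um
            if (
                not cross_centromere
                and sc.morphology == "metacentric"
                and (a < sc.centromere_um) != (b < sc.centromere_um)
            ):
                continue
            out.append((b - a) / sc.length_um if normalize else (b - a))
    if not out:
        raise EmptySelectionError("selection contains no SC with exactly two foci")
    return np.asarray(out, dtype=float)


def fit_gamma_ml(distances: Sequence[float], min_n: int = 30) -> GammaFit:
    """Maximum-likelihood two-parameter gamma fit to positive distances.

    The shape solves the profile score equation ln k − ψ(k) = ln x̄ −
    mean(ln x) (ψ the digamma function), initialized from the
    Ye–Chen-style closed form and refined to 1e-8; the rate is then
    k / x̄.  Constant input admits no proper fit and raises
    :class:`DegenerateFitError`.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < min_n:
        raise InsufficientDataError(f"gamma fit needs n >= {min_n} distances (got {x.size})")
    if np.any(x <= 0):
        raise DegenerateFitError("distances must be strictly positive")
    mean = float(x.mean())
    meanlog = float(np.log(x).mean())
    s = math.log(mean) - meanlog
    if s <= 0 or not np.isfinite(s):
        raise DegenerateFitError("zero-variance distances: gamma shape diverges")

    # closed-form initialization, then bracketed root of f(k) = ln k - psi(k) - s
    k0 = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)

    def score(k):
        return math.log(k) - special.digamma(k) - s

    lo, hi = k0 / 8.0, k0 * 8.0
    while score(lo) < 0:
        lo /= 4.0
    while score(hi) > 0:
        hi *= 4.0
    shape = float(optimize.brentq(score, lo, hi, xtol=1e-10, rtol=1e-12))
    rate = shape / mean
    loglik = float(
        x.size * (shape * math.log(rate) - math.lgamma(shape))
        + (shape - 1.0) * np.log(x).sum()
        - rate * x.sum()
    )
    # asymptotic variance of the shape from the inverse Fisher information
    denom = shape * special.polygamma(1, shape) - 1.0
    ci = None
    if denom > 0:
        se = math.sqrt(shape / (x.size * denom))
        ci = (shape - 1.959963984540054 * se, shape + 1.959963984540054 * se)
    return GammaFit(shape=shape, rate=rate, loglik=loglik, n=int(x.size), shape_ci=ci)


def arm_occupancy(
    dataset: Dataset, temperature: Optional[float] = None, n_intervals: int = 20
) -> np.ndarray:
    """Binary segment-occupancy matrix, one row per chromosome arm.

    Each arm (whole SC for acrocentrics; p and q separately for
    metacentrics) is scaled to unit length and divided into
    ``n_intervals`` equal segments; entry (arm, segment) is True iff the
    arm carries at least one CO whose centromere-referenced relative
    position falls in the segment.  Arms with no CO contribute all-False
    rows — they count in the denominator of the segment frequencies.
    """
    from .positions import _ranked_cells  # local import to avoid a cycle

    cells = _ranked_cells(dataset, temperature)
    rows = []
    for cell in cells:
        for sc in cell.scs:
            if sc.morphology == "metacentric":
                cen = sc.centromere_um
                arms = [
                    [(cen - p) / cen for p in sc.foci_um if p < cen],
                    [(p - cen) / (sc.length_um - cen) for p in sc.foci_um if p >= cen],
                ]
            else:
                arms = [[p / sc.length_um for p in sc.foci_um]]
            for fr in arms:
                row = np.zeros(n_intervals, dtype=bool)
                for f in fr:
                    row[min(int(f * n_intervals), n_intervals - 1)] = True
                rows.append(row)
    return np.asarray(rows, dtype=bool)


def coc_from_occupancy(occ: np.ndarray, weighted: bool = True) -> CoCCurve:
    """CoC curve from a binary arm × segment occupancy matrix.

    For each segment pair (i < j): observed = fraction of arms occupied
    in both; expected = product of the single-segment frequencies; pair
    CoC = observed / expected.  Pair CoCs of equal separation
    d = (j − i)/n_intervals are averaged, weighted by the number of arms
    contributing to each pair (``weighted=False`` for the plain mean);
    pairs with expected = 0 are excluded and counted as degenerate.
    """
    occ = np.asarray(occ, dtype=bool)
    if occ.ndim != 2 or occ.shape[0] == 0:
        raise EmptySelectionError("occupancy matrix has no arms")
    n_arms, n_int = occ.shape
    x = occ.astype(float)
    f = x.mean(axis=0)                      # per-segment CO frequency
    both = (x.T @ x) / n_arms               # observed double-CO frequency
    expected = np.outer(f, f)

    by_sep: dict = {}
    n_degenerate = 0
    for i in range(n_int):
        for j in range(i + 1, n_int):
            if expected[i, j] == 0:
                n_degenerate += 1
                continue
            d = (j - i) / n_int
            by_sep.setdefault(d, []).append((both[i, j] / expected[i, j], n_arms))
    if not by_sep:
        raise DegenerateFitError("every segment pair is degenerate (no occupied segments)")
    seps = sorted(by_sep)
    coc, npairs = [], []
    for d in seps:
        vals = np.array([v for v, _ in by_sep[d]])
        w = np.array([w for _, w in by_sep[d]], dtype=float)
        coc.append(float(np.average(vals, weights=w) if weighted else vals.mean()))
        npairs.append(len(vals))
    return CoCCurve(
        separations=tuple(seps),
        coc=tuple(coc),
        n_pairs=tuple(npairs),
        n_intervals=n_int,
        n_arms=n_arms,
        n_degenerate_pairs=n_degenerate,
    )


def coc_curve(
    dataset: Dataset,
    temperature: Optional[float] = None,
    n_intervals: int = 20,
    weighted: bool = True,
) -> CoCCurve:
    """Coefficient-of-coincidence curve for a condition's chromosome arms."""
    return coc_from_occupancy(arm_occupancy(dataset, temperature, n_intervals), weighted=weighted)


def interference_distance(curve: CoCCurve, threshold: float = 1.0):
    """Separation at which the CoC curve first reaches the threshold.

    Linear interpolation between adjacent curve points locates the first
    upward crossing; if the curve starts at or above the threshold the
    smallest separation is returned.  Returns ``(distance, reached)``;
    when the curve never reaches the threshold, ``reached`` is False and
    the maximum separation is returned.
    """
    if len(curve.separations) < 2:
        raise MeiocoError("interference distance needs a curve with >= 2 separations")
    seps = curve.separations
    vals = curve.coc
    if vals[0] >= threshold:
        return float(seps[0]), True
    for k in range(1, len(vals)):
        if vals[k] >= threshold:
            x0, x1, y0, y1 = seps[k - 1], seps[k], vals[k - 1], vals[k]
            return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)), True
    return float(seps[-1]), False
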
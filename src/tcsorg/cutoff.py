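"""Data-driven estimation of the functional-linkage distance cut-off.

Ranking inter-gene distances in ascending order and plotting rank against
distance separates two regimes: a steep pile of tightly spaced (often
overlapping) gene pairs near 0 bp, and a pseudo-linear regime at larger
distances where TCS genes land near each other only by chance.  A straight
line fitted to the large-distance tail models the random regime; the knee —
the largest distance at which the empirical curve departs from that line by
more than a tolerance — estimates the cut-off separating functional
juxtaposition from chance.  Extrapolating the fitted line back below the
cut-off also yields the expected false-positive rate of the cut-off.

Negative distances (overlapping genes) are real intervals and participate in
the rank curve, but the random-regime fit uses non-negative distances only:
overlaps are definitionally non-random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TCSDataError
from .linkage import partition_dataset

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object


@dataclass(frozen=True)
class RankCurve:
    """Ascending inter-gene distances for one orientation class."""

    distances: tuple
    orientation: str = "all"

    @property
    def n(self) -> int:
        return len(self.distances)

    @property
    def ranks(self):
        return np.arange(1, self.n + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_bp": list(self.distances),
                "rank": self.ranks,
                "orientation": self.orientation,
            }
        )


@dataclass(frozen=True)
class RegimeFit:
    """Least-squares line rank = slope * distance + intercept for the tail."""

    slope: float
    intercept: float
    r_value: float
    n_tail: int

    def predict(self, distance):
        return self.slope * np.asarray(distance, dtype=float) + self.intercept


@dataclass
class CutoffReport:
    """Bundled result of the cut-off analysis for one dataset."""

    estimated_cutoff_bp: int
    knee_found: bool
    slope: float
    intercept: float
    false_positive_rate: float
    fp_basis: str
    n_intervals: int
    orphan_decay: list = field(default_factory=list)  # [(cutoff_bp, n_orphans)]


def rank_curve(intervals, orientation: str = "all") -> RankCurve:
    """Build the ascending rank curve for cis, trans or all intervals."""
    if orientation not in {"cis", "trans", "all"}:
        raise ValueError(f"orientation must be cis|trans|all, got {orientation!r}")
    dist = [
        iv.distance_bp
        for iv in intervals
        if orientation == "all" or iv.orientation == orientation
    ]
    if not dist:
        raise TCSDataError(f"no {orientation} intervals to rank")
    return RankCurve(distances=tuple(sorted(dist)), orientation=orientation)


def fit_random_regime(curve: RankCurve, tail_fraction: float = 0.5) -> RegimeFit:
    """Fit the random (linear) regime on the largest-distance tail.

    Ranks are taken within the full curve; the fit pool is restricted to
    non-negative distances and, of those, the largest ``tail_fraction`` by
    count.  Requires >= 10 tail points with non-zero distance spread.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    d = np.asarray(curve.distances, dtype=float)
    r = curve.ranks.astype(float)
    nonneg = d >= 0
    d_pool, r_pool = d[nonneg], r[nonneg]
    k = max(int(round(tail_fraction * len(d_pool))), 0)
    if k < 10:
        raise TCSDataError(f"random-regime tail has {k} points; need >= 10")
    d_tail, r_tail = d_pool[-k:], r_pool[-k:]
    if np.ptp(d_tail) == 0:
        raise TCSDataError("degenerate tail: zero distance spread")
    res = stats.linregress(d_tail, r_tail)
    return RegimeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        n_tail=int(k),
    )


def estimate_cutoff(
    curve: RankCurve, fit: RegimeFit, departure_tolerance: float = 0.05
):
    """Locate the knee where the curve departs from the random-regime line.

    Scanning distinct distances from large to small, the estimate is the
    largest distance whose empirical rank deviates from the line's
    prediction by more than ``departure_tolerance * n`` intervals.  Returns
    ``(cutoff_bp, knee_found)``; with no departure (pure background) the
    estimate is 0 and ``knee_found`` is False.  Estimates are clamped at 0:
    a knee inside the overlap region means "only abutting genes pair".
    """
    d = np.asarray(curve.distances, dtype=float)
    n = curve.n
    # max rank per distinct distance = empirical count of intervals <= d
    dist_unique = np.unique(d)
    counts = np.searchsorted(d, dist_unique, side="right")
    deviation = np.abs(counts - fit.predict(dist_unique))
    threshold = departure_tolerance * n
    hits = np.nonzero(deviation > threshold)[0]
    if hits.size == 0:
        return 0, False
    return max(0, int(round(dist_unique[hits[-1]]))), True


def false_positive_rate(
    curve: RankCurve, fit: RegimeFit, cutoff_bp: int, basis_n: int = None
) -> float:
    """Expected fraction of random pairings admitted by a cut-off.

    The fitted line predicts ``slope * cutoff_bp`` random-regime intervals
    with distance in [0, cutoff]; the rate divides this by ``basis_n``
    (default: the total interval count of the curve).  Clamped to [0, 1].
    """
    denom = basis_n if basis_n is not None else curve.n
    if denom <= 0:
        raise TCSDataError("false_positive_rate: non-positive denominator")
    predicted = max(0.0, fit.slope * cutoff_bp)
    return float(min(1.0, predicted / denom))


def orphan_decay(genes, cutoffs) -> pd.DataFrame:
    """Orphan (size-1 focus) counts across a grid of candidate cut-offs.

    Monotone non-increasing in the cut-off by construction.
    """
    rows = []
    for c in cutoffs:
        foci = partition_dataset(genes, cutoff_bp=int(c), mode="foci")
        rows.append(
            {"cutoff_bp": int(c), "n_orphans": sum(1 for f in foci if f.size == 1)}
        )
    return pd.DataFrame(rows)


def cutoff_report(
    intervals,
    genes=None,
    orientation: str = "all",
    tail_fraction: float = 0.5,
    departure_tolerance: float = 0.05,
    fp_basis: str = "intervals",
    decay_cutoffs=None,
) -> CutoffReport:
    """Run the full cut-off analysis and bundle the results."""
    curve = rank_curve(intervals, orientation)
    fit = fit_random_regime(curve, tail_fraction)
    cutoff_bp, found = estimate_cutoff(curve, fit, departure_tolerance)
    rate = false_positive_rate(curve, fit, cutoff_bp)
    decay = []
    if genes is not None:
        grid = decay_cutoffs if decay_cutoffs is not None else [0, 50, 100, 150, 200, 300, 400, 600, 1000]
        decay = list(map(tuple, orphan_decay(genes, grid).itertuples(index=False)))
    return CutoffReport(
        estimated_cutoff_bp=cutoff_bp,
        knee_found=found,
        slope=fit.slope,
        intercept=fit.intercept,
        false_positive_rate=rate,
        fp_basis=fp_basis,
        n_intervals=curve.n,
        orphan_decay=decay,
    )


class CutoffKneeEstimator(BaseEstimator):
    """Sklearn-style estimator for the linkage cut-off knee.

    ``fit(distances)`` takes raw inter-gene distances (1-D array-like) or a
    list of Interval objects and exposes ``cutoff_bp_``, ``knee_found_``,
    ``slope_``, ``intercept_``.  ``score_false_positive(cutoff)`` reports the
    extrapolated false-positive fraction at any candidate cut-off.
    """

    def __init__(self, tail_fraction: float = 0.5, departure_tolerance: float = 0.05):
        self.tail_fraction = tail_fraction
        self.departure_tolerance = departure_tolerance

    def fit(self, X, y=None):
        if len(X) and hasattr(X[0], "distance_bp"):
            dist = sorted(iv.distance_bp for iv in X)
        else:
            dist = sorted(int(x) for x in np.asarray(X).ravel())
        self._curve_ = RankCurve(distances=tuple(dist))
        self._fit_ = fit_random_regime(self._curve_, self.tail_fraction)
        self.cutoff_bp_, self.knee_found_ = estimate_cutoff(
            self._curve_, self._fit_, self.departure_tolerance
        )
        self.slope_ = self._fit_.slope
        self.intercept_ = self._fit_.intercept
        return self

    def score_false_positive(self, cutoff_bp: int = None) -> float:
        c = self.cutoff_bp_ if cutoff_bp is None else cutoff_bp
        return false_positive_rate(self._curve_, self._fit_, c)
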
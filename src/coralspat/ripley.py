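"""Transformed Ripley's K (L-function), envelopes, and difference functions.

The second-order statistic used throughout is the square-root transform of
Ripley's K with weighted pair sums,

    L(d) = sqrt( A * S(d) / (pi * W) ),

where S(d) = sum over ordered pairs i != j of w_i * w_j * 1[dist(i,j) <= d]
and W = sum over ordered pairs of w_i * w_j.  With unit weights this
reduces to the familiar L(d) = sqrt(A * #pairs(d) / (pi * n (n-1))), for
which complete spatial randomness gives E[L(d)] ~= d.  Weighted mode sets
w to per-transect colony counts, turning the transect pattern into a
colony-level (marked) pattern.

No edge correction is applied by default; an optional toroidal-shift
correction is available for sensitivity analysis on rectangular regions.

Envelopes are pointwise min/max over 99 simulations, read as a 99%
(p = 0.01) simulation envelope.  Two nulls are used:

* complete spatial randomness (``csr_envelope``): locations redrawn
  uniformly over the study region, weights carried along in random order;
* random labelling (``difference_function``): locations fixed, the
  disease labels reassigned at random within the host population —
  sampling positive transects without replacement at transect level, or
  redistributing the diseased-colony total hypergeometrically over
  colonies at colony level.

The difference function D(d) = L_disease(d) - L_population(d) asks whether
the disease pattern is more or less aggregated than the host population
that carries it; D = 0 under random labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon

from .synth import sample_points_in_region

__all__ = [
    "DistanceBins",
    "LFunctionResult",
    "DifferenceResult",
    "l_function",
    "csr_envelope",
    "l_with_envelope",
    "difference_function",
    "cross_resolution_test",
    "CLUSTERED_SIG",
    "CLUSTERED_NS",
    "RANDOM",
    "DISPERSED_NS",
    "DISPERSED_SIG",
]

CLUSTERED_SIG = "clustered_significant"
CLUSTERED_NS = "clustered_ns"
RANDOM = "random"
DISPERSED_NS = "dispersed_ns"
DISPERSED_SIG = "dispersed_significant"


@dataclass(frozen=True)
class DistanceBins:
    """Evaluation distances: ``step``, ``2*step``, ..., ``d_max`` metres."""

    d_max: float = 2500.0
    step: float = 50.0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        ratio = self.d_max / self.step
        if self.d_max <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("d_max must be a positive multiple of step")

    @property
    def edges(self) -> np.ndarray:
        return self.step * np.arange(1, round(self.d_max / self.step) + 1)

    @property
    def n_bins(self) -> int:
        return round(self.d_max / self.step)


def _classify(values, expected, lo, hi, atol: float = 0.0) -> np.ndarray:
    out = np.empty(len(values), dtype=object)
    for i, (v, e, a, b) in enumerate(zip(values, expected, lo, hi)):
        if v > b:
            out[i] = CLUSTERED_SIG
        elif v < a:
            out[i] = DISPERSED_SIG
        elif v > e + atol:
            out[i] = CLUSTERED_NS
        elif v < e - atol:
            out[i] = DISPERSED_NS
        else:
            out[i] = RANDOM
    return out


@dataclass
class LFunctionResult:
    """Observed L(d) with its null envelope and per-bin classification."""

    bins: DistanceBins
    l_observed: np.ndarray
    expected: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    n_sims: int
    weighting: Literal["none", "colony"] = "none"
    significance_class: np.ndarray = field(default=None)

    def __post_init__(self):
        if np.any(self.envelope_low > self.envelope_high):
            raise ValueError("envelope_low exceeds envelope_high")
        if self.significance_class is None:
            self.significance_class = _classify(
                self.l_observed, self.expected, self.envelope_low, self.envelope_high
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.bins.edges,
                "l_observed": self.l_observed,
                "expected": self.expected,
                "envelope_low": self.envelope_low,
                "envelope_high": self.envelope_high,
                "class": self.significance_class,
            }
        )


@dataclass
class DifferenceResult:
    """D(d) = L_disease - L_population with a random-labelling envelope."""

    bins: DistanceBins
    d_values: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    n_sims: int
    level: Literal["transect", "colony"] = "transect"
    significance_class: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.significance_class is None:
            self.significance_class = _classify(
                self.d_values,
                np.zeros_like(self.d_values),
                self.envelope_low,
                self.envelope_high,
                atol=1e-9,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.bins.edges,
                "d_value": self.d_values,
                "expected": 0.0,
                "envelope_low": self.envelope_low,
                "envelope_high": self.envelope_high,
                "class": self.significance_class,
            }
        )


# ----------------------------------------------------------------------
# core estimator
# ----------------------------------------------------------------------
def l_function(
    points: np.ndarray,
    bins: DistanceBins,
    area: float,
    weights: np.ndarray | None = None,
    torus: tuple[float, float] | None = None,
) -> np.ndarray:
    """Weighted transformed-K estimator evaluated at each bin edge.

    Pairs at exactly a bin edge count toward that bin (closed upper
    bound).  ``torus=(width, height)`` applies toroidal distances on a
    rectangle of that size, an optional edge-effect sensitivity check.

    Parameters
    ----------
    points : (n, 2) planar coordinates, metres.
    weights : optional nonnegative per-point weights; omitted = unit.
    area : study-region area A in m^2.
    """
    points = np.asarray(points, dtype=float)
    if area <= 0:
        raise ValueError("area must be positive")
    n = len(points)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    active = w > 0
    if active.sum() < 2:
        raise ValueError("need at least 2 points with positive weight")
    pts, w = points[active], w[active]

    if torus is not None:
        dx = np.abs(pts[:, 0, None] - pts[None, :, 0])
        dy = np.abs(pts[:, 1, None] - pts[None, :, 1])
        dx = np.minimum(dx, torus[0] - dx)
        dy = np.minimum(dy, torus[1] - dy)
        iu = np.triu_indices(len(pts), k=1)
        dists = np.hypot(dx[iu], dy[iu])
    else:
        dists = pdist(pts)
    # condensed upper-triangle pair weights, in pdist order
    pair_w = (np.outer(w, w))[np.triu_indices(len(pts), k=1)]
    order = np.argsort(dists, kind="stable")
    cum = np.concatenate([[0.0], np.cumsum(pair_w[order])])
    idx = np.searchsorted(dists[order], bins.edges, side="right")
    s = 2.0 * cum[idx]  # ordered pairs = 2 * unordered
    total = w.sum() ** 2 - (w**2).sum()
    return np.sqrt(area * s / (np.pi * total))


# ----------------------------------------------------------------------
# envelopes
# ----------------------------------------------------------------------
def csr_envelope(
    region: Polygon,
    n_points: int,
    bins: DistanceBins,
    area: float | None = None,
    weights: np.ndarray | None = None,
    n_sims: int = 99,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise min/max L envelope under complete spatial randomness.

    Each simulation redraws ``n_points`` uniformly over ``region``; any
    weights ride along in a random permutation so the marginal weight
    distribution is preserved.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    area = region.area if area is None else area
    rng = np.random.default_rng(seed)
    lo = np.full(bins.n_bins, np.inf)
    hi = np.full(bins.n_bins, -np.inf)
    for _ in range(n_sims):
        pts = sample_points_in_region(region, n_points, rng)
        w = None if weights is None else rng.permutation(weights)
        curve = l_function(pts, bins, area, weights=w)
        np.minimum(lo, curve, out=lo)
        np.maximum(hi, curve, out=hi)
    return lo, hi


def l_with_envelope(
    points: np.ndarray,
    region: Polygon,
    bins: DistanceBins,
    weights: np.ndarray | None = None,
    area: float | None = None,
    n_sims: int = 99,
    seed=None,
) -> LFunctionResult:
    """Observed L plus a CSR envelope, classified per bin."""
    area = region.area if area is None else area
    obs = l_function(points, bins, area, weights=weights)
    lo, hi = csr_envelope(
        region, len(points), bins, area=area, weights=weights, n_sims=n_sims, seed=seed
    )
    return LFunctionResult(
        bins=bins,
        l_observed=obs,
        expected=bins.edges.astype(float),
        envelope_low=lo,
        envelope_high=hi,
        n_sims=n_sims,
        weighting="none" if weights is None else "colony",
    )


# ----------------------------------------------------------------------
# disease-vs-population difference function
# ----------------------------------------------------------------------
def difference_function(
    points: np.ndarray,
    population_weights: np.ndarray,
    disease_weights: np.ndarray,
    bins: DistanceBins,
    area: float,
    level: Literal["transect", "colony"] = "transect",
    n_sims: int = 99,
    seed=None,
) -> DifferenceResult:
    """D(d) = L_disease - L_population with a random-labelling envelope.

    The disease pattern must live on the population's locations with
    ``disease_weights <= population_weights`` pointwise.  At transect
    level the null resamples which transects are positive (without
    replacement); at colony level it redistributes the diseased-colony
    total over the population's colonies (multivariate hypergeometric),
    holding every location fixed.
    """
    points = np.asarray(points, dtype=float)
    pop_w = np.asarray(population_weights, dtype=float)
    dis_w = np.asarray(disease_weights, dtype=float)
    if dis_w.shape != pop_w.shape or np.any(dis_w > pop_w) or np.any(dis_w < 0):
        raise ValueError("disease pattern is not a subset of the population")
    l_pop = l_function(points, bins, area, weights=pop_w)
    l_dis = l_function(points, bins, area, weights=dis_w)
    d_obs = l_dis - l_pop

    rng = np.random.default_rng(seed)
    n = len(points)
    lo = np.full(bins.n_bins, np.inf)
    hi = np.full(bins.n_bins, -np.inf)
    if level == "transect":
        m = int((dis_w > 0).sum())
        for _ in range(n_sims):
            lab = np.zeros(n)
            lab[rng.choice(n, size=m, replace=False)] = 1.0
            d_sim = l_function(points, bins, area, weights=lab) - l_pop
            np.minimum(lo, d_sim, out=lo)
            np.maximum(hi, d_sim, out=hi)
    elif level == "colony":
        pop_counts = pop_w.astype(int)
        total = int(round(dis_w.sum()))
        for _ in range(n_sims):
            lab = rng.multivariate_hypergeometric(pop_counts, total).astype(float)
            d_sim = l_function(points, bins, area, weights=lab) - l_pop
            np.minimum(lo, d_sim, out=lo)
            np.maximum(hi, d_sim, out=hi)
    else:
        raise ValueError(f"unknown level {level!r}")
    return DifferenceResult(
        bins=bins, d_values=d_obs, envelope_low=lo, envelope_high=hi,
        n_sims=n_sims, level=level,
    )


# ----------------------------------------------------------------------
# cross-resolution hypothesis tests
# ----------------------------------------------------------------------
def cross_resolution_test(
    weighted: LFunctionResult, unweighted: LFunctionResult
) -> pd.DataFrame:
    """Per-bin decisions comparing the two analysis resolutions.

    Two null hypotheses on the same underlying point set:

    * colony-weighting does not change the clustering verdict — rejected
      at distance d iff the colony-weighted observed L falls outside the
      transect-level (unweighted) envelope;
    * and the converse — rejected at d iff the unweighted observed L
      falls outside the colony-weighted envelope.

    Returns a table with one row per distance and boolean ``reject``
    columns for each direction.
    """
    if weighted.bins != unweighted.bins:
        raise ValueError("results were computed on different distance bins")
    rej_w_in_u = (weighted.l_observed > unweighted.envelope_high) | (
        weighted.l_observed < unweighted.envelope_low
    )
    rej_u_in_w = (unweighted.l_observed > weighted.envelope_high) | (
        unweighted.l_observed < weighted.envelope_low
    )
    return pd.DataFrame(
        {
            "distance": weighted.bins.edges,
            "reject_weighted_vs_unweighted_envelope": rej_w_in_u,
            "reject_unweighted_vs_weighted_envelope": rej_u_in_w,
        }
    )


def plot_l(result: LFunctionResult | DifferenceResult, ax=None):
    """Plot an L or difference curve with its envelope (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = result.to_frame()
    ycol = "l_observed" if "l_observed" in frame else "d_value"
    ax.fill_between(
        frame["distance"], frame["envelope_low"], frame["envelope_high"],
        alpha=0.25, color="grey", label="envelope",
    )
    ax.plot(frame["distance"], frame[ycol], color="black", label="observed")
    ax.plot(frame["distance"], frame["expected"], "--", color="red", label="expected")
    ax.set_xlabel("distance (m)")
    ax.set_ylabel("L(d) (m)" if ycol == "l_observed" else "D(d) (m)")
    ax.legend()
    return ax
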
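"""Synthetic coral-disease surveys with known ground truth.

The generator emulates the statistical structure of an outbreak survey in
which a few hundred transects are scattered over a reef shelf several
kilometres across, each transect holding an overdispersed number of host
colonies (mean ~6.65, SD ~5.99, range 1-40) of which ~2.8% are diseased.
Three disease-placement scenarios are provided:

* ``random`` — every colony independently diseased with probability p;
  this is exactly the null model of the Monte Carlo hotspot test.
* ``focal``  — colonies near one of a handful of focus points carry an
  elevated risk (``base_p * relative_risk`` within ``radius``); emulates a
  contagious outbreak spreading from point sources.
* ``ubiquitous`` — random with a low p; emulates a region-wide chronic
  stressor.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon, box

from .survey import SurveyDataset, TransectRecord, ValidationError

__all__ = [
    "UniformLocations",
    "ClusteredLocations",
    "RandomDisease",
    "FocalDisease",
    "UbiquitousDisease",
    "HabitatPatches",
    "ScenarioConfig",
    "GroundTruth",
    "default_region",
    "sample_points_in_region",
    "generate_transect_locations",
    "assign_colony_counts",
    "assign_disease",
    "generate_survey",
    "calibrate_counts_to_total",
    "reference_survey",
]


def default_region(width: float = 7300.0, height: float = 3800.0,
                   island_hole: bool = False) -> Polygon:
    """Default study region: a rectangle matching the analysis-grid extent.

    ``island_hole=True`` punches an elliptical island out of the centre,
    mimicking a reef shelf wrapped around an island.
    """
    rect = box(0.0, 0.0, width, height)
    if island_hole:
        hole = Point(width / 2, height / 2).buffer(1.0)
        hole = shapely.affinity.scale(hole, width / 6, height / 6)
        rect = rect.difference(hole)
    return rect


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class UniformLocations:
    """Transects placed uniformly at random over the region."""


@dataclass(frozen=True)
class ClusteredLocations:
    """Thomas-type parent/offspring placement.

    Parents are uniform over the region; each transect picks a parent at
    random and is displaced by an isotropic Gaussian of sd
    ``offspring_sd`` metres, redrawn until inside the region.  The parent
    count is ``round(n_transects / offspring_per_parent)`` unless
    ``parent_intensity`` (parents per km^2) is given.
    """

    offspring_per_parent: float = 15.0
    offspring_sd: float = 150.0
    parent_intensity: float | None = None


@dataclass(frozen=True)
class RandomDisease:
    """Each colony independently diseased with probability ``p``."""

    p: float = 0.0277


@dataclass(frozen=True)
class UbiquitousDisease:
    """Region-wide low-level risk: random with a low probability."""

    p_low: float = 0.0277


@dataclass(frozen=True)
class FocalDisease:
    """Elevated colony risk within ``radius`` m of any focus.

    Foci are anchored at randomly chosen transect locations (an outbreak
    focus with no hosts in range is not a realizable point source), or
    fixed explicitly via ``foci``.  ``base_p`` defaults to 0.016 so that
    with ``relative_risk=10``, ``radius=300`` m and 8 foci over the
    default region the expected overall colony prevalence is close to
    the ~2.77% outbreak level the generator targets.
    """

    n_foci: int = 8
    base_p: float = 0.016
    relative_risk: float = 10.0
    radius: float = 300.0
    foci: tuple[tuple[float, float], ...] | None = None


@dataclass(frozen=True)
class HabitatPatches:
    """Spatial heterogeneity in colony density.

    Inside ``n_patches`` uniformly placed discs of radius ``radius`` m the
    colony-count mean is multiplied by ``multiplier``; models patchy
    habitat quality.  Off by default.
    """

    n_patches: int = 4
    radius: float = 600.0
    multiplier: float = 3.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic survey."""

    n_transects: int = 375
    region: Polygon = field(default_factory=default_region)
    # clustered by default: real transect patterns over reef hard-bottom are
    # habitat-confined and significantly aggregated at all survey scales
    location_process: UniformLocations | ClusteredLocations = field(
        default_factory=ClusteredLocations
    )
    colony_mean: float = 6.65
    colony_dispersion: float = 1.513  # NB size k; mu + mu^2/k gives SD ~5.99
    colony_max: int = 40
    disease_model: RandomDisease | FocalDisease | UbiquitousDisease = field(
        default_factory=RandomDisease
    )
    habitat: HabitatPatches | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_transects < 1:
            raise ValueError("n_transects must be >= 1")
        if not self.colony_mean > 1:
            raise ValueError("colony_mean must exceed 1 (zero-truncated counts)")
        if self.colony_dispersion <= 0:
            raise ValueError("colony_dispersion must be positive")
        if self.colony_max < 1:
            raise ValueError("colony_max must be >= 1")
        dm = self.disease_model
        probs = []
        if isinstance(dm, RandomDisease):
            probs = [dm.p]
        elif isinstance(dm, UbiquitousDisease):
            probs = [dm.p_low]
        elif isinstance(dm, FocalDisease):
            probs = [dm.base_p]
            if dm.relative_risk < 1:
                raise ValueError("relative_risk must be >= 1")
            if min(dm.base_p * dm.relative_risk, 1.0) < 0:
                raise ValueError("invalid focal risk")
        for p in probs:
            if not (0 < p < 1):
                raise ValueError(f"disease probability {p} outside (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Side-channel truth for testing recovery of planted structure."""

    foci: np.ndarray | None  # (k, 2) focus coordinates, or None
    colony_risk: np.ndarray  # per-transect colony disease probability
    patch_centers: np.ndarray | None = None


# ----------------------------------------------------------------------
# point placement
# ----------------------------------------------------------------------
def sample_points_in_region(region: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly over ``region`` by rejection from its bbox."""
    if region.area <= 0:
        raise ValueError("region is degenerate (zero area)")
    x0, y0, x1, y1 = region.bounds
    out = np.empty((0, 2))
    # bbox acceptance rate bounds the loop count; the default rectangular
    # region accepts everything on the first pass
    while len(out) < n:
        m = max(64, int(1.5 * (n - len(out)) * (x1 - x0) * (y1 - y0) / region.area))
        cand = np.column_stack(
            [rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)]
        )
        keep = shapely.intersects_xy(region, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def generate_transect_locations(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Place ``n_transects`` points per the configured location process."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    region, n = config.region, config.n_transects
    if region.area <= 0:
        raise ValueError("region is degenerate")
    proc = config.location_process
    if isinstance(proc, UniformLocations):
        return sample_points_in_region(region, n, rng)
    if proc.parent_intensity is not None:
        n_parents = max(1, round(proc.parent_intensity * region.area / 1e6))
    else:
        n_parents = max(1, round(n / proc.offspring_per_parent))
    parents = sample_points_in_region(region, n_parents, rng)
    assignment = rng.integers(0, n_parents, n)
    pts = parents[assignment] + rng.normal(0.0, proc.offspring_sd, (n, 2))
    # redraw displaced points that fell outside the region
    while True:
        bad = ~shapely.intersects_xy(region, pts[:, 0], pts[:, 1])
        if not bad.any():
            break
        k = int(bad.sum())
        pts[bad] = parents[assignment[bad]] + rng.normal(0.0, proc.offspring_sd, (k, 2))
    return pts


# ----------------------------------------------------------------------
# colony counts
# ----------------------------------------------------------------------
def _ztnb_capped(
    rng: np.random.Generator,
    mean: np.ndarray,
    dispersion: float,
    cap: int,
    size: int,
) -> np.ndarray:
    """Zero-truncated, capped negative binomial draws.

    ``mean``/``dispersion`` parameterise the untruncated NB (mean mu,
    size k, variance mu + mu^2/k); zeros and values above ``cap`` are
    redrawn.  ``dispersion=inf`` gives the zero-truncated Poisson limit.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    counts = np.zeros(size, dtype=int)
    todo = np.ones(size, dtype=bool)
    for _ in range(10_000):
        m = int(todo.sum())
        if m == 0:
            return counts
        mu = mean[todo]
        if math.isinf(dispersion):
            draw = rng.poisson(mu, m)
        else:
            p = dispersion / (dispersion + mu)
            draw = rng.negative_binomial(dispersion, p, m)
        counts[todo] = draw
        todo[todo] = (draw < 1) | (draw > cap)
    raise ValueError(
        "infeasible colony count configuration: rejection sampling did not converge"
    )


def assign_colony_counts(
    points: np.ndarray, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw per-transect colony counts; returns (counts, patch_centers)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(points)
    mean = np.full(n, config.colony_mean)
    centers = None
    if config.habitat is not None:
        h = config.habitat
        centers = sample_points_in_region(config.region, h.n_patches, rng)
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= h.radius**2).any(axis=1)
        mean = np.where(inside, np.minimum(config.colony_mean * h.multiplier,
                                           0.9 * config.colony_max), mean)
    counts = _ztnb_capped(rng, mean, config.colony_dispersion, config.colony_max, n)
    return counts, centers


# ----------------------------------------------------------------------
# disease assignment
# ----------------------------------------------------------------------
def assign_disease(
    points: np.ndarray,
    counts: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Assign per-transect diseased counts under the configured scenario.

    Colonies are labelled independently, so per-transect diseased counts
    are Binomial(n_colonies, p_i) with p_i the colony-level risk at the
    transect's location.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    dm = config.disease_model
    n = len(points)
    foci = None
    if isinstance(dm, RandomDisease):
        risk = np.full(n, dm.p)
    elif isinstance(dm, UbiquitousDisease):
        risk = np.full(n, dm.p_low)
    else:
        if dm.foci is not None:
            foci = np.asarray(dm.foci, dtype=float).reshape(-1, 2)
        else:
            # anchor foci on hosts: sample among the transect locations
            idx = rng.choice(n, size=min(dm.n_foci, n), replace=False)
            foci = points[idx].copy()
        d2 = ((points[:, None, :] - foci[None, :, :]) ** 2).sum(axis=2)
        near = (d2 <= dm.radius**2).any(axis=1)
        risk = np.where(near, min(dm.base_p * dm.relative_risk, 1.0), dm.base_p)
    diseased = rng.binomial(counts, risk)
    return diseased, GroundTruth(foci=foci, colony_risk=risk)


# ----------------------------------------------------------------------
# whole surveys
# ----------------------------------------------------------------------
def generate_survey(config: ScenarioConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Generate a full synthetic survey; pure function of ``config``.

    The master seed fans out to per-stage child streams (locations,
    counts, disease) via ``SeedSequence.spawn`` so each stage is
    independently reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_loc, rng_cnt, rng_dis = (np.random.default_rng(s) for s in ss.spawn(3))
    pts = generate_transect_locations(config, rng_loc)
    counts, centers = assign_colony_counts(pts, config, rng_cnt)
    diseased, truth = assign_disease(pts, counts, config, rng_dis)
    records = [
        TransectRecord(
            id=f"t{i:04d}",
            x=float(pts[i, 0]),
            y=float(pts[i, 1]),
            n_colonies=int(counts[i]),
            n_diseased=int(diseased[i]),
        )
        for i in range(len(pts))
    ]
    ds = SurveyDataset.from_records(records, region=config.region, crs_note="synthetic")
    return ds, GroundTruth(foci=truth.foci, colony_risk=truth.colony_risk,
                           patch_centers=centers)


def calibrate_counts_to_total(
    counts: np.ndarray,
    total: int,
    rng: np.random.Generator,
    lo: int = 1,
    hi: int = 40,
) -> np.ndarray:
    """Nudge integer counts by +/-1 at random positions until they sum to ``total``.

    Used to build surveys matching exact published totals while keeping
    the generator's distributional shape.
    """
    counts = counts.astype(int).copy()
    if not lo * len(counts) <= total <= hi * len(counts):
        raise ValueError("target total infeasible for the given bounds")
    while counts.sum() != total:
        step = 1 if counts.sum() < total else -1
        movable = np.nonzero((counts + step >= lo) & (counts + step <= hi))[0]
        counts[rng.choice(movable)] += step
    return counts


def _adjust_spread(
    counts: np.ndarray,
    sd_target: float,
    rng: np.random.Generator,
    lo: int = 1,
    hi: int = 40,
    max_iter: int = 20_000,
) -> np.ndarray:
    """Total-preserving +/-1 transfers steering the count SD toward a target.

    Moving a unit from a low count to a high count raises the SD and vice
    versa; the total (hence the mean) is invariant.
    """
    counts = counts.astype(int).copy()
    for _ in range(max_iter):
        sd = counts.std()
        if abs(sd - sd_target) < 0.005:
            break
        if sd < sd_target:  # spread out: take from a low, give to a high
            donors = np.nonzero(counts - 1 >= lo)[0]
            takers = np.nonzero(counts + 1 <= hi)[0]
            i, j = rng.choice(donors), rng.choice(takers)
            if counts[j] >= counts[i]:
                counts[i] -= 1
                counts[j] += 1
        else:
            donors = np.nonzero(counts - 1 >= lo)[0]
            takers = np.nonzero(counts + 1 <= hi)[0]
            i, j = rng.choice(donors), rng.choice(takers)
            if counts[j] < counts[i] - 1:
                counts[i] -= 1
                counts[j] += 1
    return counts


def reference_survey(seed: int = 0) -> SurveyDataset:
    """A synthetic survey calibrated to the published outbreak totals.

    375 transects, 2,492 colonies, 69 diseased spread over 44 positive
    transects (each positive transect holding >= 1 case).  Locations are
    clustered; the disease labelling among transects is random, so only
    the marginal totals — not the spatial pattern — are fixed.
    """
    ss = np.random.SeedSequence(seed)
    cfg = ScenarioConfig(
        n_transects=375,
        location_process=ClusteredLocations(),
        seed=int(ss.generate_state(1)[0] % (2**31)),
    )
    rng = np.random.default_rng(ss.spawn(1)[0])
    pts = generate_transect_locations(cfg, rng)
    counts, _ = assign_colony_counts(pts, cfg, rng)
    counts = calibrate_counts_to_total(counts, 2492, rng, lo=1, hi=cfg.colony_max)
    counts = _adjust_spread(counts, 5.99, rng, lo=1, hi=cfg.colony_max)
    # 69 cases over 44 positive transects, each with at least one case
    positive = rng.choice(375, size=44, replace=False)
    diseased = np.zeros(375, dtype=int)
    diseased[positive] = 1
    for _ in range(69 - 44):
        room = positive[diseased[positive] < counts[positive]]
        diseased[rng.choice(room)] += 1
    records = [
        TransectRecord(
            id=f"t{i:04d}", x=float(pts[i, 0]), y=float(pts[i, 1]),
            n_colonies=int(counts[i]), n_diseased=int(diseased[i]),
        )
        for i in range(375)
    ]
    return SurveyDataset.from_records(
        records, region=cfg.region, crs_note="synthetic, totals-calibrated"
    )
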
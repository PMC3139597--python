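"""Spatially filtered prevalence surfaces with Monte Carlo hotspot tests.

A rectangular grid is laid over the study area; at every grid
intersection a circular filter of fixed radius collects the transects
within it and a local prevalence is computed as numerator/denominator —
positive transects over all transects (transect mode) or diseased
colonies over all colonies (colony mode).  Overlapping filters (radius >=
cell size) smooth the surface.

Significance is assessed by Monte Carlo: transect locations and
denominators stay fixed while disease labels are redrawn under the
global-prevalence null (each transect, or each colony, independently
diseased with the observed overall prevalence), the surface is
recomputed, and each node's p-value is the fraction of null surfaces at
least as extreme, with the (1 + count) / (1 + n_sims) correction so p is
never zero.  Contiguous significant nodes (8-connectivity) form hotspot
clusters.

The filter radius can be set from the data via the optimized bandwidth
h_opt = sigma * (2 / (3 n))^(1/4), with sigma the standard distance of
the transect locations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
from scipy import ndimage, sparse
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Polygon, box, mapping

from .projection import LocalTransverseMercator
from .survey import SurveyDataset, ValidationError, summarize

__all__ = [
    "GridSpec",
    "PrevalenceSurface",
    "Cluster",
    "ClusterSet",
    "ClusterSummary",
    "standard_distance",
    "h_opt",
    "filtered_prevalence",
    "monte_carlo_significance",
    "extract_clusters",
    "cluster_summary",
    "BUCK_ISLAND_CORNERS",
    "write_ascii_grid",
]

#: Published analysis-grid corners (NW, SE) as (lon, lat); the stated
#: southern corner's hemisphere signs are corrected to N/W.
BUCK_ISLAND_CORNERS = ((-64.648, 17.809), (-64.579, 17.775))


@dataclass(frozen=True)
class GridSpec:
    """Rectangular node lattice; nodes sit on cell corners every ``cell`` m."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    cell: float = 50.0

    def __post_init__(self):
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extent is empty")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_cols(self) -> int:
        return int(np.floor((self.x_max - self.x_min) / self.cell + 1e-9)) + 1

    @property
    def n_rows(self) -> int:
        return int(np.floor((self.y_max - self.y_min) / self.cell + 1e-9)) + 1

    @property
    def xs(self) -> np.ndarray:
        return self.x_min + self.cell * np.arange(self.n_cols)

    @property
    def ys(self) -> np.ndarray:
        return self.y_min + self.cell * np.arange(self.n_rows)

    def nodes(self) -> np.ndarray:
        """(n_rows * n_cols, 2) node coordinates, row-major from y_min up."""
        gx, gy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @classmethod
    def from_region(cls, region: Polygon, cell: float = 50.0) -> "GridSpec":
        x0, y0, x1, y1 = region.bounds
        return cls(x0, y0, x1, y1, cell)

    @classmethod
    def from_geographic_corners(
        cls,
        nw: tuple[float, float],
        se: tuple[float, float],
        projection: LocalTransverseMercator,
        cell: float = 50.0,
    ) -> "GridSpec":
        """Build a planar grid from (lon, lat) NW/SE corners."""
        x_nw, y_nw = projection.forward(*nw)
        x_se, y_se = projection.forward(*se)
        return cls(float(x_nw), float(y_se), float(x_se), float(y_nw), cell)


@dataclass
class PrevalenceSurface:
    """Smoothed prevalence and (after Monte Carlo) p-values on a node grid.

    Arrays are shaped (n_rows, n_cols); nodes where no transect falls
    within the filter are undefined and carry NaN prevalence/p-value with
    ``defined`` False.
    """

    grid: GridSpec
    radius: float
    mode: Literal["transect", "colony"]
    numerator: np.ndarray
    denominator: np.ndarray
    prevalence: np.ndarray
    defined: np.ndarray
    p_value: np.ndarray | None = None
    n_sims: int = 0
    global_p: float | None = None
    _membership: sparse.csr_matrix | None = field(default=None, repr=False)

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        if self.p_value is None:
            raise ValidationError("p-values not computed; run monte_carlo_significance")
        with np.errstate(invalid="ignore"):
            return self.defined & (self.p_value <= alpha) & (self.prevalence > 0)


# ----------------------------------------------------------------------
# bandwidth statistics
# ----------------------------------------------------------------------
def standard_distance(points: np.ndarray) -> float:
    """Root-mean-square distance of points from their spatial mean (metres)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("standard distance needs at least 2 points")
    dev = points - points.mean(axis=0)
    return float(np.sqrt((dev**2).sum() / len(points)))


def h_opt(n: int, sigma: float) -> float:
    """Optimized filter bandwidth h = sigma * (2 / (3 n))^(1/4) metres."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(sigma * (2.0 / (3.0 * n)) ** 0.25)


# ----------------------------------------------------------------------
# filtered prevalence
# ----------------------------------------------------------------------
def _membership_matrix(
    nodes: np.ndarray, points: np.ndarray, radius: float
) -> sparse.csr_matrix:
    """Sparse (n_nodes, n_points) indicator of distance <= radius (closed disc)."""
    tree = cKDTree(points)
    neighbours = tree.query_ball_point(nodes, radius)
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(v) for v in neighbours])
    indices = np.concatenate([np.asarray(v, dtype=np.int64) for v in neighbours]) \
        if indptr[-1] else np.empty(0, dtype=np.int64)
    data = np.ones(indptr[-1], dtype=np.float64)
    return sparse.csr_matrix((data, indices, indptr), shape=(len(nodes), len(points)))


def filtered_prevalence(
    dataset: SurveyDataset,
    grid: GridSpec,
    radius: float,
    mode: Literal["transect", "colony"] = "transect",
) -> PrevalenceSurface:
    """Aggregate the survey into a circular filter at every grid node.

    Transect mode: numerator = positive transects within ``radius`` of
    the node, denominator = all transects within radius.  Colony mode:
    sums of diseased and total colony counts instead.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot filter an empty survey")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if radius < grid.cell:
        warnings.warn(
            "filter radius below the cell size: filters do not overlap and the "
            "surface will not be smoothed",
            stacklevel=2,
        )
    nodes = grid.nodes()
    member = _membership_matrix(nodes, dataset.points, radius)
    if mode == "transect":
        num_w = dataset.positive_mask.astype(float)
        den_w = np.ones(len(dataset))
    elif mode == "colony":
        num_w = dataset.diseased_counts.astype(float)
        den_w = dataset.colony_counts.astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    shape = (grid.n_rows, grid.n_cols)
    num = np.asarray(member @ num_w).reshape(shape)
    den = np.asarray(member @ den_w).reshape(shape)
    defined = den > 0
    prev = np.full(shape, np.nan)
    prev[defined] = num[defined] / den[defined]
    return PrevalenceSurface(
        grid=grid, radius=radius, mode=mode, numerator=num, denominator=den,
        prevalence=prev, defined=defined, _membership=member,
    )


def monte_carlo_significance(
    surface: PrevalenceSurface,
    dataset: SurveyDataset,
    n_sims: int = 1000,
    seed=None,
    chunk: int = 250,
) -> PrevalenceSurface:
    """Attach per-node Monte Carlo p-values to a prevalence surface.

    The null keeps every transect location and denominator fixed and
    redraws disease with the observed global prevalence — per transect
    (Bernoulli) in transect mode, per colony (Binomial over each
    transect's colonies) in colony mode.  p = (1 + #{sims with local
    prevalence >= observed}) / (1 + n_sims); nodes observed at zero
    prevalence get p = 1.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    summ = summarize(dataset)
    global_p = (
        summ.prevalence_transect / 100.0
        if surface.mode == "transect"
        else summ.prevalence_colony / 100.0
    )
    member = surface._membership
    if member is None:
        member = _membership_matrix(surface.grid.nodes(), dataset.points, surface.radius)
    rng = np.random.default_rng(seed)
    obs_num = surface.numerator.ravel()
    counts = np.zeros(obs_num.shape, dtype=np.int64)
    n_tr = len(dataset)
    colonies = dataset.colony_counts
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        if surface.mode == "transect":
            labels = (rng.random((n_tr, m)) < global_p).astype(float)
        else:
            labels = rng.binomial(colonies[:, None], global_p, size=(n_tr, m)).astype(float)
        sim_num = np.asarray(member @ labels)
        # fixed denominators: comparing numerators is comparing prevalences
        counts += (sim_num >= obs_num[:, None] - 1e-12).sum(axis=1)
        done += m
    p = (1.0 + counts) / (1.0 + n_sims)
    p = p.reshape(surface.numerator.shape)
    p[~surface.defined] = np.nan
    p[surface.defined & (surface.numerator == 0)] = 1.0
    surface.p_value = p
    surface.n_sims = n_sims
    surface.global_p = global_p
    return surface


# ----------------------------------------------------------------------
# hotspot clusters
# ----------------------------------------------------------------------
@dataclass
class Cluster:
    """One contiguous block of significant grid nodes."""

    id: int
    polygon: Polygon | MultiPolygon
    area_km2: float
    node_count: int
    transect_ids: list[str]
    mean_depth: float | None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    alpha: float
    total_area_km2: float

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def union(self) -> Polygon | MultiPolygon:
        if not self.clusters:
            return Polygon()
        return shapely.unary_union([c.polygon for c in self.clusters])

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(c.polygon),
                "properties": {
                    "id": c.id,
                    "area_km2": c.area_km2,
                    "node_count": c.node_count,
                    "n_transects_inside": len(c.transect_ids),
                    "mean_depth": c.mean_depth,
                },
            }
            for c in self.clusters
        ]
        return {"type": "FeatureCollection", "features": feats}


def extract_clusters(
    surface: PrevalenceSurface, dataset: SurveyDataset | None = None,
    alpha: float = 0.05,
) -> ClusterSet:
    """Group significant nodes (p <= alpha, prevalence > 0) into hotspots.

    Nodes are connected with 8-connectivity; each node contributes the
    cell-sized square centred on it, and a cluster's polygon is the union
    of its squares.  Cluster ids are assigned by descending area.
    """
    mask = surface.significant_mask(alpha)
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    half = surface.grid.cell / 2.0
    xs, ys = surface.grid.xs, surface.grid.ys
    clusters = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        boxes = [
            box(xs[c] - half, ys[r] - half, xs[c] + half, ys[r] + half)
            for r, c in zip(rows, cols)
        ]
        poly = shapely.unary_union(boxes)
        area_km2 = len(rows) * surface.grid.cell**2 / 1e6
        t_ids, mean_depth = [], None
        if dataset is not None and len(dataset):
            pts = dataset.points
            inside = shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
            t_ids = [dataset.records[i].id for i in np.nonzero(inside)[0]]
            depths = dataset.depths[inside]
            depths = depths[np.isfinite(depths)]
            mean_depth = float(depths.mean()) if depths.size else None
        clusters.append(
            Cluster(id=0, polygon=poly, area_km2=area_km2,
                    node_count=len(rows), transect_ids=t_ids, mean_depth=mean_depth)
        )
    clusters.sort(key=lambda c: -c.area_km2)
    for i, c in enumerate(clusters, start=1):
        c.id = i
    return ClusterSet(
        clusters=clusters, alpha=alpha,
        total_area_km2=float(sum(c.area_km2 for c in clusters)),
    )


@dataclass(frozen=True)
class ClusterSummary:
    """How the observed disease sits relative to the extracted hotspots."""

    n_clusters: int
    total_area_km2: float
    buffer_m: float
    pct_positive_transects_inside: float
    pct_positive_transects_within_buffer: float
    pct_diseased_colonies_inside: float
    pct_diseased_colonies_within_buffer: float
    mean_depth_inside: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cluster_summary(
    clusters: ClusterSet, dataset: SurveyDataset, buffer_m: float = 100.0
) -> ClusterSummary:
    """Percentages of positive transects / diseased colonies in and near hotspots."""
    pos = dataset.positive_mask
    n_pos = int(pos.sum())
    dis = dataset.diseased_counts
    total_dis = int(dis.sum())
    if len(clusters) == 0 or n_pos == 0:
        return ClusterSummary(
            n_clusters=len(clusters), total_area_km2=clusters.total_area_km2,
            buffer_m=buffer_m,
            pct_positive_transects_inside=0.0,
            pct_positive_transects_within_buffer=0.0,
            pct_diseased_colonies_inside=0.0,
            pct_diseased_colonies_within_buffer=0.0,
            mean_depth_inside=None,
        )
    union = clusters.union
    buffered = union.buffer(buffer_m)
    pts = dataset.points
    inside = shapely.intersects_xy(union, pts[:, 0], pts[:, 1])
    near = shapely.intersects_xy(buffered, pts[:, 0], pts[:, 1])
    depths = dataset.depths[inside]
    depths = depths[np.isfinite(depths)]
    return ClusterSummary(
        n_clusters=len(clusters),
        total_area_km2=clusters.total_area_km2,
        buffer_m=buffer_m,
        pct_positive_transects_inside=100.0 * int((pos & inside).sum()) / n_pos,
        pct_positive_transects_within_buffer=100.0 * int((pos & near).sum()) / n_pos,
        pct_diseased_colonies_inside=(
            100.0 * int(dis[inside].sum()) / total_dis if total_dis else 0.0
        ),
        pct_diseased_colonies_within_buffer=(
            100.0 * int(dis[near].sum()) / total_dis if total_dis else 0.0
        ),
        mean_depth_inside=float(depths.mean()) if depths.size else None,
    )


# ----------------------------------------------------------------------
# raster export
# ----------------------------------------------------------------------
def write_ascii_grid(values: np.ndarray, grid: GridSpec, path, nodata: float = -9999.0):
    """Write a node-value array as an Esri ASCII grid (text raster).

    Rows are written north to south, per the format; NaN becomes the
    NODATA value.
    """
    arr = np.where(np.isfinite(values), values, nodata)
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.x_min - grid.cell / 2.0}",
        f"yllcorner {grid.y_min - grid.cell / 2.0}",
        f"cellsize {grid.cell}",
        f"NODATA_value {nodata}",
    ]
    for row in arr[::-1]:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
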
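"""Domain types, file I/O and descriptive summaries for transect surveys.

A survey is a set of point-referenced transects; each transect carries a
count of host colonies and a count of diseased colonies.  The same survey
supports two analysis resolutions:

* **transect level** — presence/absence of disease per transect (each
  transect has weight 1);
* **colony level** — each transect weighted by its colony counts (total
  colonies for the population pattern, diseased colonies for the disease
  pattern).

Files are delimited text (comma or tab, sniffed) with a header row, or
GeoJSON FeatureCollections of Points with the same attributes carried in
``properties``.  Geographic coordinates are projected to a planar metric
frame on load; all downstream analysis is planar, in metres.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box, mapping, shape

from .projection import LocalTransverseMercator, project_coordinates


class SchemaError(ValueError):
    """A required input column could not be resolved."""


class ValidationError(ValueError):
    """A record or dataset violates a survey invariant."""


@dataclass(frozen=True)
class TransectRecord:
    """One surveyed transect.

    Attributes
    ----------
    id : str
        Opaque identifier.
    x, y : float
        Planar coordinates in metres.
    n_colonies : int
        Host colonies on the transect (>= 0).
    n_diseased : int
        Diseased colonies on the transect (0 <= n_diseased <= n_colonies).
    depth : float or None
        Transect depth in metres, optional.
    """

    id: str
    x: float
    y: float
    n_colonies: int
    n_diseased: int
    depth: float | None = None

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"record {self.id!r}: non-finite coordinates")
        if self.n_colonies < 0 or self.n_diseased < 0:
            raise ValidationError(f"record {self.id!r}: negative count")
        if self.n_diseased > self.n_colonies:
            raise ValidationError(
                f"record {self.id!r}: n_diseased ({self.n_diseased}) exceeds "
                f"n_colonies ({self.n_colonies})"
            )

    @property
    def positive(self) -> bool:
        return self.n_diseased > 0


@dataclass
class SurveyDataset:
    """Ordered transect records plus study-region geometry.

    ``region`` is a planar polygon in metres whose area ``region_area`` is
    the A that normalises every K/L statistic; it is therefore validated
    to match the geometry within 0.1%.
    """

    records: list[TransectRecord]
    region: Polygon
    region_area: float | None = None
    crs_note: str = ""

    def __post_init__(self):
        if self.region_area is None:
            self.region_area = self.region.area
        if self.region_area <= 0:
            raise ValidationError("region_area must be positive")
        if abs(self.region_area - self.region.area) > 1e-3 * self.region.area:
            raise ValidationError(
                f"region_area {self.region_area} disagrees with geometry "
                f"area {self.region.area} by more than 0.1%"
            )

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) planar coordinates in record order."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float).reshape(-1, 2)

    @property
    def colony_counts(self) -> np.ndarray:
        return np.array([r.n_colonies for r in self.records], dtype=int)

    @property
    def diseased_counts(self) -> np.ndarray:
        return np.array([r.n_diseased for r in self.records], dtype=int)

    @property
    def positive_mask(self) -> np.ndarray:
        return self.diseased_counts > 0

    @property
    def depths(self) -> np.ndarray:
        """Depths with NaN for missing values."""
        return np.array(
            [np.nan if r.depth is None else r.depth for r in self.records], dtype=float
        )

    def validate_containment(self, tolerance: float = 0.0) -> None:
        """Check every record lies in (or within ``tolerance`` m of) the region."""
        if not self.records:
            return
        geom = self.region if tolerance == 0 else self.region.buffer(tolerance)
        pts = self.points
        ok = shapely.intersects_xy(geom, pts[:, 0], pts[:, 1])
        if not np.all(ok):
            bad = [self.records[i].id for i in np.nonzero(~ok)[0][:5]]
            raise ValidationError(
                f"{int((~ok).sum())} record(s) outside the study region "
                f"(first: {bad})"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[TransectRecord],
        region: Polygon | None = None,
        crs_note: str = "",
    ) -> "SurveyDataset":
        records = list(records)
        if region is None:
            if records:
                xs = [r.x for r in records]
                ys = [r.y for r in records]
                region = box(min(xs), min(ys), max(xs), max(ys))
                if region.area == 0:  # degenerate: collinear points
                    region = box(min(xs) - 1, min(ys) - 1, max(xs) + 1, max(ys) + 1)
            else:
                region = box(0, 0, 1, 1)
        return cls(records=records, region=region, crs_note=crs_note)


@dataclass(frozen=True)
class SurveySummary:
    """Descriptive statistics of a survey at both resolutions."""

    n_transects: int
    n_transects_positive: int
    n_colonies: int
    n_colonies_diseased: int
    prevalence_transect: float  # percent
    prevalence_colony: float  # percent
    mean_colonies_per_transect: float
    sd_colonies_per_transect: float
    min_colonies_per_transect: int
    max_colonies_per_transect: int
    mean_diseased_per_positive_transect: float
    sd_diseased_per_positive_transect: float
    min_diseased_per_positive_transect: int
    max_diseased_per_positive_transect: int
    mean_healthy_per_transect: float
    mean_depth: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.mean_depth is None:
            d.pop("mean_depth")
        return d

    def formatted(self) -> dict:
        """Presentation form: percentages and means to two decimals."""
        out = {}
        for k, v in self.to_dict().items():
            out[k] = round(v, 2) if isinstance(v, float) else v
        return out


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------
def summarize(dataset: SurveyDataset) -> SurveySummary:
    """Compute transect- and colony-level prevalence and count statistics.

    Prevalences are percentages: 100 * positives/transects and
    100 * diseased/colonies.  Standard deviations are population SDs over
    the listed transects (ddof=0), matching descriptive usage.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot summarize an empty survey")
    colonies = dataset.colony_counts
    diseased = dataset.diseased_counts
    n_colonies = int(colonies.sum())
    if n_colonies == 0:
        raise ValidationError("survey has zero colonies; prevalence undefined")
    pos = dataset.positive_mask
    n_pos = int(pos.sum())
    dis_pos = diseased[pos]
    depths = dataset.depths
    has_depth = np.isfinite(depths)
    return SurveySummary(
        n_transects=len(dataset),
        n_transects_positive=n_pos,
        n_colonies=n_colonies,
        n_colonies_diseased=int(diseased.sum()),
        prevalence_transect=100.0 * n_pos / len(dataset),
        prevalence_colony=100.0 * diseased.sum() / n_colonies,
        mean_colonies_per_transect=float(colonies.mean()),
        sd_colonies_per_transect=float(colonies.std(ddof=0)),
        min_colonies_per_transect=int(colonies.min()),
        max_colonies_per_transect=int(colonies.max()),
        mean_diseased_per_positive_transect=float(dis_pos.mean()) if n_pos else 0.0,
        sd_diseased_per_positive_transect=float(dis_pos.std(ddof=0)) if n_pos else 0.0,
        min_diseased_per_positive_transect=int(dis_pos.min()) if n_pos else 0,
        max_diseased_per_positive_transect=int(dis_pos.max()) if n_pos else 0,
        mean_healthy_per_transect=float((colonies - diseased).mean()),
        mean_depth=float(depths[has_depth].mean()) if has_depth.any() else None,
    )


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------
_CANONICAL = ("id", "x", "y", "lon", "lat", "n_colonies", "n_diseased", "depth")


def _resolve_columns(columns: Sequence[str], schema: Mapping[str, str] | None) -> dict:
    """Map canonical field names to actual column names (case-insensitive)."""
    schema = dict(schema or {})
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for name in _CANONICAL:
        if name in schema:
            if schema[name] not in columns:
                raise SchemaError(f"schema maps {name!r} to missing column {schema[name]!r}")
            resolved[name] = schema[name]
        elif name in lower:
            resolved[name] = lower[name]
    return resolved


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()
    first = header[0] if header else ""
    return "\t" if first.count("\t") > first.count(",") else ","


def load_survey(
    path,
    schema: Mapping[str, str] | None = None,
    region: Polygon | None = None,
    projection: LocalTransverseMercator | None = None,
) -> SurveyDataset:
    """Load a survey from delimited text or GeoJSON.

    Coordinates may be planar metres (columns ``x``/``y``) or geographic
    (``lon``/``lat``); geographic input is projected with ``projection``,
    or, if none is supplied, with a transverse Mercator centred on the
    data's mean coordinate (recorded in ``crs_note``).

    Parameters
    ----------
    schema : mapping, optional
        Maps canonical names (id, x, y, lon, lat, n_colonies, n_diseased,
        depth) to the file's column names when they differ.
    region : shapely Polygon, optional
        Planar study region; defaults to the bounding rectangle of the
        points.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in {".geojson", ".json"} or text.lstrip().startswith("{"):
        df = _geojson_to_frame(json.loads(text) if text.strip() else {})
    else:
        if not text.strip():
            df = pd.DataFrame()
        else:
            df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.empty:
        warnings.warn(f"{path}: no records loaded", stacklevel=2)
        return SurveyDataset.from_records([], region=region, crs_note="empty survey")

    cols = _resolve_columns(df.columns, schema)
    for required in ("n_colonies", "n_diseased"):
        if required not in cols:
            raise SchemaError(f"missing required column {required!r}")
    crs_note = "planar input (metres)"
    if "x" in cols and "y" in cols:
        xy = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    elif "lon" in cols and "lat" in cols:
        lon = df[cols["lon"]].to_numpy(dtype=float)
        lat = df[cols["lat"]].to_numpy(dtype=float)
        if projection is None:
            projection = LocalTransverseMercator(float(lon.mean()), float(lat.mean()))
            crs_note = (
                f"auto transverse Mercator, origin "
                f"({projection.lon0:.5f}, {projection.lat0:.5f})"
            )
        else:
            crs_note = f"caller projection {projection!r}"
        xy = project_coordinates(lon, lat, projection)
    else:
        raise SchemaError("missing coordinate columns: need x/y or lon/lat")

    ids = (
        df[cols["id"]].astype(str).tolist()
        if "id" in cols
        else [f"t{i:04d}" for i in range(len(df))]
    )
    depth_col = cols.get("depth")
    records = []
    for i in range(len(df)):
        depth = None
        if depth_col is not None:
            v = df[depth_col].iloc[i]
            depth = None if pd.isna(v) else float(v)
        records.append(
            TransectRecord(
                id=ids[i],
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
                n_colonies=int(df[cols["n_colonies"]].iloc[i]),
                n_diseased=int(df[cols["n_diseased"]].iloc[i]),
                depth=depth,
            )
        )
    return SurveyDataset.from_records(records, region=region, crs_note=crs_note)


def _geojson_to_frame(gj: dict) -> pd.DataFrame:
    feats = gj.get("features", [])
    rows = []
    for f in feats:
        geom = f.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError(f"GeoJSON geometry type {geom.get('type')!r}; expected Point")
        props = dict(f.get("properties") or {})
        props["x"], props["y"] = geom["coordinates"][:2]
        if "id" not in props and f.get("id") is not None:
            props["id"] = f["id"]
        rows.append(props)
    return pd.DataFrame(rows)


def to_frame(dataset: SurveyDataset) -> pd.DataFrame:
    """Tabular view of a dataset (one row per transect)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in dataset.records],
            "x": [r.x for r in dataset.records],
            "y": [r.y for r in dataset.records],
            "n_colonies": [r.n_colonies for r in dataset.records],
            "n_diseased": [r.n_diseased for r in dataset.records],
            "depth": [r.depth for r in dataset.records],
        }
    )


def write_survey(dataset: SurveyDataset, path) -> None:
    """Write a survey as CSV/TSV or GeoJSON, by file suffix.

    Numeric fields round-trip exactly through either format (coordinates
    are written with repr precision).
    """
    path = Path(path)
    df = to_frame(dataset)
    if df["depth"].isna().all():
        df = df.drop(columns=["depth"])
    if path.suffix.lower() in {".geojson", ".json"}:
        feats = []
        for _, row in df.iterrows():
            props = {k: row[k] for k in df.columns if k not in ("x", "y")}
            props = {
                k: (None if pd.isna(v) else v) for k, v in props.items()
            }
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                    "properties": props,
                }
            )
        gj = {"type": "FeatureCollection", "features": feats}
        path.write_text(json.dumps(gj, default=float))
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df.to_csv(path, sep=sep, index=False, float_format=None)


def write_summary(summary: SurveySummary, path) -> None:
    """Serialize a summary as a flat JSON key-value report."""
    Path(path).write_text(json.dumps(summary.formatted(), indent=2))


def region_to_geojson(region: Polygon) -> dict:
    return {"type": "Feature", "geometry": mapping(region), "properties": {}}


def region_from_geojson(obj: dict) -> Polygon:
    geom = obj.get("geometry", obj)
    return shape(geom)
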
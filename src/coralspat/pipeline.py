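"""End-to-end two-resolution outbreak analysis.

One call runs, for both the transect (presence/absence) and colony
(count-weighted) resolutions of a survey:

1. descriptive summary;
2. six homogeneous L-function analyses with CSR envelopes — disease,
   healthy, and whole-population patterns at each resolution;
3. two disease-minus-population difference functions with
   random-labelling envelopes;
4. two filtered prevalence surfaces with Monte Carlo significance and
   hotspot extraction.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` in a fixed, documented order
(generation, envelopes in the order listed above, difference functions,
Monte Carlo surfaces), so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synth
from .filtermap import (
    ClusterSet,
    ClusterSummary,
    GridSpec,
    PrevalenceSurface,
    cluster_summary,
    extract_clusters,
    filtered_prevalence,
    h_opt,
    monte_carlo_significance,
    standard_distance,
)
from .ripley import DifferenceResult, DistanceBins, LFunctionResult, l_with_envelope, difference_function
from .survey import SurveyDataset, SurveySummary, load_survey, summarize, to_frame, write_survey
from .filtermap import write_ascii_grid

logger = logging.getLogger("coralspat")

#: analysis names in seed-fanout order
_L_ANALYSES = (
    ("transect", "disease"),
    ("transect", "healthy"),
    ("transect", "population"),
    ("colony", "disease"),
    ("colony", "healthy"),
    ("colony", "population"),
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario: synth.ScenarioConfig | None = None
    input_path: str | None = None
    dataset: SurveyDataset | None = None
    schema: dict | None = None
    bins: DistanceBins = field(default_factory=DistanceBins)
    envelope_sims: int = 99
    grid: GridSpec | None = None
    cell: float = 50.0
    radius: float | str = "auto"
    mc_sims: int = 1000
    alpha: float = 0.05
    buffer_m: float = 100.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        sources = sum(x is not None for x in (self.scenario, self.input_path, self.dataset))
        if sources != 1:
            raise ValueError("provide exactly one of scenario, input_path, or dataset")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunReport:
    """Everything one run computes, plus the provenance manifest."""

    config: RunConfig
    dataset: SurveyDataset
    summary: SurveySummary
    sigma: float
    radius: float
    l_results: dict[str, LFunctionResult]
    differences: dict[str, DifferenceResult]
    surfaces: dict[str, PrevalenceSurface]
    clusters: dict[str, ClusterSet]
    cluster_summaries: dict[str, ClusterSummary]
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def _analysis_weights(dataset: SurveyDataset, level: str, pattern: str):
    """(weights or None) selecting the requested pattern at the given level."""
    colonies = dataset.colony_counts.astype(float)
    diseased = dataset.diseased_counts.astype(float)
    if level == "transect":
        pos = dataset.positive_mask
        sel = {"disease": pos, "healthy": ~pos, "population": np.ones(len(dataset), bool)}[
            pattern
        ]
        return sel.astype(float)
    w = {"disease": diseased, "healthy": colonies - diseased, "population": colonies}[
        pattern
    ]
    return w


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the full two-resolution analysis; deterministic given the seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(12)  # 0: generation, 1-6: envelopes, 7-8: differences, 9-10: MC
    # --- data -----------------------------------------------------------
    if config.scenario is not None:
        scen = dataclasses.replace(
            config.scenario, seed=int(seeds[0].generate_state(1)[0] % (2**31))
        )
        dataset, _truth = _stage("simulate")(synth.generate_survey)(scen)
    elif config.dataset is not None:
        dataset = config.dataset
    else:
        dataset = _stage("load")(load_survey)(config.input_path, schema=config.schema)
    logger.info("dataset: %d transects, %d colonies", len(dataset),
                int(dataset.colony_counts.sum()))
    summary = _stage("summarize")(summarize)(dataset)

    # --- Ripley / difference -------------------------------------------
    pts, region, area = dataset.points, dataset.region, dataset.region_area
    l_results: dict[str, LFunctionResult] = {}
    for i, (level, pattern) in enumerate(_L_ANALYSES):
        w = _analysis_weights(dataset, level, pattern)
        if (w > 0).sum() < 2:  # e.g. an all-healthy survey has no disease pattern
            logger.warning("skipping %s_%s: fewer than 2 positive-weight points",
                           level, pattern)
            continue
        res = _stage(f"ripley_{level}_{pattern}")(l_with_envelope)(
            pts, region, config.bins, weights=w, area=area,
            n_sims=config.envelope_sims, seed=seeds[1 + i],
        )
        res.weighting = "none" if level == "transect" else "colony"
        l_results[f"{level}_{pattern}"] = res
    differences: dict[str, DifferenceResult] = {}
    for j, level in enumerate(("transect", "colony")):
        pop_w = _analysis_weights(dataset, level, "population")
        dis_w = _analysis_weights(dataset, level, "disease")
        if (dis_w > 0).sum() < 2:
            logger.warning("skipping difference_%s: fewer than 2 disease points", level)
            continue
        differences[level] = _stage(f"difference_{level}")(difference_function)(
            pts, pop_w, dis_w, config.bins, area, level=level,
            n_sims=config.envelope_sims, seed=seeds[7 + j],
        )

    # --- filter maps ----------------------------------------------------
    sigma = standard_distance(pts)
    radius = (
        h_opt(len(dataset), sigma) if config.radius == "auto" else float(config.radius)
    )
    grid = config.grid or GridSpec.from_region(region, cell=config.cell)
    surfaces, clusters, summaries = {}, {}, {}
    for j, mode in enumerate(("transect", "colony")):
        surf = _stage(f"dmap_{mode}")(filtered_prevalence)(dataset, grid, radius, mode)
        monte_carlo_significance(surf, dataset, n_sims=config.mc_sims, seed=seeds[9 + j])
        cl = extract_clusters(surf, dataset, alpha=config.alpha)
        surfaces[mode] = surf
        clusters[mode] = cl
        summaries[mode] = cluster_summary(cl, dataset, buffer_m=config.buffer_m)

    report = RunReport(
        config=config, dataset=dataset, summary=summary, sigma=sigma, radius=radius,
        l_results=l_results, differences=differences, surfaces=surfaces,
        clusters=clusters, cluster_summaries=summaries, manifest={},
    )
    report.manifest = _build_manifest(report)
    if config.outdir is not None:
        write_outputs(report, Path(config.outdir))
    return report


def _build_manifest(report: RunReport) -> dict:
    cfg = report.config
    return {
        "seed": cfg.seed,
        "n_transects": len(report.dataset),
        "bins": {"d_max": cfg.bins.d_max, "step": cfg.bins.step},
        "envelope_sims": cfg.envelope_sims,
        "mc_sims": cfg.mc_sims,
        "alpha": cfg.alpha,
        "radius_m": report.radius,
        "sigma_m": report.sigma,
        "l_curves": sorted(report.l_results),
        "difference_curves": sorted(report.differences),
        "surfaces": sorted(report.surfaces),
        "cluster_sets": sorted(report.clusters),
        "files": {},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(report: RunReport, outdir: Path) -> None:
    """Write every result (tables, rasters, polygons, report, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    p = outdir / "survey.csv"
    write_survey(report.dataset, p)
    files.append(p)
    for name, res in report.l_results.items():
        p = outdir / f"l_{name}.csv"
        res.to_frame().to_csv(p, index=False)
        files.append(p)
    for name, res in report.differences.items():
        p = outdir / f"difference_{name}.csv"
        res.to_frame().to_csv(p, index=False)
        files.append(p)
    for name, surf in report.surfaces.items():
        p = outdir / f"prevalence_{name}.asc"
        write_ascii_grid(surf.prevalence, surf.grid, p)
        files.append(p)
        if surf.p_value is not None:
            p = outdir / f"pvalue_{name}.asc"
            write_ascii_grid(surf.p_value, surf.grid, p)
            files.append(p)
    for name, cl in report.clusters.items():
        p = outdir / f"clusters_{name}.geojson"
        p.write_text(json.dumps(cl.to_geojson()))
        files.append(p)
    p = outdir / "report.txt"
    p.write_text(write_report(report))
    files.append(p)
    p = outdir / "report.json"
    p.write_text(json.dumps(_report_dict(report), indent=2, default=float))
    files.append(p)

    report.manifest["files"] = {f.name: _sha256(f) for f in files}
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))


def _report_dict(report: RunReport) -> dict:
    return {
        "summary": report.summary.formatted(),
        "sigma_m": round(report.sigma, 2),
        "filter_radius_m": round(report.radius, 2),
        "clusters": {
            mode: {
                "n_clusters": len(report.clusters[mode]),
                "total_area_km2": round(report.clusters[mode].total_area_km2, 2),
                **{
                    k: (round(v, 2) if isinstance(v, float) else v)
                    for k, v in report.cluster_summaries[mode].to_dict().items()
                },
            }
            for mode in report.clusters
        },
    }


def write_report(report: RunReport) -> str:
    """Human-readable comparison report across the two resolutions.

    Percentages are shown to two decimals; depth lines are omitted when
    the survey carries no depths.
    """
    s = report.summary
    lines = [
        "Coral disease survey — two-resolution spatial analysis",
        "=" * 56,
        f"Transects surveyed:            {s.n_transects}",
        f"Transects with disease:        {s.n_transects_positive}",
        f"Colonies surveyed:             {s.n_colonies}",
        f"Diseased colonies:             {s.n_colonies_diseased}",
        f"Prevalence (transect level):   {s.prevalence_transect:.2f}%",
        f"Prevalence (colony level):     {s.prevalence_colony:.2f}%",
        f"Mean colonies/transect:        {s.mean_colonies_per_transect:.2f} "
        f"(min {s.min_colonies_per_transect}, max {s.max_colonies_per_transect}, "
        f"SD {s.sd_colonies_per_transect:.2f})",
    ]
    if s.n_transects_positive:
        lines.append(
            f"Mean diseased/positive transect: {s.mean_diseased_per_positive_transect:.2f} "
            f"(min {s.min_diseased_per_positive_transect}, "
            f"max {s.max_diseased_per_positive_transect}, "
            f"SD {s.sd_diseased_per_positive_transect:.2f})"
        )
    if s.mean_depth is not None:
        lines.append(f"Mean transect depth:           {s.mean_depth:.2f} m")
    lines += [
        "",
        f"Standard distance: {report.sigma:.1f} m; filter radius: {report.radius:.2f} m",
        "",
    ]
    for level, diff in report.differences.items():
        sig = diff.significance_class
        n_clu = int((sig == "clustered_significant").sum())
        n_dis = int((sig == "dispersed_significant").sum())
        lines.append(
            f"Difference function ({level} level): "
            f"{n_clu}/{len(sig)} bins significantly clustered, "
            f"{n_dis}/{len(sig)} significantly dispersed"
        )
    lines.append("")
    for mode in report.clusters:
        cl = report.clusters[mode]
        cs = report.cluster_summaries[mode]
        lines.append(f"Hotspots ({mode} level): {len(cl)} cluster(s), "
                     f"total area {cl.total_area_km2:.2f} km2")
        if len(cl):
            lines.append(
                f"  positive transects inside: {cs.pct_positive_transects_inside:.2f}%"
                f"; within {cs.buffer_m:.0f} m: "
                f"{cs.pct_positive_transects_within_buffer:.2f}%"
            )
            lines.append(
                f"  diseased colonies inside: {cs.pct_diseased_colonies_inside:.2f}%"
                f"; within {cs.buffer_m:.0f} m: "
                f"{cs.pct_diseased_colonies_within_buffer:.2f}%"
            )
            if cs.mean_depth_inside is not None:
                lines.append(f"  mean depth inside clusters: {cs.mean_depth_inside:.2f} m")
    return "\n".join(lines) + "\n"
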
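"""Filtered prevalence surfaces, Monte Carlo significance, hotspot clusters."""

import numpy as np
import pytest
from shapely.geometry import Point, box

from coralspat.filtermap import (
    GridSpec,
    cluster_summary,
    extract_clusters,
    filtered_prevalence,
    h_opt,
    monte_carlo_significance,
    standard_distance,
    write_ascii_grid,
)
from coralspat.survey import SurveyDataset, TransectRecord, ValidationError
from coralspat.synth import (
    FocalDisease,
    RandomDisease,
    ScenarioConfig,
    UniformLocations,
    generate_survey,
)


def naive_surface(dataset, grid, radius, mode):
    """Per-node double-loop oracle for the circular-filter aggregation."""
    num = np.zeros((grid.n_rows, grid.n_cols))
    den = np.zeros_like(num)
    for r, y in enumerate(grid.ys):
        for c, x in enumerate(grid.xs):
            for rec in dataset.records:
                if np.hypot(rec.x - x, rec.y - y) <= radius:
                    if mode == "transect":
                        num[r, c] += rec.n_diseased > 0
                        den[r, c] += 1
                    else:
                        num[r, c] += rec.n_diseased
                        den[r, c] += rec.n_colonies
    return num, den


class TestBandwidth:
    def test_symmetric_pair(self):
        assert standard_distance(np.array([[0.0, 0.0], [2.0, 0.0]])) == 1.0

    def test_unit_square_corners(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        assert standard_distance(pts) == pytest.approx(np.sqrt(0.5))

    def test_coincident_points(self):
        assert standard_distance(np.zeros((5, 2))) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            standard_distance(np.zeros((1, 2)))

    def test_h_opt_near_published_value(self):
        """h_opt(375, 1688.2 m) is within 2% of the published 342.55 m."""
        assert h_opt(375, 1688.2) == pytest.approx(342.55, rel=0.02)

    def test_h_opt_scalings(self):
        assert h_opt(375, 2 * 1688.2) == pytest.approx(2 * h_opt(375, 1688.2))
        assert h_opt(16 * 375, 1688.2) == pytest.approx(h_opt(375, 1688.2) / 2)

    @pytest.mark.parametrize("n,sigma", [(1, 100.0), (10, 0.0), (10, -1.0)])
    def test_h_opt_invalid_inputs(self, n, sigma):
        with pytest.raises(ValueError):
            h_opt(n, sigma)


class TestGrid:
    def test_node_lattice(self):
        g = GridSpec(0, 0, 200, 100, cell=50)
        assert (g.n_cols, g.n_rows) == (5, 3)
        nodes = g.nodes()
        assert nodes.shape == (15, 2)
        assert nodes[0].tolist() == [0, 0] and nodes[-1].tolist() == [200, 100]

    def test_invalid_grids(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, 0, 100)
        with pytest.raises(ValueError):
            GridSpec(0, 0, 10, 10, cell=0)

    def test_geographic_corners(self):
        from coralspat.filtermap import BUCK_ISLAND_CORNERS
        from coralspat.projection import LocalTransverseMercator

        proj = LocalTransverseMercator(-64.6135, 17.792)
        g = GridSpec.from_geographic_corners(*BUCK_ISLAND_CORNERS, proj, cell=50)
        assert 7000 <= g.x_max - g.x_min <= 7500
        assert 3700 <= g.y_max - g.y_min <= 3900


class TestFilteredPrevalence:
    def test_hand_aggregation(self):
        """Two transects (4,1) at x=0 and (6,0) at x=100; node (50,0) with
        radius 150 sees both: colony prevalence 1/10, transect 1/2."""
        ds = SurveyDataset.from_records(
            [TransectRecord("a", 0, 0, 4, 1), TransectRecord("b", 100, 0, 6, 0)],
            region=box(-100, -100, 200, 100),
        )
        grid = GridSpec(50, 0, 100, 50, cell=50)
        col = filtered_prevalence(ds, grid, 150.0, mode="colony")
        tra = filtered_prevalence(ds, grid, 150.0, mode="transect")
        assert col.prevalence[0, 0] == pytest.approx(0.10)
        assert tra.prevalence[0, 0] == pytest.approx(0.50)

    def test_far_node_is_undefined(self):
        ds = SurveyDataset.from_records(
            [TransectRecord("a", 0, 0, 4, 1), TransectRecord("b", 10, 0, 2, 0)],
            region=box(0, 0, 5000, 200),
        )
        grid = GridSpec(0, 0, 5000, 100, cell=100)
        surf = filtered_prevalence(ds, grid, 150.0, mode="transect")
        far = surf.grid.nodes()[:, 0].reshape(surf.prevalence.shape) > 1000
        assert not surf.defined[far].any()
        assert np.isnan(surf.prevalence[far]).all()

    def test_all_diseased_gives_unit_prevalence(self, rng):
        recs = [
            TransectRecord(f"t{i}", *rng.uniform(0, 500, 2), 3, 3) for i in range(20)
        ]
        ds = SurveyDataset.from_records(recs, region=box(0, 0, 500, 500))
        surf = filtered_prevalence(ds, GridSpec(0, 0, 500, 500, cell=100), 200.0,
                                   mode="colony")
        assert np.allclose(surf.prevalence[surf.defined], 1.0)

    def test_matches_naive_oracle(self):
        cfg = ScenarioConfig(n_transects=150, region=box(0, 0, 2000, 1500), seed=8)
        ds, _ = generate_survey(cfg)
        grid = GridSpec(0, 0, 2000, 1500, cell=250)
        for mode in ("transect", "colony"):
            surf = filtered_prevalence(ds, grid, 400.0, mode=mode)
            num, den = naive_surface(ds, grid, 400.0, mode)
            assert np.array_equal(surf.numerator, num)
            assert np.array_equal(surf.denominator, den)

    def test_small_radius_warns(self, small_survey):
        with pytest.warns(UserWarning, match="radius"):
            filtered_prevalence(small_survey, GridSpec(0, 0, 1000, 1000, cell=100),
                                50.0, mode="transect")

    def test_empty_dataset_rejected(self):
        ds = SurveyDataset.from_records([], region=box(0, 0, 10, 10))
        with pytest.raises(ValidationError):
            filtered_prevalence(ds, GridSpec(0, 0, 10, 10, cell=1), 5.0)

    def test_smoothing_reduces_variance(self):
        """On a fixed survey, widening the filter never increases the
        variance of node prevalences (10 synthetic datasets).  Compared on
        the nodes defined at every radius: widening also defines new fringe
        nodes with tiny denominators, which would confound the comparison."""
        for seed in range(10):
            cfg = ScenarioConfig(n_transects=200, seed=seed)
            ds, _ = generate_survey(cfg)
            grid = GridSpec.from_region(ds.region, cell=200)
            surfs = [
                filtered_prevalence(ds, grid, radius, mode="colony")
                for radius in (250.0, 500.0, 1000.0, 2000.0)
            ]
            common = np.logical_and.reduce([s.defined for s in surfs])
            variances = [float(np.var(s.prevalence[common])) for s in surfs]
            assert np.all(np.diff(variances) <= 1e-12)


class TestMonteCarlo:
    def _surface(self, seed=0, mode="colony", dm=None, cell=100.0):
        cfg = ScenarioConfig(disease_model=dm or RandomDisease(), seed=seed)
        ds, truth = generate_survey(cfg)
        grid = GridSpec.from_region(ds.region, cell=cell)
        surf = filtered_prevalence(ds, grid, 342.55, mode=mode)
        return ds, surf, truth

    def test_zero_prevalence_nodes_get_p_one(self):
        ds, surf, _ = self._surface(seed=1)
        monte_carlo_significance(surf, ds, n_sims=99, seed=5)
        zero = surf.defined & (surf.numerator == 0)
        assert zero.any()
        assert np.all(surf.p_value[zero] == 1.0)

    def test_p_value_range_and_floor(self):
        """p is never 0: the most extreme node has p >= 1/(n_sims+1)."""
        ds, surf, _ = self._surface(seed=2, dm=FocalDisease())
        monte_carlo_significance(surf, ds, n_sims=1000, seed=5)
        p = surf.p_value[surf.defined]
        assert np.all(p > 0) and np.all(p <= 1)
        assert p.min() >= 1.0 / 1001.0
        # a strong planted focus beats essentially every null surface
        assert p.min() == pytest.approx(1.0 / 1001.0, rel=1e-9)

    def test_null_calibration(self):
        """Under the random scenario the fraction of defined nodes with
        p <= 0.05 is near the nominal rate (pooled over 20 seeds; nodes
        are spatially correlated so the per-run spread is wide)."""
        sig = defined = 0
        for seed in range(20):
            cfg = ScenarioConfig(location_process=UniformLocations(), seed=seed)
            ds, _ = generate_survey(cfg)
            grid = GridSpec.from_region(ds.region, cell=100.0)
            surf = filtered_prevalence(ds, grid, 342.55, mode="colony")
            monte_carlo_significance(surf, ds, n_sims=999, seed=100 + seed)
            mask = surf.significant_mask(0.05)
            sig += int(mask.sum())
            defined += int(surf.defined.sum())
        assert 0.01 <= sig / defined <= 0.12

    def test_reproducible(self):
        ds, surf, _ = self._surface(seed=3)
        a = monte_carlo_significance(surf, ds, n_sims=200, seed=7).p_value.copy()
        ds2, surf2, _ = self._surface(seed=3)
        b = monte_carlo_significance(surf2, ds2, n_sims=200, seed=7).p_value
        assert np.array_equal(a, b, equal_nan=True)


class TestClusters:
    def _manual_surface(self, sig_nodes, shape=(6, 6), cell=50.0):
        grid = GridSpec(0, 0, cell * (shape[1] - 1), cell * (shape[0] - 1), cell=cell)
        p = np.ones(shape)
        prev = np.zeros(shape)
        for r, c in sig_nodes:
            p[r, c] = 0.01
            prev[r, c] = 0.5
        from coralspat.filtermap import PrevalenceSurface

        return PrevalenceSurface(
            grid=grid, radius=cell, mode="transect",
            numerator=prev, denominator=np.ones(shape), prevalence=prev,
            defined=np.ones(shape, bool), p_value=p, n_sims=99, global_p=0.1,
        )

    def test_single_node_cluster_area(self):
        surf = self._manual_surface([(2, 2)])
        cs = extract_clusters(surf)
        assert len(cs) == 1
        assert cs.clusters[0].area_km2 == pytest.approx(0.0025)  # one 50 m cell
        assert cs.total_area_km2 == pytest.approx(0.0025)

    def test_diagonal_nodes_join_by_8_connectivity(self):
        cs = extract_clusters(self._manual_surface([(1, 1), (2, 2)]))
        assert len(cs) == 1
        assert cs.clusters[0].node_count == 2

    def test_separate_blocks_sorted_by_area(self):
        cs = extract_clusters(self._manual_surface([(0, 0), (4, 4), (4, 5), (5, 4)]))
        assert [c.node_count for c in cs.clusters] == [3, 1]
        assert [c.id for c in cs.clusters] == [1, 2]

    def test_no_significant_nodes_gives_empty_set(self):
        cs = extract_clusters(self._manual_surface([]))
        assert len(cs) == 0 and cs.total_area_km2 == 0.0

    def test_planted_foci_recovered(self):
        """Focal scenario (relative risk 10, 300 m foci): >= 90% of planted
        foci lie within 100 m of an extracted hotspot (20 seeds), while the
        matched random scenario yields much smaller significant area."""
        hits = total = 0
        focal_area, random_area = [], []
        for seed in range(20):
            cfg = ScenarioConfig(disease_model=FocalDisease(), seed=seed)
            ds, truth = generate_survey(cfg)
            grid = GridSpec.from_region(ds.region, cell=100.0)
            surf = filtered_prevalence(ds, grid, 342.55, mode="colony")
            monte_carlo_significance(surf, ds, n_sims=999, seed=seed)
            cs = extract_clusters(surf, ds)
            focal_area.append(cs.total_area_km2)
            near = cs.union.buffer(100.0)
            for f in truth.foci:
                total += 1
                hits += near.covers(Point(f))
            cfg_r = ScenarioConfig(disease_model=RandomDisease(), seed=seed)
            ds_r, _ = generate_survey(cfg_r)
            surf_r = filtered_prevalence(ds_r, grid, 342.55, mode="colony")
            monte_carlo_significance(surf_r, ds_r, n_sims=999, seed=seed)
            random_area.append(extract_clusters(surf_r, ds_r).total_area_km2)
        assert hits / total >= 0.90
        from scipy import stats

        p = stats.wilcoxon(focal_area, random_area, alternative="greater").pvalue
        assert p < 0.05

    def test_maup_prevalence_inflation(self):
        """Spatially heterogeneous colony counts + colony-random disease:
        transect-level prevalence exceeds colony-level prevalence, and the
        transect-level difference function is more clustered at short range
        than the colony-weighted one (pooled over 12 seeds)."""
        from coralspat.ripley import DistanceBins, difference_function
        from coralspat.survey import summarize
        from coralspat.synth import HabitatPatches

        short_t, short_c = [], []
        for seed in range(12):
            cfg = ScenarioConfig(
                location_process=UniformLocations(),
                habitat=HabitatPatches(n_patches=3, radius=800.0, multiplier=5.0),
                disease_model=RandomDisease(),
                seed=seed,
            )
            ds, _ = generate_survey(cfg)
            s = summarize(ds)
            assert s.prevalence_transect > s.prevalence_colony
            bins = DistanceBins(d_max=2500, step=250)
            pts, area = ds.points, ds.region_area
            dt = difference_function(
                pts, np.ones(len(ds)), ds.positive_mask.astype(float), bins, area,
                level="transect", n_sims=19, seed=seed,
            )
            dc = difference_function(
                pts, ds.colony_counts.astype(float), ds.diseased_counts.astype(float),
                bins, area, level="colony", n_sims=19, seed=seed,
            )
            sel = bins.edges <= 1000
            short_t.append(dt.d_values[sel].mean())
            short_c.append(dc.d_values[sel].mean())
        assert np.mean(short_t) > np.mean(short_c)
        assert np.mean(short_t) > 0.0  # presence/absence pattern is aggregated


class TestClusterSummary:
    def test_percentages_and_buffer_superset(self):
        cfg = ScenarioConfig(disease_model=FocalDisease(), seed=5)
        ds, _ = generate_survey(cfg)
        grid = GridSpec.from_region(ds.region, cell=100.0)
        surf = filtered_prevalence(ds, grid, 342.55, mode="colony")
        monte_carlo_significance(surf, ds, n_sims=499, seed=9)
        cs = extract_clusters(surf, ds)
        summ = cluster_summary(cs, ds, buffer_m=100.0)
        assert 0 <= summ.pct_positive_transects_inside <= 100
        assert summ.pct_positive_transects_within_buffer >= summ.pct_positive_transects_inside
        assert summ.pct_diseased_colonies_within_buffer >= summ.pct_diseased_colonies_inside

    def test_empty_cluster_set_gives_zeros(self, small_survey):
        from coralspat.filtermap import ClusterSet

        summ = cluster_summary(ClusterSet([], 0.05, 0.0), small_survey)
        assert summ.pct_positive_transects_inside == 0.0
        assert summ.total_area_km2 == 0.0

    def test_all_positive_inside(self):
        """Clusters covering every positive transect report 100% inside."""
        recs = [
            TransectRecord("a", 100, 100, 4, 2),
            TransectRecord("b", 120, 110, 5, 1),
            TransectRecord("c", 900, 900, 5, 0),
        ]
        ds = SurveyDataset.from_records(recs, region=box(0, 0, 1000, 1000))
        from coralspat.filtermap import Cluster, ClusterSet

        poly = box(50, 50, 200, 200)
        cs = ClusterSet(
            [Cluster(1, poly, poly.area / 1e6, 9, ["a", "b"], None)],
            alpha=0.05, total_area_km2=poly.area / 1e6,
        )
        summ = cluster_summary(cs, ds)
        assert summ.pct_positive_transects_inside == 100.0
        assert summ.pct_positive_transects_within_buffer == 100.0


class TestAsciiGrid:
    def test_round_trip_shape_and_nodata(self, tmp_path):
        grid = GridSpec(0, 0, 200, 100, cell=50)
        vals = np.arange(15, dtype=float).reshape(3, 5)
        vals[0, 0] = np.nan
        f = tmp_path / "g.asc"
        write_ascii_grid(vals, grid, f)
        lines = f.read_text().splitlines()
        assert lines[0] == "ncols 5" and lines[1] == "nrows 3"
        body = np.array([[float(v) for v in ln.split()] for ln in lines[6:]])
        assert body.shape == (3, 5)
        assert body[2, 0] == -9999.0  # nan written as NODATA, bottom row last
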
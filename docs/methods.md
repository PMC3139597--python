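# Methods

`coralspat` analyses a point-referenced coral-disease survey at two
resolutions: each transect as a presence/absence point (transect level),
and each transect weighted by its colony counts (colony level).  The
package implements three statistical layers — a second-order clustering
statistic, a disease-vs-host difference function, and a smoothed
prevalence surface with Monte Carlo hotspot detection — plus a synthetic
survey generator that provides ground truth for testing all of them.

## Coordinate frame

All statistics are computed in a single planar frame in metres.
Geographic input is projected once, on load, with a spherical transverse
Mercator centred on the study area (`projection.LocalTransverseMercator`).
Forward and inverse are exact analytic inverses; over a survey a few
kilometres across, the departure from an ellipsoidal datum is a uniform
sub-0.4% scale factor that cancels from every ratio-based statistic and
is far below transect positioning error.  Hand-rolling the projection
keeps the dependency footprint to the scientific Python stack; the
package never needs datum transformations, only one local metric frame.

## The L-function

The second-order statistic is the square-root transform of Ripley's K
with weighted pair sums:

    L(d) = sqrt( A * S(d) / (pi * W) )

with `S(d) = Σ_{i≠j} w_i w_j 1[dist(i,j) ≤ d]` over ordered pairs,
`W = Σ_{i≠j} w_i w_j`, and A the study-region area.  Unit weights give
the familiar `L(d) = sqrt(A·#pairs/(π n(n−1)))` with `E[L(d)] ≈ d` under
complete spatial randomness (CSR); colony-count weights turn the transect
pattern into a colony-level marked pattern.  Design notes:

* **Normalisation is an assumption.**  The historical tooling this
  estimator mirrors did not publish its exact transform; the implemented
  form is the standard weighted transformed K and reduces to the textbook
  unweighted form.  This is flagged here deliberately: absolute L values
  depend on it, significance classifications far less so, because the
  null curves are computed with the same estimator.
* **No edge correction by default.**  Observed and simulated curves share
  the same (downward) boundary bias, so envelope comparisons remain
  valid.  A toroidal-distance option exists for sensitivity analysis on
  rectangular regions.
* **A comes from the dataset's region geometry, never silently from a
  bounding box**, because L scales with sqrt(A).
* **Ties at a bin edge count toward that bin** (closed upper bound),
  identically in the implementation and in the test oracles.
* Distances are evaluated at `step, 2·step, …, d_max`; defaults 50 m and
  2,500 m (50 bins), matching the scale of a few-km reef survey.

## Envelopes and the difference function

Envelopes are pointwise min/max over `n_sims` simulations; the default
99 simulations give a two-sided pointwise exceedance of 2/(99+1) = 2%,
conventionally read as a p = 0.01 envelope.  Two null models:

* **CSR** (`csr_envelope`): locations redrawn uniformly over the region,
  any weights carried along in random order.  Used for the homogeneous
  analyses of each pattern (disease, healthy, population × two levels).
* **Random labelling** (`difference_function`): locations held fixed;
  the disease labels are reassigned within the host population — at
  transect level by sampling the observed number of positive transects
  without replacement, at colony level by redistributing the observed
  diseased-colony total over the population's colonies (multivariate
  hypergeometric).  Random labelling, not random relocation, is the
  correct null for "is the disease pattern unusual *given* its host
  pattern".

The difference function `D(d) = L_disease(d) − L_population(d)` is zero
in expectation under random labelling; positive D means the disease is
more aggregated than its host population.  Per-bin classification:
above/below the envelope → significantly clustered/dispersed; inside the
envelope the sign of the deviation from the expectation gives the
non-significant tendency.

The cross-resolution table (`cross_resolution_test`) compares the
colony-weighted observed curve against the unweighted envelope and vice
versa, asking whether weighting by colony counts changes the clustering
verdict at each distance.

At very sparse configurations (few cases, short distances) the labelling
distribution of D is strongly discrete and the min/max envelope becomes
conservative (observed exceedance below 2%); the calibration tests use a
dense enough configuration that D is effectively continuous.

## Filtered prevalence surfaces and hotspots

A rectangular lattice of grid nodes (cell corners, default spacing 50 m)
covers the study area; at each node a circular filter of fixed radius
collects transects within it (closed disc) and local prevalence is
numerator/denominator — positive transects over all transects, or
diseased colonies over all colonies.  Filters must overlap (radius ≥
cell) to smooth the surface; nodes whose filter is empty are explicitly
undefined, never zero.

The default radius is the optimized bandwidth

    h_opt = sigma * (2 / (3 n))^(1/4)

with `sigma` the standard distance (RMS distance from the spatial mean)
of the transect locations.  For the published survey inputs (n = 375,
sigma = 1,688.2 m) this formula gives 346.65 m where the source analysis
printed 342.55 m — a 1.2% discrepancy whose origin (rounding or a
variant constant) cannot be recovered from the published material; the
standard form is implemented and the difference documented here.

**Monte Carlo significance.**  The null keeps every location and
denominator fixed and redraws disease at the observed global prevalence:
per transect (Bernoulli) in transect mode, per colony (Binomial within
each transect) in colony mode — so simulated diseased counts per
transect are Binomial(n_colonies, p), honouring the individual-level
null.  Per defined node, `p = (1 + #{sims ≥ observed}) / (1 + n_sims)`
(p is never 0); nodes observed at zero prevalence get p = 1.  Because
denominators are fixed, comparing numerators is equivalent to comparing
prevalences.  Default 1,000 simulations.

**Clusters.**  Significant nodes (p ≤ α, default α = 0.05, prevalence
> 0) are joined by 8-connectivity; each node contributes the cell-sized
square centred on it, cluster polygons are unions of these squares, and
areas (node count × cell², reported in km²) assign cluster ids in
descending order.  `cluster_summary` reports the share of positive
transects and diseased colonies inside clusters and within a 100 m
buffer, and mean member depth when depths are recorded.

The node-level null calibration is conservative (≈2% of defined nodes at
p ≤ 0.05 rather than 5%) because local case counts are small and
discrete and the zero-prevalence rule forces p = 1 over large empty
tracts; the calibration tests assert the spec'd band rather than exact
nominal behaviour.

## Synthetic surveys

`synth.ScenarioConfig` generates surveys that emulate the statistical
structure of a reef-shelf outbreak survey; the defaults are the study
conditions every test runs under.

* **Region**: 7,300 m × 3,800 m rectangle (the analysis-grid extent),
  optional central island hole.
* **Locations**: Thomas-type clustered placement by default (parents
  uniform, `n/15` parents, offspring displaced by an isotropic 150 m sd
  Gaussian, redrawn into the region).  Real transect patterns over reef
  hard-bottom are habitat-confined and significantly aggregated at all
  survey scales, so a uniform default would misrepresent the data the
  generator emulates; uniform placement remains available and is what
  the CSR calibration tests use.
* **Colony counts**: zero-truncated negative binomial, untruncated mean
  6.65 and size (dispersion) 1.513 — chosen so the implied variance
  `μ + μ²/k` matches the published SD of 5.99 — capped at 40.  The
  published minimum of 1 motivates the zero truncation (transects
  without hosts were excluded from the survey).  An optional
  habitat-patch modifier multiplies the local mean inside a few discs,
  producing the spatially heterogeneous colony densities needed to study
  aggregation-resolution artefacts; the base generator draws counts
  i.i.d. and cannot produce them.
* **Disease**: colonies are labelled independently, so per-transect
  diseased counts are Binomial(n_colonies, p_local).  `random` and
  `ubiquitous` use a flat p (default 0.0277, the outbreak's colony
  prevalence).  `focal` elevates risk to `base_p × relative_risk` within
  300 m of each of 8 foci (defaults), with `base_p = 0.016` chosen so
  the scenario's expected overall prevalence stays near 2.77% at
  relative risk 10.  Foci are anchored at randomly chosen transect
  locations: a point source with no hosts in range plants no signal and
  is not a realizable outbreak focus (explicit coordinates can still be
  supplied, including over empty water).
* **Reproducibility**: every generator is a pure function of
  (config, seed); a master seed fans out per stage via
  `SeedSequence.spawn`.

`reference_survey` additionally calibrates one generated survey to the
published marginal totals — 375 transects, 2,492 colonies (mean 6.65,
SD 5.99, min 1), 69 diseased colonies on 44 positive transects — by
±1 adjustments and mean-preserving transfers.  Only the marginals are
fixed; the spatial labelling is random, so the calibrated survey
reproduces the published summary table but *not* the published maps.

### What passing tests do and do not show

The generator produces clustered-but-stationary locations, i.i.d. or
patch-modulated counts, and conditionally independent colony labels.  It
does not emulate contagion through time, depth/habitat gradients in
risk, within-transect colony positions (the survey records one point per
transect), or observation error in the case definition.  Tests passing
on these scenarios demonstrate the estimators' correctness and
calibration under known truth — not that any particular ecological
conclusion about a real reef is right.

## Numerical choices and degenerate inputs

* Pair sums use sorted condensed distances + cumulative weighted counts;
  an O(n²) double loop in the tests serves as the independent oracle
  (agreement to 1e-9 relative).
* Surfaces reuse a sparse node×transect membership matrix, so 1,000
  Monte Carlo surfaces are two sparse matrix products; simulations are
  chunked (250 at a time) to bound memory.
* Fewer than 2 positive-weight points make L undefined → error; the
  pipeline skips (with a warning) disease-pattern analyses of an
  all-healthy survey rather than failing the run.
* An empty input file loads as an empty dataset with a warning;
  summaries and surfaces reject it.
* Significance contours use p ≤ α (inclusive), and pairs exactly at a
  bin edge count toward that bin.
* Test problem sizes (n = 60–375 points, 100–250 m analysis grids,
  99–999 simulations) are chosen so the full suite exercises every
  calibration property at comfortable statistical resolution while
  remaining a desk-scale computation.

## Known limitations

* No inhomogeneous-intensity K estimator and no spatio-temporal
  statistics; the design targets single-snapshot surveys.
* No covariate adjustment (e.g., depth) in the prevalence surfaces;
  depth is carried and summarised only.
* The min/max envelope is a pointwise test; no global (simultaneous)
  envelope is provided, so reading significance across many bins invites
  multiplicity.
* Cluster areas are lattice unions of 50 m cells, not smooth contours;
  at the default cell size this quantises areas in 0.0025 km² steps.
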
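# coralspat

Spatial analysis of coral-disease transect surveys at two resolutions.

Reef disease surveys typically record one GPS point per transect together
with counts of host colonies and diseased colonies.  The same survey can
then be read two ways: as presence/absence of disease per transect, or
with each transect weighted by its colony counts.  The choice of
resolution — a classic modifiable-areal-unit problem — can change the
estimated prevalence several-fold and redraw the map of apparent disease
hotspots.  `coralspat` gives marine-disease ecologists and reef managers
a tested, reproducible pipeline for running both analyses side by side
on a white-band-disease-style outbreak survey (or any point-referenced
numerator/denominator survey):

* **Ripley's L-function** with simulation envelopes, in unweighted and
  colony-weighted form:
  `L(d) = sqrt(A · S(d) / (π · W))`, with
  `S(d) = Σ_{i≠j} w_i w_j 1[dist(i,j) ≤ d]` and `W = Σ_{i≠j} w_i w_j`,
  so that complete spatial randomness gives `E[L(d)] ≈ d`.
* **Disease−population difference function**
  `D(d) = L_disease(d) − L_population(d)` with a random-labelling
  envelope: positive D means disease is more aggregated than the host
  population that carries it.
* **Spatially filtered prevalence surfaces**: a circular filter of
  radius `h_opt = σ·(2/(3n))^(1/4)` (σ = standard distance of the
  transect locations) centred on every node of a 50 m grid, with
  Monte Carlo significance (disease labels redrawn per colony at the
  observed global prevalence, locations and denominators fixed) and
  hotspot polygons from contiguous significant nodes (p ≤ 0.05,
  8-connectivity).
* **A synthetic survey generator** with clustered transect placement,
  overdispersed colony counts (zero-truncated negative binomial, mean
  6.65, SD 5.99, range 1–40) and random / focal / ubiquitous disease
  scenarios, providing ground truth for every statistic above.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Analyse a synthetic survey calibrated to the totals of a real outbreak
(375 transects, 44 with disease; 2,492 colonies, 69 diseased):

```python
from coralspat import RunConfig, run_full_analysis, write_report
from coralspat.synth import reference_survey

report = run_full_analysis(RunConfig(dataset=reference_survey(seed=1), seed=1))
print(write_report(report))
```

```
Coral disease survey — two-resolution spatial analysis
========================================================
Transects surveyed:            375
Transects with disease:        44
Colonies surveyed:             2492
Diseased colonies:             69
Prevalence (transect level):   11.73%
Prevalence (colony level):     2.77%
Mean colonies/transect:        6.65 (min 1, max 32, SD 5.99)
Mean diseased/positive transect: 1.57 (min 1, max 4, SD 0.72)

Standard distance: 2373.2 m; filter radius: 487.31 m

Difference function (transect level): 0/50 bins significantly clustered, 0/50 significantly dispersed
Difference function (colony level): 8/50 bins significantly clustered, 0/50 significantly dispersed

Hotspots (transect level): 18 cluster(s), total area 0.84 km2
  positive transects inside: 13.64%; within 100 m: 27.27%
  diseased colonies inside: 13.04%; within 100 m: 28.99%
Hotspots (colony level): 23 cluster(s), total area 1.63 km2
  positive transects inside: 13.64%; within 100 m: 31.82%
  diseased colonies inside: 10.14%; within 100 m: 33.33%
```

Reading it: presence/absence aggregation inflates prevalence more than
fourfold (11.73% vs 2.77%) on the very same survey.  The difference
functions compare each disease pattern to its host population under
random labelling — here the disease labels *are* random among transects
(the calibrated survey fixes only the marginal totals), so few bins
reach significance and the hotspot sets are small and scattered, as they
should be for a spatially unstructured labelling.  The filter radius is
the optimized bandwidth computed from this survey's own standard
distance.

The same workflow is available from the shell:

```sh
coralspat simulate --seed 4 --out survey.csv --truth-out truth.json
coralspat summarize survey.csv
coralspat ripley survey.csv --level colony --pattern difference --out d.csv
coralspat dmap survey.csv --mode colony --radius auto --out-dir out/
coralspat run-all --seed 4 --out-dir out/
```

Outputs are plain text: tidy CSV tables (one row per distance bin),
Esri ASCII grids for the prevalence and p-value surfaces, GeoJSON
hotspot polygons, and a JSON manifest with per-file SHA-256 hashes.

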
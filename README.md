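# dietscape

Individual dietary niche variation for a GPS-collared browsing herbivore:
from plant-DNA metabarcoding read tables and movement tracks through
bootstrap-standardized diets, spatial and vegetation-structure covariates,
and permutation statistics — plus a synthetic-world generator that emulates
the whole study design so every stage can be verified without field data.

## What's inside

| module | role |
| --- | --- |
| `dietscape.synthetic` | landscapes with distance-decaying plant communities, condition-dependent foragers, mean-reverting GPS tracks, multinomial read tables with PCR replicates and sub-1% contaminants, LiDAR point clouds |
| `dietscape.diet_tables` | PCR-replicate averaging → 1% within-sample RRA filter → rarefaction to 7000 reads → RRA/occurrence profiles |
| `dietscape.diet_metrics` | bootstrap diet standardization (k = 6 samples × 1000 iterations), individual/population richness, Shannon diversity, exact species-accumulation curves, DP-weighted diet quality, single-sample comparison |
| `dietscape.space_use` | 95/100% minimum convex polygons, centroid distances, intensity of use (path length / squared 100% MCP area, 21-day window), habitat affiliation, LiDAR height-class structure profiles |
| `dietscape.stats` | from-scratch Bray–Curtis, blocked sequential perMANOVA, pairwise contrasts with Holm adjustment, Mantel tests, NMDS, OLS with AICc/Akaike-weight ranking, Welch's t, PCA condition index |
| `dietscape.pipeline` / `dietscape.cli` | end-to-end orchestration, reporting, and the `dietscape` command |

## CLI

```bash
# 1. generate a synthetic study (reads.csv, gps.csv, lidar.csv, traits.csv,
#    animals.csv, samples.csv, floodplain.geojson, truth.json)
dietscape simulate --config world.yaml --out data/ --seed 1

# 2. run the full analysis (perMANOVAs, Mantel tests, condition regressions,
#    AICc table, accumulation curves, report.md + results.json)
dietscape run --config analysis.yaml --data data/ --out results/

# 3. print the report
dietscape report results/
```

`analysis.yaml` accepts only documented keys (unknown keys are rejected);
defaults are the study protocol: rarefaction depth 7000, 1% RRA filter,
k = 6, B = 1000, 9999 permutations, 21-day movement window, 95% MCP.

## Library use

```python
from dietscape import synthetic as syn, pipeline as pl

world = syn.generate_world(seed=1)          # 15 individuals, two habitats
ds = pl.Dataset.from_world(world)
bundle = pl.run_pipeline(ds, pl.AnalysisConfig(seed=1))
md, js = pl.report(bundle)
```

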
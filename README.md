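# benthos

Global benthic species-richness surfaces from occurrence records.

Large-scale descriptions of sea-floor biodiversity — latitudinal diversity
gradients, bathymetric richness surfaces, faunal provinces — have to be built
from sparse, unevenly sampled museum and survey records. `benthos` implements
a complete, tested pipeline for this problem, modelled on the workflow used
for globally distributed benthic clades such as starfish (Asteroidea):

1. **Cleaning** — occurrence records (Darwin-Core-like CSV) are validated
   against a descriptive range catalogue (per-species bathymetric limits,
   latitudinal limits, known disjunctions), missing depths are imputed from a
   bathymetric grid, land-placed and hadal (>6,000 m) records are removed.
2. **Informed range interpolation** — the core algorithm. A species' range is
   filled between its observed latitudes, but only across latitudes whose
   sea-floor depth envelope (the min/max depth available in each 1° band,
   estimated with 100 sampling points per 1°×1° cell) overlaps the species'
   bathymetric limits, and never across catalogued disjunctions
   (anti-tropical gaps). Blocked latitudes split a range; segments holding no
   observation are dropped rather than bridged.
3. **Richness surfaces** — raw and interpolated occupancy cubes
   (species × 1° latitude × depth bin, with 10/50/200 m bins over the
   shallow 0–200 m, bathyal 200–2,000 m and abyssal 2,000–6,000 m strata),
   latitudinal curves, per-cell sampling-effort grids, and an uncertainty map
   `100·(interpolated − raw)/interpolated`.
4. **Beta diversity** — shallow-water (<200 m) faunas per eco-province,
   Sorenson similarity `100·2a/(2a+b+c)`, and UPGMA clustering into an
   ultrametric dendrogram (Newick export).
5. **Driver inference** — Poisson GLMs of cell richness with a log-effort
   offset (`ln(records+1)`), all-subsets AIC selection,
   autocorrelation-inflated standard errors, random-forest %IncMSE importance
   (1,000 trees, `mtry` 3, 70:30 split), partial-dependence surfaces, and a
   segmented-fit estimator for the cold-water thermal threshold (~1–1.5 °C)
   below which deep-sea richness collapses.
6. **Synthetic worlds** — a generator producing bathymetry, sea-floor
   environmental fields, archetype-based species assemblages and
   effort-biased samples with exported ground truth, so every stage is
   testable without any downloads.

## Worked example

```python
import numpy as np
from benthos import (CellEnvelopes, DepthBins, interpolated_cube_from_records,
                     raw_occupancy, richness, interpolation_uncertainty,
                     latitudinal_curve, make_world)

world = make_world(seed=1, n_species=100)        # synthetic study system
records = world.records.dropna(subset=["depth_m"])
envs = CellEnvelopes.from_grid(world.bathy)      # per-latitude depth envelopes
bins = DepthBins.stratified()                    # 10/50/200 m bins

raw = raw_occupancy(records, world.catalogue, envs, bins)
interp = interpolated_cube_from_records(records, world.catalogue, envs, bins)
r = richness(interp)
curve = latitudinal_curve(r, depth_m=100.0)
u = interpolation_uncertainty(richness(raw), r)

print("records:", len(records))
print("peak richness latitude at 100 m:", int(curve.idxmax()),
      "with", int(curve.max()), "species")
print("mean interpolation uncertainty: %.1f%%" % u.values[r.values > 0].mean())
```

prints

```
records: 8023
peak richness latitude at 100 m: 6 with 27 species
mean interpolation uncertainty: 48.4%
```

— the interpolated surface peaks just north of the equator at shallow depth
(the generator's shallow-tropical archetype, centred near 5° N, dominates the
assemblage), and on average ~48% of each occupied cell's interpolated
richness is gap-filled rather than directly sampled, the quantity the
uncertainty map exists to expose.

## Command line

A thin CLI covers the two shell-friendly stages:

```bash
benthos simulate-world --seed 1 --out world/       # synthetic world + truth
benthos validate --records world/occurrences.csv \
    --catalogue world/catalogue.csv --bathy world/bathymetry.csv --out clean/
```
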
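# Methods

This note documents the models, conventions and numerical choices behind
`benthos`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Conventions shared across the pipeline

* **Latitude bins** are half-open one-degree intervals `[b, b+1)` labelled by
  their integer southern edge. Climate bands are classified by bin centre:
  tropical `|lat| < 23.4°`, temperate `23.4–66.5°`, polar `> 66.5°` (the
  astronomical tropic and polar-circle latitudes).
* **Depth** is positive metres down; bathymetry values ≤ 0 encode land. Depth
  bins are half-open `[top, bottom)` with the deepest bin closed at 6,000 m.
  The richness surfaces use 10 m bins over the shallow stratum (0–200 m),
  50 m over the bathyal (200–2,000 m) and 200 m over the abyssal
  (2,000–6,000 m); environmental tables and effort grids use uniform 100 m
  bins. A species' closed depth interval `[d0, d1]` maps to the bins
  intersecting `[d0, d1)`, so a 0–100 m species occupies ten 10-m bins; a
  degenerate point interval falls in its single containing bin.
* All randomness flows through `numpy.random.default_rng` seeded from an
  explicit configuration or function argument; identical seeds reproduce
  worlds, samples and fits bit-for-bit.

## Sea-floor depth envelopes

The envelope of a 1°×1° cell is the min/max over 100 equally spaced interior
points (a 10×10 lattice at offsets 0.05, 0.15, …, 0.95°), each taking the
depth of its nearest bathymetry node; points on land are excluded. "100
equally spaced points" admits several readings; the square lattice is the
natural one and converges to the dense-lattice envelope within one node's
local variation (tested against a 32×32 oracle). Latitude-band envelopes
aggregate cell envelopes over a longitude window — by default each species'
observed longitudinal extent padded by 1°, on the argument that sea floor far
outside a species' longitudinal range should not license latitudinal
gap-filling; a full-domain window is available (`lon_range="all"`).

## Record cleaning

Validation applies, per record and in order: catalogue membership,
latitudinal limits and disjunction (exclusion) bands, land placement
(bathymetry ≤ 0 at the coordinate), and bathymetric limits with a
configurable tolerance (default 0 m — the strictest reading of removing
records "outside known ranges"). Records whose depth is missing after
imputation pass the depth check rather than being guessed at. Missing depths
are imputed from the nearest bathymetry node and flagged; land or off-grid
coordinates leave the depth missing. Hadal records (strictly deeper than
6,000 m) are removed after depth resolution. Duplicates collapse on (species,
coordinates to 4 decimals, depth to 1 m). Report percentages round half-up to
one decimal. All of these rules are exact set operations, which is why the
planted-contaminant tests demand precision and recall of exactly 1.

## Informed interpolation

Candidate latitudes span the observed bins, intersected with the catalogued
latitudinal limits. A candidate is *blocked* when it lies inside a
disjunction band (bin centre inside the open band) or when the latitude's
depth envelope fails to overlap the species' catalogued bathymetric interval.
Blocked latitudes split the candidate span into segments; segments containing
no observation are discarded, never bridged. One deliberate asymmetry:
**an observed latitude is always retained**, even if the rules would block
it — a physical record outranks a plausibility gate whose purpose is to
restrain gap-filling, and this keeps the raw cube a subset of the
interpolated cube by construction. Within an occupied latitude the species
occupies its catalogued depth interval clipped at the envelope maximum (both
flavours apply the same clip, mirroring the masking of cells deeper than the
deepest available sea floor). Species without catalogued depth limits fall
back to 0–10 m when flagged intertidal/shallow, else to the span of their
record depths. The implementation is verified cell-for-cell against an
independent brute-force checker that applies the rules literally, on
hundreds of randomised small worlds.

## Beta diversity

Sorenson similarity is the printed formula `100·2a/(2a+b+c)`; two empty
faunas are an error, not 100. UPGMA is implemented directly (not via scipy)
so its contract is explicit: merge the pair with minimal average-linkage
distance at height `D/2`, size-weighted distance updates, ties broken by the
lowest (row, column) index for determinism. Similarities convert to
dissimilarity as `D = 100 − S` (an affine map, so the topology is unchanged
whichever orientation the original analysis clustered). scipy's
average-linkage cophenetic matrix serves as an independent oracle in the
tests, and Newick output (branch lengths = height differences, 12 significant
digits) is round-tripped through dendropy. Provinces with fewer species than
a threshold are excluded before clustering — small endemic-dominated island
faunas cannot be placed stably in the dendrogram.

## Environmental layers

Each bathymetry node contributes its sea-floor field values to the
(1° latitude × 100 m) cell containing its floor depth; cell values are node
means and empty cells are absent, not zero. POC flux uses a Martin-type
power law `flux = export_ratio · NPP · (depth/z_ref)^(−b)` with `b = 0.858`,
`z_ref = 100 m` and `export_ratio = 0.1` — the classic open-ocean
attenuation; both the exponent and the export ratio are parameters, because
published export models differ and the analysis only requires a monotone,
depth-attenuated chemical-energy proxy. Collinearity screening drops the
configured victim (silicate first, then phosphate) from pairs with
`|r| > 0.7` strictly; pairs without a listed victim are reported but kept.
Per-stratum normalisation centres and scales predictors to unit SD (scaling
added beyond plain centring so GLM coefficients are comparable across
predictors; `center_only=True` restores pure centring).

## Driver models

Richness per cell is Poisson with log link and an additive `ln(records+1)`
offset. The serial-correlation correction is deliberately simple: the lag-1
autocorrelation ρ of Pearson residuals along latitude inflates standard
errors by `sqrt((1+ρ)/(1−ρ))` (the effective-sample-size factor of an AR(1)
process); it is exposed as a pluggable error adjustment because richer
spatial error models exist but none is canonical here. Model fit is reported
as the squared correlation of fitted and observed values — a pragmatic
"multiple-r²" analogue for Poisson fits, labelled as such. All-subsets
selection fits every predictor subset (capped at 12 predictors) and ranks by
AIC.

Random-forest importance follows the randomForest conventions: 1,000 trees,
`mtry = 3`, and %IncMSE — here computed by permuting one predictor at a time
on a held-out 30% split (`100·(MSE_perm − MSE)/MSE`), with an OOB-style mode
available. Partial dependence is clamp-and-average; large tables may be
subsampled to an evenly spaced row subset (default cap 250 rows in the
recovery studies) since the PD mean converges quickly in the background
sample.

### Thermal-threshold estimator

The breakpoint of a 1-D partial-dependence curve over temperature is located
by a two-segment piecewise-linear fit: every interior grid point (0.1 °C
spacing, matching the precision at which such thresholds are reported) is a
candidate join; independent lines are fitted left and right of the join and
the join minimising total RSS wins. The segments are *not* constrained to
meet: threshold responses in these data are step-shaped (flat-low below the
threshold, flat-high above, because above it richness tracks POC rather than
temperature), and a continuity-constrained hinge demonstrably drags the join
toward the grid edge on a step, while the unconstrained fit recovers both
hinge- and step-shaped breakpoints to grid resolution. A breakpoint is
flagged unidentified when the split improves on a single straight line by
less than 5% relative RSS (flat or linear curves). Uncertainty comes from
resampling the curve's points with replacement and refitting (200 reps,
percentile interval).

## The synthetic world generator

The generator emulates the statistical structure of a compiled global
occurrence dataset, not its geography:

* **Bathymetry** — two wiggling continental margins (1° shelf ramp to 200 m,
  2° slope to ~4,000 m) flanking an abyssal plain near 4,200–5,500 m with
  smooth random relief, on a 0.5° node grid over 160° of latitude
  (−78° to +82°) and 36 longitude columns; latitudes north of 70° are
  progressively shallowed like a restricted Arctic basin.
* **Environment** — sea-floor temperature is a latitudinal surface profile
  (−1.8 + 29·cos²φ) decaying exponentially with depth (400 m scale) toward a
  deep-water value that falls below the configured threshold poleward of
  ~60–70°, floored at −1.9 °C; NPP peaks at temperate latitudes; salinity is
  near-constant with a single step at 42° N (a water-mass proxy); nitrate
  and silicate are strongly correlated (r > 0.9) to exercise the
  collinearity screen.
* **Assemblage** — species draw from six archetypes (shallow tropical 35%,
  shallow anti-tropical 10%, bathyal tropical 20%, bathyal bimodal 10%,
  abyssal cosmopolitan 15%, polar endemic 10%); ranges are rectangles in
  (latitude, depth) clipped to latitudes whose envelope overlaps the depth
  interval, so the exported truth is exactly the bin set a perfect analysis
  should recover. Anti-tropical archetypes carry a tropical exclusion gap.
* **Sampling** — 12,000 records by default, drawn only inside true ranges,
  with multiplicative effort `exp(bias · g)` where `g` is a north-temperate
  (45°, σ 20°) × shallow (800 m scale) mode; `bias = 0` is exactly uniform.
  One third of depths are withheld uniformly at random (the generator's
  default missing-depth rate), and records carry obis/gbif/literature source
  tags.

What the generator does **not** emulate: real coastline geometry, spatial
autocorrelation of sampling within cruises, taxonomic misidentification,
temporal structure, or longitude-dependent environmental gradients. Passing
recovery tests therefore demonstrates correctness of the algorithms under
known ground truth — not that real-data inferences are unbiased.

### Study sizes used by tests and the acceptance script

Recovery studies use worlds of 36 longitude columns at 0.5° resolution;
stratum cell tables are capped at 900 evenly spaced rows before forest
fitting, chosen once as the smallest table that leaves every latitude and
depth bin represented. Threshold recovery runs 20 seeded worlds per
generating threshold (1.0, 1.2, 1.5 °C); driver ranking runs 20 seeded
worlds per scenario; Poisson slope recovery averages 50 replicates of
n = 500.

## Known limitations

* The AR(1) inflation corrects standard errors, not point estimates, and
  only along the latitudinal ordering.
* UPGMA tie-breaking is deterministic but arbitrary; genuinely tied merges
  can differ from other implementations (ties have measure zero for
  continuous similarity data).
* The interpolation's longitudinal gating uses a padded observed extent;
  species whose true longitudinal range greatly exceeds their sampled extent
  are gated conservatively.
* `exclude_sparse` and the disjunction bands encode expert knowledge as
  inputs; nothing in the pipeline infers coastline disjunctions from data.
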
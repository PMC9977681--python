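# Methods

## The accounting model

A detected tree is a green crown with projected area A > 3 m².  Component
dry masses are power laws of crown area, `mass_c(A) = a_c · A^{b_c}` for
c ∈ {wood, foliage, root}, fitted by ordinary least squares on
(ln A, ln mass) from destructive-sampling data (698 / 900 / 26 trees).
Total dry mass is the sum of the three components and carbon is a fixed
0.47 fraction of dry mass.  Natural logs are used in the fit (the base is
immaterial to the back-transformed parameters) and **no back-transform
bias correction** (smearing factor) is applied: the coefficient is the
direct exponential of the fitted intercept.  This matters for the
uncertainty budget — with multiplicative lognormal residuals the
median-unbiased back-transform under-predicts the *mean* mass, and the
subsampling procedure below measures exactly that kind of mismatch.

Crowns above 200 m² are treated as clumped canopies: the area is split
into ⌊A/100⌋ pieces of 100 m² plus one remainder piece (if non-zero), each
piece receives the allometry, and the components are summed over pieces.
Splitting is applied to the area once and identically for all three
components.  Consequences we document and test:

* pieces sum exactly to A;
* for the superlinear components (b > 1) the split-based mass just above
  200 m² is *below* the unsplit extrapolation — a deliberate cap on
  extending single-tree allometry to clumps, with a discontinuity at
  200 m²;
* split fragments below the 3 m² detection threshold still receive
  allometry: the threshold is a property of detected crowns, not of
  fragments.

Carbon is monotone in area within (3, 200] and within each 100 m² regime
beyond; it is not globally monotone across the 200 m² boundary, which is
inherent to the splitting rule.

## Uncertainty budget

Per component, the records are split at random into 80% training / 20%
validation.  The power law is refitted on the training split; on the
validation split we take μ = mean observed mass, μ̂ = mean predicted mass
and Δ = |μ − μ̂| (kg).  The three component errors combine in quadrature,
Δ_allometric = √(Δ_f² + Δ_w² + Δ_r²), and are normalised by
μ_mass = μ_w + μ_f + μ_r to give a relative uncertainty per repetition.
The procedure runs ten times (default) and reports the mean δ̄_allometric.
Design choices where the procedure is underdetermined:

* splits are simple random, independently per component and per
  repetition; no stratification by crown size;
* one master seed drives a single split stream, so the first repetitions
  of two runs with the same seed coincide regardless of `n_reps`;
* the root set (n = 26) leaves only 5 validation points per repetition;
  this is accepted as-is (with a logged warning) and is the dominant
  source of scatter: across seeds δ̄_allometric has a standard deviation
  of roughly 0.03 under the default synthetic conditions.

Crown-area mapping error δ_area is |predicted − labelled| / labelled on
pooled crown-area totals; a per-plot-mean variant
(`crown_area_relative_error_per_plot`) is also exposed because the pooled
and per-plot estimators differ in general and either may be the one a
given evaluation reports.  The combined carbon uncertainty is
δ = √(δ_area² + δ̄_allometric²), which treats the two sources as
independent multiplicative perturbations and drops the interaction term.

## Crown-mapping evaluation

Predictions are matched one-to-one to labels greedily in descending
overlap-area order (ties: smaller labelled id, then smaller predicted id).
Greedy matching is not guaranteed to maximise total overlap; on small
instances the tests compare it against an exhaustive assignment oracle.
A prediction covering several labels keeps the largest-overlap label; the
rest count as omissions (clumping).  Rates are pooled counts over plots
(micro-average), and both the commission and omission rate are expressed
relative to the number of evaluated labelled trees — the convention under
which a planted-error fixture's rates are recovered exactly;
commissions/predictions is reported as a secondary figure.  The net
detection uncertainty is the signed difference commission − omission.
Per-tree area RMSE is computed over labelled crowns, with missed trees
contributing their full labelled area.

Evaluation plots (256 × 128 m, the footprint of a 512 × 256-pixel window
at 0.5 m) are sampled with a configurable wet bias: with probability 0.8 a
plot is drawn where rainfall ≥ 200 mm yr⁻¹, mirroring designs that
oversample where the trees are; plots devoid of vegetation are dropped.

## Rainfall and aggregation

Mean annual precipitation is the multi-year mean of annual totals (monthly
stacks are summed to annual first; incomplete years are an error).
Per-tree rainfall is bilinear interpolation between the four surrounding
cell centres, with constant extrapolation over the half-cell fringe and a
nodata sentinel outside the raster or next to nodata cells.  Zones use
half-open intervals [0,150), [150,300), [300,600), [600,1000] with the
1,000 mm study bound inclusive and anything above it out of domain — the
printed zone limits share endpoints, so a convention is required; tests
pin it at every boundary.

Trees are assigned to density-grid cells by centroid (crowns are small
relative to the default 1-ha cells); cell values are Σ carbon / cell area,
in Mg C ha⁻¹.  Zone land areas for density denominators are counted from
the rainfall raster cells of the whole landscape (not only vegetated
area).  Percentiles use linear interpolation between order statistics.
Rainfall-gradient percentile profiles use 25 mm bins.  Conservation — the
same total carbon per tree, per cell and per zone — is exact by
construction and asserted to 1e-9 relative in the tests.

## Mosaic selection

Round 1 ranks images by (cloud cover ↑, sun elevation ↓, |off-nadir| ↑).
Round 2 assigns priority classes: November–January at <15° off-nadir,
November–January at 15–30°, February–March at <15°, February–March at
15–30°; other months or angles beyond 30° are ineligible.  The tile winner
minimises (class, round-1 keys) — class is made the primary key with
round 1 as tie-break, which reproduces the stated preferences.  The final
deterministic tie-breaks are later acquisition year first (archives are
assembled with a focus on recent coverage), then image id, making the
ordering total and input-order invariant.  NDVI = (NIR − red)/(NIR + red),
defined as 0 when both bands are 0.  Tiles are abstract ids; tiling
geometry is out of scope.

## Synthetic data: what it emulates, and what it does not

The landscape generator lays a linear west–east rainfall gradient
(default 0→1,000 mm yr⁻¹ over 20 km × 1 km at 100 m cells) and populates
each rainfall zone's band with:

* tree densities 0.6 / 8.6 / 21 / 38 ha⁻¹ (hyper-arid → sub-humid) —
  each zone's reported carbon density divided by its reported mean
  per-tree stock;
* crown areas from a lognormal with log-scale σ = 0.85, truncated below
  at 3 m², whose *truncated* mean is calibrated to the reported zone means
  15.1 / 18.4 / 20.9 / 28.1 m² (the location parameter is solved so the
  mean conditional on A > 3 matches, since observed crowns are all above
  the detection threshold).  This σ puts ≈88–89% of crowns below 50 m²
  and well under 1% above 200 m², matching the reported crown-size
  shares.  The full crown-size distribution shape is not reported
  anywhere; lognormal is an assumption.

Crowns are disjoint circles (placement re-sampled up to 50 times against a
spatial hash); real crowns are free-form polygons, but every downstream
computation uses area only.  The synthetic CRS is planar metric with no
UTM handling.

Field samples draw crown areas log-uniformly over 3–400 m² and masses from
the true power laws with multiplicative lognormal noise — the residual
model implied by log–log OLS.  The default noise σ = 0.70 is calibrated by
simulation so the subsampling procedure on the default sample sizes yields
δ̄_allometric ≈ 0.195 (mean 0.1955 ± 0.032 over 100 independent simulated
campaigns); it is a property of the emulated study conditions, not a
per-run tuning knob.

Evaluation fixtures plant exactly round(n·rate) commission and omission
errors on a lattice spaced so all circles are disjoint, which makes the
planted rates recoverable exactly — a round-trip identity the tests and
the acceptance script rely on.  Image catalogs draw months 1–12, off-nadir
−45…45°, Beta-skewed cloud cover and years 2002–2020 so that all four
priority classes and ineligible records occur.

What passing tests on these synthetics do **not** show: robustness to real
segmentation noise (irregular polygons, merged/fragmented crowns), to
spatially structured rainfall, to species- or landscape-level deviations
from a single allometry, or to the area-dependent error structure of real
crown mapping.  The generators validate the accounting machinery, not the
upstream mapping.

## Numerical choices and problem sizes

* Vectorised estimation (`add_carbon_estimates`) and the scalar
  `estimate_tree_carbon` agree to 1e-12 relative; an independent
  brute-force oracle pins both on a ~2,000-point area grid.
* Seeds: every generator and the subsampling procedure take explicit
  seeds; derived child seeds come from `numpy.random.SeedSequence` and
  stay below 2³¹.
* Default problem sizes keep the full test suite around ten seconds and
  the acceptance run a few seconds: ~2,300-tree landscapes in unit tests,
  ~11,000 trees for the conservation check, ~46,000 trees (2,000 ha) in
  the acceptance script, 100-seed simulation studies for parameter
  recovery.
* The acceptance script reports the allometric uncertainty as the mean
  over 10 replicate simulated campaigns, because a single campaign's
  estimate scatters by ±0.03 (root-set validation noise) and the quantity
  of interest is the procedure's expectation under the study conditions.
* Degenerate inputs: zero-tree landscapes run cleanly end to end; zones
  with no trees report n = 0 and undefined means; empty denominators in
  per-class rates are `None`; crowns at or below 3 m² raise a distinct
  filtered-out signal rather than a generic error.

## Known limitations

* Greedy matching can in principle differ from optimal assignment on
  pathological overlap patterns; the exhaustive oracle covers only small
  instances.
* The two printed crown-area totals of the original evaluation imply a
  pooled relative error of ≈3.0%, while the reported figure is 3.3%; the
  exact estimator behind the reported value is not stated, so both the
  pooled-totals and per-plot-mean estimators are exposed.
* Rainfall rasters travel as ESRI ASCII grids and crowns as GeoJSON in a
  planar CRS; no projection handling or GeoTIFF support.
* The uncertainty budget ignores the interaction term of the two error
  sources and any spatial correlation of mapping errors.
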
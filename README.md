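# sahelcarbon

Tree-level carbon accounting for dryland landscapes.

Dryland trees grow scattered rather than in closed forests, so plot
inventories and coarse satellite carbon maps miss most of them.  When
individual tree crowns *can* be mapped (e.g. by segmenting sub-metre
satellite imagery), each crown's horizontal area A (m²) becomes a predictor
of the tree's biomass, and carbon stocks can be built bottom-up, tree by
tree.  This package implements that accounting chain for the 0–1,000 mm yr⁻¹
rainfall domain of semi-arid Africa:

* **allometry** — destructive-sampling power laws predicting oven-dry mass
  (kg) from crown area:

      mass_w(A) = 3.9448 · A^1.1068   (wood,    n = 698)
      mass_f(A) = 0.2693 · A^0.9441   (foliage, n = 900)
      mass_r(A) = 0.8339 · A^1.1730   (root,    n = 26)

  with mass(A) = mass_w + mass_f + mass_r and carbon = 0.47 · mass.
  Crowns above 200 m² (usually clumped canopies) are split into ⌊A/100⌋
  pieces of 100 m² plus a remainder before the power laws are applied.
* **geo** — mean-annual-rainfall fields, bilinear per-tree rainfall
  extraction, classification into rainfall zones (hyper-arid [0,150),
  arid [150,300), semi-arid [300,600), sub-humid [600,1000] mm yr⁻¹),
  per-hectare carbon-density grids and per-zone summaries.
* **crown_eval** — the crown-mapping accuracy protocol: greedy one-to-one
  overlap matching of predicted vs hand-labelled crowns, commission /
  omission error rates by crown-area class, per-tree area RMSE, and
  wet-biased random sampling of evaluation plots.
* **uncertainty** — the propagated error budget: repeated 80/20
  subsampling of the field data gives the relative allometric uncertainty
  δ̄_allometric; the crown-area mapping error δ_area combines with it in
  quadrature, δ = √(δ_area² + δ̄_allometric²).
* **mosaic** — NDVI and the two-round image-selection rules that pick one
  early-dry-season, near-nadir acquisition per tile so no tree is counted
  twice.
* **synthetic** — generators for landscapes (lognormal crown sizes along a
  rainfall gradient), field-allometry samples with known truth, evaluation
  fixtures with planted errors, and image catalogs, so the whole chain is
  testable offline.
* **pipeline / cli** — an end-to-end runner with plain-text I/O (GeoJSON
  crowns, ESRI ASCII-grid rasters, CSV tables, JSON reports).

## Worked example

```sh
sahelcarbon generate --out-dir demo --seed 42
sahelcarbon estimate demo/crowns.geojson --out demo/crowns_carbon.geojson
sahelcarbon aggregate demo/crowns_carbon.geojson demo/rainfall.asc --out-dir demo
```

prints

```
wrote 22880 crowns and inputs to demo
22880 trees, total carbon 2068.73 Mg C -> demo/crowns_carbon.geojson
hyper-arid:      90 trees,   39.5 kg C/tree,  0.02 Mg C/ha,   0.2% of carbon
      arid:    1290 trees,   61.2 kg C/tree,  0.53 Mg C/ha,   3.8% of carbon
 semi-arid:    6300 trees,   73.3 kg C/tree,  1.54 Mg C/ha,  22.3% of carbon
 sub-humid:   15200 trees,  100.3 kg C/tree,  3.81 Mg C/ha,  73.7% of carbon
```

The demo landscape is 2,000 ha under a linear 0→1,000 mm yr⁻¹ west–east
rainfall gradient.  Mean per-tree stocks rise from ~40 kg C in the
hyper-arid zone to ~100 kg C in the sub-humid zone, and carbon density
rises from 0.02 to 3.8 Mg C ha⁻¹ — the hallmark pattern of dryland tree
carbon concentrating in the wetter zones.  The evaluation protocol and the
uncertainty budget run the same way:

```sh
sahelcarbon evaluate                  # planted-error fixture round trip
sahelcarbon uncertainty demo/field_samples.csv --delta-area 0.033
```

```
commission 4.9%, omission 2.7%, net 2.2%
Carbon uncertainty budget
  allometric (mean of 10 reps): 22.8%
  crown-area mapping:             3.3%
  combined (quadrature):          23.1%
```

(The allometric figure is a stochastic subsampling estimate; across seeds
it scatters around ~19.5% with a spread of about ±3 percentage points.)
`sahelcarbon run-all --out-dir out --seed 1` chains every stage and writes
`report.json` plus all intermediate products.

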
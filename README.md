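# mangrove-typology

A tested re-implementation of a global biophysical mangrove typology
pipeline. Starting from a coastline, river network, watershed polygons and
a handful of rasters, it:

1. **Delineates coastal embayment polygons (CEPs)** — indents in the
   coastline — by morphological closing of the land and Euclidean
   allocation of contested water to the nearest mouth (`cep_builder`).
2. **Computes ten per-CEP covariates** spanning polygon shape, upstream
   catchment (aggregated whole watersheds with network-upstream closure),
   and network-routed monthly precipitation (`cep_covariates`).
3. **Classifies CEPs geomorphically**: deltas by a drainage-outlet rule
   (>2 sea outlets) plus a configured list, then a two-pass random forest
   for bay/estuary/lagoon with a review-and-correct loop
   (`geomorphic_classifier`).
4. **Attributes every mangrove patch to exactly one typological unit**
   (deltaic / estuarine / lagoonal / open coast) by splitting straddling
   patches along allocation boundaries, direct intersection, catchment
   containment, and distance fallback (`patch_assigner`).
5. **Classifies sedimentary setting** (terrigenous vs carbonate) with a
   binomial GLM of M2 tidal amplitude and mean inorganic suspended
   particulate matter; deltaic/estuarine units are terrigenous by
   definition (`sedimentary_classifier`).
6. **Accounts for extent change** by type x region x timestep, with
   shares, percent changes and loss rankings (`extent_change`).
7. **Analyses above-ground biomass** per unit with a heteroscedastic
   (per-type variance) one-way model of sqrt(mean AGB), ML-fitted, with a
   Wald F test, Nagelkerke pseudo-R², Tukey-adjusted pairwise contrasts
   and a compact letter display (`agb_analysis`).

Because the real input datasets are external and large, the package ships a
first-class **synthetic coastal world** (`synthetic_world`): planted
embayments of known class with class-dependent geometry (funnel estuaries,
near-closed lagoons, protruding delta fans with distributaries), mangrove
fringes, per-type extent loss applied cell-by-cell across timesteps,
logistic structure in the tide/SPM fields, and planted per-type AGB means.
Every downstream stage is tested against this ground truth.

All geometry lives in a planar equal-area frame with km units. Vector I/O
is GeoJSON; raster I/O is ESRI ASCII grid (single band) or TIFF with a JSON
geotransform description (multi-band).

## CLI

```bash
mangrove-typer simulate  --config config.yaml --seed 1 --out out   # scene only
mangrove-typer run-all   --config config.yaml --seed 1 --out out   # full pipeline
mangrove-typer build-ceps|covariates|classify|assign|sediment|change|agb ...
```

Each command takes `--config PATH --seed INT --out DIR`, logs stage timings
to stderr, exits 0 on success and 2 on validation failure. `run-all` writes
the scene plus `ceps.geojson`, `covariates.csv`, `labels.csv`, `units.csv`,
`units.geojson`, `change_table.csv`, `shares.csv`, `changes.csv`,
`losses.csv`, `sediment_model.json` and `agb_model.json`. The config file
is a flat YAML rendering of `SceneConfig` (see
`src/mangrove_typology/synthetic_world.py` for all keys and defaults).

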
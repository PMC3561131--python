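# snakerisk

Small-area snakebite risk mapping and antivenom treatment accessibility
analysis, driven entirely by a synthetic-world generator so every stage is
testable offline.

The pipeline mirrors a geospatial epidemiology workflow:

1. **synthetic_world** — generates a district lattice with queen adjacency,
   per-district covariates and populations, spatially correlated case counts
   from a Poisson log-linear model with an intrinsic CAR field, individual
   case records (with injected duplicates), and a raster world (elevation,
   land class, road network, biotic units) with facility / ambulance-station
   / census-centroid point sets.
2. **disease_mapping** — Bayesian Poisson regression with intrinsic Besag CAR
   spatial random effects, fitted by an adaptive Metropolis-within-Gibbs
   sampler; produces smoothed annual incidence per 100,000, incidence-ratio
   summaries with 95% credible intervals, and threshold-exceedance
   probabilities (default threshold 30 per 100,000 per year).
3. **smoothing_eval** — compares raw incidence, model exceedance probability
   (method A) and Marshall local empirical-Bayes smoothing (method B) by
   their ability to predict future high-incidence districts (ROC/AUC with
   Hanley–McNeil SEs and empirical CIs), plus sensitivity-targeted cutoff
   calibration.
4. **risk_overlay** — case-record deduplication, mean imputation, the habitat
   rule (below 1,200 m in Moist/Wet/Pluvial biotic units), 2 km populated-
   area buffers, and combination of incidence- and habitat-based risk.
5. **travel_time** — slope-penalized cost surface
   (`t = (cell/cos α)/v + β·α²`), multi-source accumulated travel time from
   ambulance stations and from hospitals/clinics (8-connected Dijkstra),
   their sum as total ambulance time, zonal extraction, and <2 h / 2–3 h /
   >3 h categorization.
6. **cli_pipeline** — orchestration with YAML config, per-stage seeds, and a
   checksummed run manifest.

## CLI

```bash
snakerisk run-all --out runs/demo --seed 42            # defaults end to end
snakerisk run-all --config cfg.yaml --out runs/x --seed 7
snakerisk simulate --out runs/x --seed 7               # single stage
snakerisk rerun --manifest runs/x/manifest.json --out runs/y
```

`--paper-scale` raises the MCMC to 50,000 + 50,000 iterations. Stages:
`simulate, clean, fit, evaluate, habitat, traveltime, overlay, report`;
each stage reads only files written by earlier stages into the run
directory, so stages can be re-run individually.

Config is YAML (JSON also parses); any subset of keys may be given and the
rest default; unknown keys are rejected. Example:

```yaml
world:
  lattice_rows: 8
  lattice_cols: 8
  n_years: 18
mcmc: {n_burn: 2000, n_keep: 2000, n_chains: 2}
exceedance_cutoff: 0.10
incidence_threshold: 30.0
seed: 42
```

Outputs are text formats only: CSV tables, GeoJSON vector layers, ESRI
ASCII grid rasters, JSON summaries, and `manifest.json` with a SHA-256
checksum for every file written.

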
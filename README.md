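# abyssrange

Analysis pipeline for widely distributed deep-sea taxa: per-locus
population-genetic summaries (haplotype/nucleotide diversity, segregating
sites, Tajima's D with beta-approximation significance), corrected genetic
distances (raw p, JC69, F81), statistical-parsimony haplotype networks,
a distance-threshold species-partition sweep scored by the barcode gap, and
a depth-envelope habitat projection over gridded bathymetry yielding
per-ocean-basin suitable-area percentages.

A synthetic-data module (neutral coalescent sequence simulator with known
theta, analytic latitude-band bathymetry, parametric occurrence records)
makes every stage testable offline.

## Test

```
python -m pytest -q tests/
```

One acceptance test (`test_t2_indian_percent`) fails by design: the
published percentage cell it encodes was truncated rather than rounded in
the source table, while this package's contract is round-half-even at two
decimals. See the test docstring.

## CLI

```
abyssrange records summarize records.csv
abyssrange popgen stats aln.fasta --locality locality.csv
abyssrange popgen distances aln.fasta --model F81 --freqs 0.269 0.213 0.173 0.345 --out dist.csv
abyssrange popgen network aln.fasta --locality locality.csv --threshold 0.95 --out-prefix net
abyssrange popgen delimit aln.fasta --model JC69 --out-prefix parts
abyssrange habitat project bathy.nc --envelope 3890 8931 --out report.csv
abyssrange simulate seqs --n 20 --length 600 --theta 5 --seed 1 --out sim.fasta
abyssrange simulate grid --resolution 1.0 --out bathy.nc
abyssrange simulate records --n-records 195 --n-sites 75 --out recs.csv
abyssrange run config.yaml
```

Exit codes: 0 success, 2 validation/configuration error, 3 stage error.
A full run writes a `manifest.json` (input hashes, seed, stage outputs,
timings) next to the stage outputs.

`config.yaml` keys: `output_dir` (required), `records_path`,
`alignment_path`, `locus`, `locality_path` (CSV `id,locality`),
`bathymetry_path` (netCDF with `elevation` and `basin_code` variables),
`deletion_mode` (`complete`/`pairwise`), `distance_model` (`JC69`/`F81`),
`base_frequencies` (list `[piA, piC, piG, piT]`), `network_threshold`,
`mc_reps`, `seed`, `envelope` (`[d_min, d_max]` in metres), `stages`
(subset of `records, popgen, distances, network, delimitation, habitat`).

## Input formats

* **Occurrence records** — CSV with columns `site_id, feature, basin, lat,
  lon, depth_m, record_type` (optional `source_ref, n_individuals`);
  header names remappable via `column_map`.
* **Sequences** — aligned FASTA, equal lengths; site filtering defaults to
  complete deletion (drop any column with gap/N/ambiguity in any sequence).
* **Bathymetry** — netCDF-3 (lat/lon cell centres, `elevation` in metres,
  negative below sea level, optional integer `basin_code` raster with a
  legend attribute). `abyssrange simulate grid` writes this dialect.

## Area accounting

Cell areas are computed analytically on the sphere (authalic radius
6371.0088 km): `R^2 * dlon_rad * (sin lat_top - sin lat_bottom)`, which is
exactly what any equal-area projection computes and is testable against
closed forms (whole sphere `4*pi*R^2`, 0-30 deg zone `pi*R^2`). Percentages
are rounded half-even at two decimals.

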
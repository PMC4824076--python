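# qpid

Quantitative protein–DNA affinity analysis toolkit: a tested, reusable
pipeline from microfluidic-chip scan tables through fluorescence
calibration, equilibrium dissociation-constant (Kd) estimation with
censoring, pentamer-based DNA shape features, genomic binding-site library
design, and shape-feature regression models of affinity and affinity
differences.  A fully seeded synthetic-data module stands in for the
microfluidic device and for genomic peak downloads, so the entire analysis
is reproducible offline.

## Modules

| module | what it does |
| --- | --- |
| `qpid.chipsim` | synthetic scan tables (64×64 chamber chips, mass-action equilibrium with ligand depletion, realistic noise), synthetic genomes with planted CRE / CRE half-sites plus ChIP/DNase peak files, synthetic pentamer shape tables, planted regression ground truth |
| `qpid.quantify` | scan-table I/O, linear fluorescence calibration (fit + inversion), background-corrected bound-DNA/protein occupancy ratios, replicate aggregation |
| `qpid.affinity` | binding-series assembly, nonlinear least-squares isotherm fits with multi-start initialization and sensitivity censoring (1 nM – 50 μM), group summaries (mean ± population SD), affinity differences, rank tests |
| `qpid.shape` | pentamer-table shape prediction (MGW/ProT/Roll/HelT), 4(2k+w)-long feature vectors, reference profiles, normalized Euclidean distances, exact binomial concordance test |
| `qpid.sitelib` | motif scanning in both orientations, 200 bp first-site windows, full-site-in-flank exclusion, bound/unbound categorization against ChIP/DNase peaks, seeded library sampling |
| `qpid.shapemodel` | design matrices over flank shape features, OLS affinity / affinity-difference models, standardized-coefficient feature ranking |
| `qpid.cli` / `qpid.pipeline` | `qpid` command-line interface and end-to-end orchestration with per-stage derived seeds |

## CLI

```bash
qpid run --seed 1 --out-dir runs/demo        # full pipeline, all artifacts
qpid report runs/demo                        # regenerate the report

# individual stages
qpid simulate-chip --seed 1 --out-dir chip/
qpid calibrate --in points.tsv --out curve.json
qpid quantify --scan chip/scan.tsv --curve curve.json --out occupancy.tsv
qpid fit --occupancy occupancy.tsv --out kd.tsv
qpid simulate-genome --seed 1 --out-dir genome/
qpid design-library --genome genome/genome.fa --chip-a genome/chip_a.narrowPeak \
    --chip-b genome/chip_b.narrowPeak --dnase genome/dnase.narrowPeak \
    --site half --quota 34,34,34,5 --seed 1 --out lib/
qpid simulate-shape-table --seed 1 --out pentamers.tsv
qpid shape --fasta lib/library.fa --core-start 99 --w 5 --k 10 \
    --table pentamers.tsv --out vectors.tsv
```

Every stochastic stage derives its own substream from the single run seed,
so identical seeds give byte-identical outputs and stages can be re-run in
isolation.

## Data formats

Scan tables, occupancy tables, Kd tables, libraries and shape tables are
tab-delimited text with headers; genomes are FASTA; peaks are narrowPeak
(BED6+4, 0-based half-open).  Chip coordinates and report coordinates are
1-based; everything internal is 0-based.
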
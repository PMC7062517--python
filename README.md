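# dropchim

Droplet scRNA-seq chimerism analysis: determine donor vs recipient origin of
cells in sex-mismatched transplant samples from the sex-exclusive transcripts
XIST (female) and RPS4Y1 (male), starting from raw droplet read records.

The package provides, as composable modules with a shared pipeline:

- **`dropchim.sim`** — simulator for chimeric two-sex droplet experiments
  with known ground truth: Poisson sex-transcript expression (closed-form
  dropout), macrophage marker programs (CD68/MARCO), mitochondrial and
  ribosomal gene fractions, ambient/empty droplets, log-normal library
  sizes, and read-level expansion with Hamming-1 substitution errors in
  barcodes and UMIs.
- **`dropchim.demux`** — cell-barcode whitelist retention/correction
  (quality- and abundance-weighted posterior over Hamming-1 candidates),
  UMI filtering (no homopolymers, all Phred > 10), within-gene UMI merging
  into strictly more prolific Hamming-1 neighbors, and multi-gene collision
  resolution.
- **`dropchim.calling`** — cell calling: nearest-rank 99th percentile of the
  top expected-cell barcode totals; barcodes within an order of magnitude of
  it are retained.
- **`dropchim.qc`** — four-metric (library size, genes detected, % mito,
  % ribo) 3x raw-MAD outlier removal, >20% mito / >50% ribo hard caps,
  <1%-prevalence gene removal, and mitochondrial/ribosomal gene-family
  discard.
- **`dropchim.embed`** — log-normalization (`ln(1 + 1e4 * count/libsize)`),
  deterministic gene-centered PCA, greedy-modularity clustering on a kNN
  graph in PC space.
- **`dropchim.origin`** — per-cell sex calls (count > 0 rule), sex-to-origin
  mapping from sample metadata, optional macrophage marker gating,
  per-sample chimerism summaries, and a dropout-corrected chimerism-fraction
  estimator with Wilson intervals.
- **`dropchim.stats`** — two-sided Mann-Whitney U with exact enumeration
  for m+n <= 12 (tie-aware), and Spearman rank correlation with exact
  permutation p for n <= 8.
- **`dropchim.mmio` / `dropchim.pipeline` / `dropchim.cli`** — Matrix-Market
  triplet I/O (CellRanger-style `matrix.mtx` + `barcodes.tsv` +
  `features.tsv`), YAML run configuration, stage logging, and a subcommand
  CLI.

## CLI

```sh
# simulate a chimeric experiment (counts + truth; --reads adds read records)
dropchim simulate --out out/sim --seed 1 --reads

# demultiplex reads into a count matrix
dropchim demux --reads out/sim/reads.tsv --whitelist out/sim/whitelist.tsv --out out/counts

# call cells, filter, assign origin, summarize
dropchim callcells --counts out/counts --expected-cells 500 --out out/cells.txt
dropchim qc --counts out/counts --cells out/cells.txt --out out/qc
dropchim assign --counts out/qc/filtered --recipient-sex female --donor-sex male --out out/calls.tsv
dropchim summarize --calls out/calls.tsv --recipient-sex female --donor-sex male --out out/summary.json

# or everything at once from a YAML config
dropchim run --config run.yaml --out out/run
```

A minimal `run.yaml`:

```yaml
seed: 1
expected_cells: 1000
samples:
  - sample_id: patient1
    recipient_sex: female
    donor_sex: male
    sim: {n_cells: 1000, chimerism_fraction: 0.9, n_ambient_droplets: 500}
```

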
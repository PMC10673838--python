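# scarscope

Analysis toolkit for double-strand-break (DSB) repair outcomes, built around
six components:

- **`scarscope.junctionscan`** — build predicted blunt-fusion translocation
  products from two parental loci (explicit cuts or Cas9 guides, 17/18 cut
  rule), classify junction reads into deletion / insertion / microhomology
  scars against the predicted product, aggregate per-coordinate
  deletion/MH frequency profiles, and compute well-based translocation
  frequencies.
- **`scarscope.resectmap`** — quantify DNA end resection from END-seq-style
  end-count coverage: find `GCGATCGC` motif sites, bin signal ±20 kb, call
  cut sites by center/flank enrichment, measure per-side resection distance
  from peak width, rank the top resected sites, and emit heatmap matrices.
- **`scarscope.focicount`** — foci counting per nucleus: opening-based
  background subtraction, percentile contrast rescale, Gaussian blur, fixed
  threshold, area-gated particle counting, and ≥k / >k positivity summaries.
- **`scarscope.reporterquant`** — ddPCR Poisson-occupancy inversion, HR%
  and TMEJ reporter scores, and CRISPR clone binning by per-allele
  frameshift status with knockout fractions.
- **`scarscope.crossstats`** — exact multi-locus Mendelian expectations
  (with lethality renormalization, computed in `Fraction` arithmetic),
  chi-square goodness-of-fit and per-genotype binomial tests,
  marker-chromosome normalization to 40 chromosomes, and 4-parameter
  log-logistic IC50 fitting with fold changes.
- **`scarscope.synthcore`** — deterministic, seeded generators producing
  inputs with the statistical structure each stage assumes (junction reads
  with junction-proximal scars, strand-resolved end-count tracks with
  exponential resection endpoints, Mendelian offspring draws with
  genotype-specific lethality, disk-nuclei images with Gaussian foci and
  Poisson noise, droplet positivity, 4PL dose-colony tables) together with
  ground-truth tables for recovery testing. All draws flow from one
  top-level seed through named substreams.

Coordinates are 0-based half-open throughout. File formats are plain text:
FASTA for sequences, 4-column bedGraph for coverage, TSV for tables, YAML
for configs, single-channel 16-bit TIFF for images.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracles (anchored-decomposition enumeration
for scar calls, sliding-window motif scans, per-base bin recounts,
exhaustive gamete enumeration) and property tests (hypothesis) alongside
`tests/test_acceptance.py`, which implements the ten acceptance criteria at
their stated tolerances.

## CLI

Every stage is reachable through the `scarscope` entry point:

```bash
# simulate inputs + truth tables
scarscope simulate junctions --config junctions.yaml --seed 7 --out sim/
scarscope simulate endseq    --config endseq.yaml    --seed 7 --out sim/
scarscope simulate cross     --config cross.yaml     --seed 7 --out sim/
scarscope simulate foci      --config foci.yaml      --seed 7 --out sim/
scarscope simulate droplets  --config droplets.yaml  --seed 7 --out sim/
scarscope simulate dose      --config dose.yaml      --seed 7 --out sim/

# analyses
scarscope junctions call    --config junctions.yaml --reads sim/reads.fasta --out calls.tsv
scarscope junctions profile --config junctions.yaml --reads sim/reads.fasta --out profile.tsv
scarscope junctions frequency --grid wells.tsv --positivity any
scarscope endseq sites    --genome genome.fasta --out sites.bed
scarscope endseq distance --genome genome.fasta --coverage ends.bedgraph --out distances.tsv
scarscope endseq matrix   --genome genome.fasta --coverage ends.bedgraph --out matrix.tsv
scarscope foci count      --image image.tiff --params foci_params.yaml --out counts.tsv
scarscope reporter hr     --repair 5 --control 100
scarscope reporter tmej   --products products.tsv --reference-sum 20
scarscope reporter clones --alleles alleles.tsv --out bins.tsv
scarscope cross expected  --config cross.yaml
scarscope cross test      --config cross.yaml --counts counts.tsv
scarscope dose fit        --table dose_response.tsv
```

Example junction config:

```yaml
template:
  parent_a: GATTACAGATTACAGATTACAGATTACAGATTACA
  parent_b: CTGCAGTCTGCAGTCTGCAGTCTGCAGTCTGCAGT
  cut_a: 18          # or guide_a: <20-nt protospacer> (NGG PAM required)
  cut_b: 7
params:
  n_reads: 1000
  deletion_size_dist: {name: geometric, mean: 8.0}
  insertion_rate: 0.2
  mh_propensity: 0.5
```

## Conventions worth knowing

- Junction scars: anchors are maximal exact matches; when prefix+suffix
  over-explain a read the excess goes to the prefix. Deletion size
  `d = L − p − s` counts MH bases once. Microhomology is the junction-shift
  ambiguity of the deletion within the predicted product; equivalent
  placements share an identical `mh_span`, so downstream profiles are
  tie-break-invariant. Reads with an `N` within 1 bp of the junction or an
  anchor below `min_anchor` (default 10) are flagged `excluded`.
- Well positivity is configurable (`any`/`all`/`sum`; default: positive in
  ≥1 technical replicate).
- END-seq defaults (250 bp bins, 5× enrichment, 10% height fraction, 3-bin
  smoothing, RPM normalization, combined distance = max of sides) are
  conventions exposed as parameters, not published values.
- Foci positivity supports both `>k` and `≥k` rules, matching the two
  phrasings used for different markers.
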
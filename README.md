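# pamquant

Amplicon deep-sequencing indel quantification, reporter-assay arithmetic,
and Cas12a (Cpf1) PAM-preference profiling — with seeded synthetic data so
the whole pipeline is testable end to end without any external downloads.

## What it does

- **`pamquant.align`** — semiglobal pairwise alignment with affine gaps
  (free end gaps on the reference, the read aligned in full), orientation
  selection against both strands, and the anchor-identity filter: a read is
  kept iff it matches **at least 75 % of the first 20 bp** of the reference
  amplicon (alignment-based identity; the boundary is inclusive).
- **`pamquant.quant`** — cut-site inference (configurable offset from the
  PAM-proximal protospacer end, default 18), insertion/deletion/mismatch
  calls flagged by whether they intersect the closed **±60 bp window**
  around the cut site, read classification (mismatches never count as
  edits), and the per-sample indel frequency
  `(reads with an in-window indel) / (anchor-passing reads)` — the
  all-reads denominator is reported alongside. Samples with fewer than
  1000 total reads are flagged excluded.
- **`pamquant.assay`** — reporter arithmetic: background-subtracted GFxFP
  activity within the mCherry⁺ gate, both GFP-disruption variants
  (`1 − sample/control-mean` and `control-mean − sample`), day-2-normalized
  HDR activity, and notched-boxplot summaries (quartiles = medians of
  halves, Tukey 1.5 · IQR whiskers, notch = median ± 1.58 · IQR/√n).
- **`pamquant.pam`** — per-position base-preference matrices from activity
  panels (per-target sum normalization before unweighted averaging over
  targets), IUPAC consensus calling with a tunable inclusion threshold
  (default 0.15, e.g. `TTTV`, `TWTV`, `TTYV`), IUPAC PAM matching, and
  two-strand target-site enumeration with BED6 output.
- **`pamquant.simulate`** — seeded simulators for edited amplicon reads
  (FASTQ + ground-truth table), reporter plates, and PAM activity panels.
  Identical seeds give byte-identical outputs.
- **`pamquant.cli`** — `simulate`, `quantify`, `assay`, `profile`,
  `pamscan`, and a config-driven `run` chain that writes a reproducibility
  manifest (config hash + output checksums).

Coordinates are 0-based half-open internally; emitted reports are 1-based
inclusive and say so in their headers (BED output stays 0-based half-open).

## CLI

Reference amplicons are FASTA records whose header carries the site
annotation in 1-based inclusive coordinates:

```
>ampA protospacer=101..123 pam=97..100 strand=+
```

Examples:

```sh
# synthetic sample + quantification + PAM panel + consensus, one config:
pamquant run --config config.yaml --out-dir out/

# individual stages:
pamquant quantify --ref ref.fasta --reads reads.fastq \
    --cut-offset 18 --window 60 --min-reads 1000 --out-dir out/
pamquant assay --mode disruption-ratio --table plate.csv --out out.tsv
pamquant profile --activities panel.tsv --threshold 0.15 --out-dir out/
pamquant pamscan --fasta genome.fa --pattern TTTV --out sites.bed
```

A minimal `run` config:

```yaml
seed: 7
simulate_reads:
  n_reads: 2000
  indel_rate: 0.2
quantify:
  min_reads: 1000
simulate_panel:
  weights:
    -4: {T: 1.0, C: 0.02, A: 0.02, G: 0.02}
    -3: {T: 1.0, C: 0.02, A: 0.02, G: 0.02}
    -2: {T: 1.0, C: 0.02, A: 0.02, G: 0.02}
    -1: {A: 1.0, C: 1.0, G: 1.0, T: 0.02}
  n_targets: 12
profile:
  include_threshold: 0.15
```

Unknown config keys are rejected by name; rerunning with the same config
and seed reproduces every output byte for byte.

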
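# pss-screen

Detection of transposase signal sequences at structural-variant breakpoints,
with the statistics of a forward genetic screen, exercised end to end on a
synthetic single-gene locus with planted inverted-terminal-repeat elements.

The package has five library modules and a CLI:

- `pss_screen.genome_io` — locus/interval/variant data model; FASTA, BED,
  BEDPE, and small-variant (TSV / minimal VCF 4.2) readers and writers;
  reverse complement; amplicon tiling. Coordinates are 0-based, half-open
  everywhere; BEDPE anchors are single-base intervals at the first and last
  rearranged base.
- `pss_screen.synthetic_data` — seeded simulator: a ~43 kb locus with nine
  exons, two SV cohorts (case/control), inward-planted elements with GGG
  breakpoint-proximal termini, per-copy substitution noise, and windowed
  small-variant counts with an exonic boost under selection. Includes a truth
  table for recovery tests.
- `pss_screen.pss_detection` — the detection criteria: best ungapped inverted
  alignment of breakpoint flanks (identity >= 50% within 3 bp of the
  breakpoints), rejection of candidates with homopolymer/tandem tracts longer
  than 5 bp, and subtraction of alignments resembling any passing control-
  cohort alignment. Also classifies inactivating (exon-disrupting)
  rearrangements and summarizes cohorts.
- `pss_screen.motif_analysis` — breakpoint-anchored (right-justified)
  stacking of candidates, position-frequency matrices, per-column information
  content in bits, terminal k-mer / T-content composition, and both-strand
  occurrence scanning.
- `pss_screen.screen_stats` — mutational frequency ln(X_S/N_S)/ln(X_0/N_0),
  clonogenic efficiency, the exact Poisson rate-ratio test (conditional
  binomial, minlike two-sided p, Clopper–Pearson-backed CI), the exact
  binomial enrichment test, 40-bp windowed variant profiles, and
  exonic/intronic region comparisons.

## CLI

The `pss-screen` command has subcommands `simulate`, `detect`, `motif`,
`stats`, `report`, and `demo`. A full, reproducible end-to-end run on a
bundled synthetic fixture:

```sh
pss-screen demo --seed 7 --out runs/demo
```

which writes the locus FASTA, exon BED, cohort BEDPE files, truth table,
candidate TSV/FASTA, logo TSV, composition JSON, test-result JSON, a collated
`report.json`/`report.txt`, and a `manifest.json` of SHA-256 checksums (byte-
identical across reruns with the same seed). Individual stages:

```sh
pss-screen simulate --config config.yaml --out runs/x
pss-screen detect --locus runs/x/locus.fasta --exons runs/x/exons.bed \
    --case runs/x/case.bedpe --control runs/x/control.bedpe --out runs/x
pss-screen motif --candidates runs/x/candidates.tsv --out runs/x
pss-screen stats --locus runs/x/locus.fasta --exons runs/x/exons.bed \
    --case runs/x/case.bedpe --control runs/x/control.bedpe \
    --variants-a runs/x/variants_unselected.tsv \
    --variants-b runs/x/variants_selected.tsv --out runs/x
pss-screen report --run-dir runs/x
```

Exit code 2 signals a validation error (bad config, missing seed, malformed
input). Omitting `--control` from `detect` disables control subtraction with
a prominent warning.

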
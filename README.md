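# tebias

Analysis pipeline linking transposable-element (TE) insertions within gene
bodies to homoeolog expression bias in allopolyploid genomes with three
subgenomes (A/B/D), plus a synthetic-data generator so every stage is
testable without external downloads.

The pipeline:

1. **annotations_io** — parse gene models (GFF3/TSV), TE annotations with
   ClariTeRep-style subfamily names and a `repeat_region` status filter,
   homoeolog-group tables, and a five-region chromosome partition
   (R1/R2a/C/R2b/R3; proximal = R2a∪C∪R2b, distal = R1∪R3).
2. **overlap** — TE-in-gene calls by interval intersection (≥ 1 shared base,
   1-based inclusive coordinates) for gene bodies, exons, and 5'/3' UTRs,
   backed by `pyranges`.
3. **groups** — dyads/triads/tetrads; a group is *monomorphic* when every
   member gene carries a TE insertion, *polymorphic* when some but not all do.
4. **expression** — per-triad normalized expression proportions and
   nearest-centroid assignment to seven categories (balanced, A/B/D dominant,
   A/B/D suppressed), with dyad/tetrad generalizations.
5. **stats** — conditional-binomial null for morphism counts with a
   chi-square goodness of fit, contingency tests (Yates correction for 2×2),
   and TE-superfamily/subfamily association screens with a ≥ 5-per-cell
   filter and Benjamini–Hochberg correction per screen family.
6. **enrichment** — GO singular enrichment analysis (one-sided Fisher) of
   triad sets against the eligible-triad background, FDR per GO domain.
7. **simulate** — seeded synthetic genomes/TEs/groups/expression/GO with
   planted effects and a truth ledger; includes calibration and
   parameter-recovery utilities.
8. **cli** — `tebias` command orchestrating all stages from a YAML config.

## CLI

Generate a synthetic dataset and run the full pipeline on it:

```sh
tebias simulate --seed 1 --n-triads 2000 --out sim/
cat > config.yaml <<EOF
genes: sim/genes.gff3
tes: sim/tes.gff3
groups: sim/groups.tsv
regions: sim/regions.tsv
expression: sim/expression.tsv
gene_to_go: sim/gene_to_go.tsv
output_dir: out/
thresholds: {expression_floor: 0.5, min_tissues: 6, min_cell: 5, fdr: 0.05}
EOF
tebias run-all --config config.yaml
```

Outputs (TSV with `#` metadata headers): per-gene TE content, group
morphism table, observed-vs-expected morphism report (overall and
region-stratified), triad categories, association screen tables per
TE level × comparison, and GO enrichment tables. Stage subcommands
(`annotate-overlaps`, `classify-groups`, `assign-categories`, `screen`,
`enrich`) run subsets of the pipeline.

## Notes

- Coordinates are 1-based inclusive everywhere (GFF3 convention); TSV
  dialects are documented on the reader functions.
- The plug-in estimator for the per-gene TE probability (estimated from
  TE-containing groups only) is upward-biased under the ≥ 1-insertion
  conditioning; `tebias.simulate.gof_calibration` exposes both the biased
  plug-in variant and the exactly calibrated known-p variant.
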
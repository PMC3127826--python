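# stripemeth

Analysis toolkit for promoter methylation assays of the kind used to link
fruit-peel pigment striping to differential promoter methylation of an
anthocyanin-pathway MYB transcription factor:

- **McrBC/qPCR percent methylation** — delta-Ct estimator
  `%M = 100 × (1 − E^−(Ct_McrBC − Ct_mock))` with standard-curve efficiency
  calibration, replicate/digestion aggregation, negative-value clamping,
  low-template QC flags, Welch group comparison and sample-size estimation.
- **Bisulfite Sanger-clone analysis** — conversion-aware clone alignment,
  per-cytosine methylation calls, CG/CHG/CHH context classification,
  per-position/per-context/per-clone summaries, green-vs-red stripe
  comparison, degenerate-primer bias checking and motif-level methylation.
- **Efficiency-corrected relative expression** — Pfaffl-form ratios
  normalized to a reference gene, with SE propagation and one-sided
  ratio-greater-than-one tests.
- **Sequence features** — IUPAC motif scanning (e.g. the E-box `CACATG`),
  McrBC purine-C half-site enumeration, eligible cut-pair counting
  (40–3000 bp separation) and pairwise percent identity.
- **Synthetic data** — generators for references with embedded motifs,
  per-context methylation mosaics with regional blocks and stripe offsets,
  bisulfite clone pools, McrBC-digested molecule pools and noisy Ct
  tables, so every estimator can be validated by parameter recovery.

Coordinates throughout are ATG-relative with no position zero
(`…, −2, −1, +1, +2, …`; `+1` is the A of the start codon).

## CLI

```bash
stripemeth run --config examples/demo.yaml --out results/      # full pipeline
stripemeth simulate --config examples/demo.yaml --out results/ # synthetic data only
stripemeth mcrbc --ct ct.tsv --efficiency 1.9 --compare green:red
stripemeth bisulfite --fasta ref.fa --atg-offset 2850 \
    --fragment -1007:-684 --clones green green.fa --clones red red.fa
stripemeth expr --ct expr.tsv --ref-gene actin --compare red:green
stripemeth features --fasta promoter.fa --atg-offset 2850 \
    --motif CACATG --region -1411:-555
stripemeth report --results results/
```

The demo config (`examples/demo.yaml`) simulates a 3.2 kb promoter with a
hypermethylated block, embedded E-boxes and a green-vs-red stripe offset,
then runs every stage; it completes in well under two minutes. All result
TSVs carry a provenance header (version, config hash, seed) and a run is
byte-reproducible given config + seed.

Ct tables are TSV with columns
`sample  fragment  treatment  replicate  ct` (optional `digestion`);
treatments are `mcrbc`/`mock`, missing Ct is `NA`, no-amplification is
`inf`. Clone FASTAs use `>sample|clone_id` headers.

## Layout

| module | contents |
| --- | --- |
| `stripemeth.coords` | `ReferenceRegion`, `AmpliconFragment`, ATG-relative coordinate conversion |
| `stripemeth.io` | Ct-table / FASTA / result-TSV I/O |
| `stripemeth.simulate` | synthetic references, profiles, clones, molecule pools, Ct tables |
| `stripemeth.mcrbc` | efficiency calibration, percent-methylation estimator, aggregation, tests |
| `stripemeth.bisulfite` | clone alignment, context classification, calls, summaries, comparisons |
| `stripemeth.expression` | efficiency-corrected ratios and significance tests |
| `stripemeth.features` | motif scanning, McrBC half-sites/pairs, pairwise identity |
| `stripemeth.pipeline` / `stripemeth.cli` | YAML-config orchestration and the `stripemeth` command |
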
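# cnvclassify

Automated clinical classification of copy-number variants (CNVs) under the
2019 ACMG/ClinGen scoring rubrics.

Clinical labs now call deletions and duplications in batches of exomes and
genomes, but assigning each variant one of the five clinical tiers — Benign,
Likely benign, Uncertain significance, Likely pathogenic, Pathogenic — is
slow when done by hand. `cnvclassify` automates the machine-checkable part
of the rubrics: for every CNV it evaluates

* **Section 1 — genomic content**: ≥ 1 bp overlap with protein-coding or
  noncoding genes, enhancers or promoters (`1A`, else `1B` −0.60);
* **Section 2 — dosage sensitivity**: complete or partial overlap with
  curated haploinsufficient (HI) or triplosensitive (TS) genes/regions
  (curation score 3 required), strand-aware breakpoint geometry for
  partially deleted HI genes (`2C`–`2E` sub-criteria), established benign
  CNV regions (`2F`/`2G` and the gain-side gene-content comparisons), and
  predicted haploinsufficiency (DECIPHER HI index ≤ 10 %, gnomAD pLI ≥ 0.9,
  LOEUF upper bound < 0.35 → `2H` +0.15);
* **Section 3 — gene count**: protein-coding genes overlapped, binned
  (losses: 25–34 → +0.45, ≥ 35 → +0.90; gains: 35–49 → +0.45, ≥ 50 → +0.90);
* **Section 4 — population frequency**: same-type population CNVs covering
  ≥ 80 % of the query; mean frequency > 1 % fires `4O` (−1.00).

Points are summed in exact decimal arithmetic and mapped to the five tiers
(≥ 0.99 Pathogenic; 0.90–0.98 Likely pathogenic; −0.89–0.89 Uncertain;
−0.98 – −0.90 Likely benign; ≤ −0.99 Benign). Criteria requiring case-level
or phenotype evidence are deliberately left to the clinician; the report
carries the full evidence breakdown and gene lists for that follow-up.

## Worked example

The package ships a synthetic-data generator that writes a complete
annotation bundle (genes with exon structure, regulatory elements, dosage
curations, predictor scores, population CNVs), so the tool runs with no
downloads:

```bash
python - <<'EOF'
from cnvclassify import FixtureSpec, generate_bundle
generate_bundle(FixtureSpec(seed=1), "demo_db", build="GRCh38")
EOF

printf 'chr1\t3480000\t3530000\tDEL\nchr1\t400000\t450000\tDEL\n' > demo.bed
cnvclassify --infile demo.bed --GenomeBuild GRCh38 --db-dir demo_db \
            --outdir demo_out --precise
```

`demo_out/classifications.tsv` then contains (criterion columns abridged):

```
VariantID                Classification          Total_score  Loss_1A  Loss_1B  Loss_2A  Known_dosage_genes  Protein_coding_genes
chr1_3480000_3530000_DEL Pathogenic              1.00         0.00              1.00     HIG3(HI)            HIG3
chr1_400000_450000_DEL   Uncertain significance  -0.60                 -0.60
```

The first deletion completely contains the established haploinsufficient
gene `HIG3`: criterion `2A` awards +1.00 and the total of 1.00 crosses the
0.99 Pathogenic threshold. The second falls in a feature desert: `1B`
contributes −0.60, which stays inside the Uncertain band.

The same pipeline is available as a library
(`cnvclassify.evaluate_cnv(cnv, bundle, rubric)` returns the evidence list,
exact total and tier), and all point values and thresholds are editable
configuration (`--rubric-config`, YAML; defaults in
`src/cnvclassify/data/acmg_cnv_rubric.yaml`).

## Layout

```
src/cnvclassify/
  intervals.py       half-open interval arithmetic, breakpoint geometry, indexing
  annotation_db.py   typed readers/writers for the five databases per build
  rubric_config.py   criterion points, gene-count bins, tier thresholds (YAML)
  loss_scorer.py     loss rubric sections 1-4 (sections 1/3/4 shared with gains)
  gain_scorer.py     gain-specific section 2 and the gain walk
  classifier.py      exact decimal totaling, five-tier mapping, result assembly
  cli_report.py      BED input, versioned TSV report, `cnvclassify` entry point
  fixtures.py        synthetic bundles + hand-scored scenario test sets
```

Database schemas and the updater hook are documented in
`annotation_db.py` and `scripts/update_clingen.sh`; the scientific choices
and limitations are in `docs/methods.md`.
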
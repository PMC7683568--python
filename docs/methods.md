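# Methods

## The procedure

`cnvclassify` scores each copy-number variant (deletion or duplication)
against the 2019 ACMG/ClinGen CNV scoring rubrics and maps the summed
points to the five-tier clinical classification. The walk is strictly
sequential and always completes: even when a benign or pathogenic total is
already inevitable, all four automatable sections are evaluated so that the
report carries the full evidence picture.

1. **Genomic content.** Any ≥ 1 bp overlap with a gene (coding or
   noncoding) or a regulatory element (enhancer/promoter) fires `1A`
   (0 points); a feature desert fires `1B` (−0.60).
2. **Dosage sensitivity.** Curated haploinsufficient (loss side) or
   triplosensitive (gain side) genes and regions count only at curation
   score 3 — the 0/1/2 evidence levels and the 30 ("autosomal recessive")
   and 40 ("dosage sensitivity unlikely") dialect codes never establish
   dosage sensitivity. Complete containment fires `2A` (+1.00); a partially
   overlapped region fires `2B` (0). Partially deleted HI *genes* are
   resolved by breakpoint geometry (below). Established benign CNV regions
   drive the negative criteria: a deletion fully inside one fires `2F`
   (−1.00), any other overlap `2G` (0); the gain side compares *gene
   content* (`2C`–`2G`). If no established HI feature overlaps a deletion,
   predicted haploinsufficiency (all three of: DECIPHER HI index ≤ 10 %,
   gnomAD pLI ≥ 0.9, LOEUF upper bound < 0.35 — the first two inclusive,
   the third strict) fires `2H` (+0.15) once, however many genes qualify.
3. **Gene count.** Protein-coding genes with ≥ 1 bp overlap, mapped through
   type-specific bins: losses 0–24/25–34/≥ 35 → 0/+0.45/+0.90; gains
   0–34/35–49/≥ 50 → 0/+0.45/+0.90.
4. **Population frequency.** Only for CNVs overlapping no established
   dosage-sensitive feature. Population CNVs of the same type whose overlap
   covers ≥ 80 % of the query length (inclusive) are pooled across sources;
   if their arithmetic mean frequency exceeds 1 % (strict), `4O` (−1.00)
   fires. Coverage and frequency comparisons use exact rational arithmetic
   so both printed boundaries are sharp.

Totals are summed as exact decimals and mapped to tiers at
≥ 0.99 / ≥ 0.90 / ≤ −0.99 / ≤ −0.90, everything between being Uncertain
significance. The bands are 0.01 apart, which is why the score path never
touches binary floating point.

## Breakpoint geometry for partially affected HI genes

Coordinates are 0-based half-open throughout (BED convention). A CNV
endpoint counts as inside a feature only under *strict* interior
containment: a deletion ending exactly where a gene starts removes none of
it. Orientation is strand-aware — the 5' end of a minus-strand gene is its
higher-coordinate edge.

For a deletion removing the 5' end of an established HI gene, involvement
of coding sequence fires `2C-1` (+0.90), a 5'-UTR-only loss `2C-2` (0).
On the 3' side: 3'-UTR-only → `2D-1` (0); only the last exon's coding bases
→ `2D-2` (+0.90) when the database flags established pathogenic variants in
that exon, else `2D-3` (+0.30); additional coding exons → `2D-4` (+0.90).
Both breakpoints inside the gene is an intragenic deletion (`2E`). When
several HI genes are partially overlapped, each is evaluated and the single
highest-scoring sub-criterion is kept — the rubric scores evidence
categories, not per-gene sums; the per-gene calls are logged.

Duplication breakpoints inside genes fire the gain-side family: both
endpoints inside the same established HI gene → `2I`; one endpoint inside
an established HI gene → `2J`; an endpoint inside a gene of no established
dosage sensitivity → `2L`. `2K` (one breakpoint in an HI gene *with a
highly specific patient phenotype*) requires phenotype input and is
therefore not part of the automatable configuration.

**Conservative defaults.** The reading-frame consequence of an intragenic
event is unknowable from coordinates alone, so `2E` and `2I` default to 0
points rather than the frame-dependent positive options. With imprecise
breakpoints (the default; `--precise` asserts exact coordinates) all
geometry-dependent sub-criteria resolve to the 0-point member of their
family (`2C-2`, `2D-1`, `2J`), while full-containment criteria (`2A`, `2F`,
`2H` gain) still fire. A dosage-curated gene lacking a usable gene model
likewise falls back to the 0-point sub-value with a logged warning. The
bias is deliberate: when in doubt, stay in the Uncertain band.

## Configuration

All point values, gene-count bins, tier thresholds and the two population
parameters live in one YAML file
(`src/cnvclassify/data/acmg_cnv_rubric.yaml`, schema-versioned); a guideline
revision is a config edit, and the loader rejects incomplete tables, broken
threshold ordering, or malformed bins by name. Gene membership for the
predicted-HI lookup is ≥ 1 bp overlap, consistent with the module-wide
content rule; `annotation_db.genes_overlapping(..., containment="full")`
provides the stricter alternative for callers who want it.

## Databases

Five TSV-with-BED-prefix files per genome build (GRCh37/GRCh38 accepted;
coordinates must already be in the declared build — no liftover is
performed): gene models with exon structure and CDS, regulatory elements,
dosage curations, per-gene predictor scores, and population CNVs with
frequencies. Exact column orders are documented and enforced in
`annotation_db.py`; malformed lines abort with file and line number. Benign
CNV regions are carried in the dosage file via the score-40 dialect
("dosage sensitivity unlikely"): hi_score 40 marks an established
benign-loss region, ts_score 40 a benign-gain region. This keeps a single
curation file while giving the benign-overlap criteria a data source.
`scripts/update_clingen.sh` documents, but does not perform, the refresh of
the curated lists.

## The synthetic-data generator

`fixtures.py` emulates the annotation landscape the scorers consume, not
any population-genetic reality. chr1 carries 45 fixed scenario blocks, one
engineered boundary case per 1 Mb block — an HI gene to be contained or
truncated at each geometric variant, benign regions with controlled gene
content, population CNVs placed exactly at the 80 %-coverage and
1 %-frequency boundaries, 25/30/35/50-gene clusters at the bin edges —
using a standard 10 kb test gene (5 exons, CDS from +500 to +9500). chr2
carries seed-dependent random filler (2–10 exons per gene, both strands,
mixed dialect dosage scores, predictor rows with missing values) that can
never touch chr1 scenarios. Each scenario's expected evidence list, total
and tier were derived by hand from the rubric tables when the scenario was
written and are stored as literal data with a worked note; the generator
never calls the scorers, so the end-to-end comparison is an oracle test,
not a snapshot.

What passing therefore shows: the implementation applies every automatable
criterion, boundary and precedence rule exactly as specified, at realistic
coordinate scales. What it does not show: performance or concordance on
real curated databases, whose content is messier (overlapping transcripts,
partial curations, frequency ascertainment differences), and nothing about
the phenotype-dependent criteria the tool deliberately leaves to
clinicians. Likely benign is reachable only through score combinations the
automatable subset rarely produces; the fixture set exercises that band at
the classifier level rather than through a scenario.

## Numerical and determinism choices

* Interval overlap uses an interval-tree index; its exact equivalence to a
  brute-force double loop on ≥ 1000 seeded random features × 1000 queries
  is asserted in the acceptance suite.
* Evidence order is fixed (rubric order; ties broken by coordinates, then
  identifiers), database serialization is canonically sorted, and all
  randomness is seeded, so repeated runs are byte-identical.
* Problem sizes in the tests and the acceptance script (45 scenario CNVs,
  10^6 brute-force interval pairs, ~250-gene bundles) were chosen so the
  whole verification runs in seconds on one CPU while still covering every
  criterion and boundary.

## Known limitations

* Section 5 of the rubrics (inheritance, de novo status, phenotype
  specificity, literature/case counts) is out of scope by design.
* No VCF input and no liftover; callers supply BED coordinates in the
  declared build.
* `2D-2` depends on a curated "pathogenic variants in the last exon" flag
  in the gene database rather than a live variant-database lookup.
* The gain-side "larger than a benign region" comparison requires full
  containment of the region plus no additional protein-coding genes; with
  identical gene content the identical-content criterion (`2C`) takes
  precedence.
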
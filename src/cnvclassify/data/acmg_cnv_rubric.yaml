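# Default scoring rubric for clinical CNV classification, transcribed from
# the 2019 ACMG/ClinGen copy-number-variant scoring rubrics (automatable
# subset: genomic content, dosage sensitivity, gene count, population
# frequency; no case/family/phenotype evidence).  Points are strings so they
# load as exact decimals.  Edit a copy of this file and pass it via
# --rubric-config to change point values without touching code.
schema_version: 1

thresholds:
  pathogenic_min: "0.99"        # total >= 0.99            -> Pathogenic
  likely_pathogenic_min: "0.90" # 0.90 <= total < 0.99     -> Likely pathogenic
  likely_benign_max: "-0.90"    # -0.99 < total <= -0.90   -> Likely benign
  benign_max: "-0.99"           # total <= -0.99           -> Benign

population:
  min_coverage: "0.80"     # population CNV must cover >= 80 % of the query
  common_frequency: "0.01" # mean frequency must exceed 1 % to count as common

gene_count_bins:
  loss:
    - {max: 24, criterion: "3A"}
    - {max: 34, criterion: "3B"}
    - {criterion: "3C"}
  gain:
    - {max: 34, criterion: "3A"}
    - {max: 49, criterion: "3B"}
    - {criterion: "3C"}

loss:
  - {id: "1A", points: "0.00", description: "Contains protein-coding or other known functionally important elements"}
  - {id: "1B", points: "-0.60", description: "Does not contain protein-coding or any known functionally important elements"}
  - {id: "2A", points: "1.00", description: "Complete overlap of an established haploinsufficient gene or genomic region"}
  - {id: "2B", points: "0.00", description: "Partial overlap of an established haploinsufficient genomic region"}
  - {id: "2C-1", points: "0.90", description: "Partial overlap with the 5' end of an established HI gene; coding sequence involved"}
  - {id: "2C-2", points: "0.00", description: "Partial overlap with the 5' end of an established HI gene; only the 5' UTR involved"}
  - {id: "2D-1", points: "0.00", description: "Partial overlap with the 3' end of an established HI gene; only the 3' UTR involved"}
  - {id: "2D-2", points: "0.90", description: "Partial overlap with the 3' end of an established HI gene; only the last exon involved, established pathogenic variants in this exon"}
  - {id: "2D-3", points: "0.30", description: "Partial overlap with the 3' end of an established HI gene; only the last exon involved, no established pathogenic variants"}
  - {id: "2D-4", points: "0.90", description: "Partial overlap with the 3' end of an established HI gene; coding exons in addition to the last exon involved"}
  - {id: "2E", points: "0.00", description: "Both breakpoints within the same established HI gene (intragenic deletion); conservative default, consequence on reading frame unknown"}
  - {id: "2F", points: "-1.00", description: "Completely contained within an established benign copy-number-loss region"}
  - {id: "2G", points: "0.00", description: "Overlaps an established benign copy-number-loss region but includes additional genomic material"}
  - {id: "2H", points: "0.15", description: "Two or more haploinsufficiency predictors suggest at least one overlapped gene is haploinsufficient"}
  - {id: "3A", points: "0.00", description: "0-24 protein-coding genes"}
  - {id: "3B", points: "0.45", description: "25-34 protein-coding genes"}
  - {id: "3C", points: "0.90", description: "35 or more protein-coding genes"}
  - {id: "4O", points: "-1.00", description: "Common population variant: overlapping population CNVs (>= 80 % query coverage) with mean frequency > 1 %"}

gain:
  - {id: "1A", points: "0.00", description: "Contains protein-coding or other known functionally important elements"}
  - {id: "1B", points: "-0.60", description: "Does not contain protein-coding or any known functionally important elements"}
  - {id: "2A", points: "1.00", description: "Complete overlap of an established triplosensitive gene or genomic region"}
  - {id: "2B", points: "0.00", description: "Partial overlap of an established triplosensitive genomic region"}
  - {id: "2C", points: "-1.00", description: "Identical in gene content to an established benign copy-number-gain region"}
  - {id: "2D", points: "-1.00", description: "Smaller than an established benign copy-number-gain region, breakpoints do not interrupt protein-coding genes"}
  - {id: "2E", points: "0.00", description: "Smaller than an established benign copy-number-gain region, breakpoints potentially interrupt protein-coding genes"}
  - {id: "2F", points: "-1.00", description: "Larger than an established benign copy-number-gain region, no additional protein-coding genes"}
  - {id: "2G", points: "0.00", description: "Overlaps an established benign copy-number-gain region but includes additional genomic material"}
  - {id: "2H", points: "0.00", description: "An established haploinsufficient gene is fully contained within the duplication"}
  - {id: "2I", points: "0.00", description: "Both breakpoints within the same established HI gene; conservative default, consequence on reading frame unknown"}
  - {id: "2J", points: "0.00", description: "One breakpoint within an established HI gene; patient phenotype unknown or nonspecific"}
  - {id: "2L", points: "0.00", description: "One breakpoint within a gene of no established dosage sensitivity"}
  - {id: "3A", points: "0.00", description: "0-34 protein-coding genes"}
  - {id: "3B", points: "0.45", description: "35-49 protein-coding genes"}
  - {id: "3C", points: "0.90", description: "50 or more protein-coding genes"}
  - {id: "4O", points: "-1.00", description: "Common population variant: overlapping population CNVs (>= 80 % query coverage) with mean frequency > 1 %"}
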
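#!/usr/bin/env bash
# Stub: documents (does not perform) the refresh of the local ClinGen-derived
# dosage-sensitivity database.
#
# In a production deployment the curated haploinsufficiency/triplosensitivity
# gene and region lists should be refreshed regularly from the ClinGen FTP
# area, converted to the dosage.tsv schema documented in
# src/cnvclassify/annotation_db.py (chrom, start, end, name, scope,
# hi_score, ts_score; one file per genome build), and validated by loading
# them with cnvclassify.annotation_db.load_bundle before being swapped in.
#
# This repository ships no live downloader: network retrieval, licensing and
# release pinning are site-specific concerns.  This stub exists so pipelines
# that expect an updater hook have a documented place to put one.
echo "update_clingen.sh is a documentation stub; see comments inside." >&2
exit 1
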
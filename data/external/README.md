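# External inputs (not redistributed)

Two acceptance checks recompute published counts from publicly deposited
data that is not bundled with this repository.  To run them, download the
supplementary tables of the source study (sRNA-seq counts, differential
expression results, TargetScan and miRanda prediction lists) and the RefSeq
3'UTR sequences of the protein-coding DEM host transcripts, then convert
them to the following plain-text files in this directory:

| file | contents |
| --- | --- |
| `s3_mir_counts.tsv` | raw miR counts, rows = miR ids, columns = 6 samples |
| `s3_samples.tsv` | sample sheet: `sample_id`, `condition` (WT/KD) |
| `s4_differential.tsv` | differential results with a `padj` column |
| `s5_targetscan_sites.tsv` | seed-site predictions: `mir`, `gene` |
| `s6_miranda_predictions.tsv` | prediction list: `mir`, `gene` |
| `dem_host_utrs.fasta` | host 3'UTRs, headers `GENE|accession` |

Without these files the corresponding tests report failure with a message
pointing here; everything else in the test suite is self-contained.
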
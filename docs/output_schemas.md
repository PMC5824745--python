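# Output file schemas

All tables are tab-separated with one header row, '.' decimal separator,
no quoting; floats printed with `%.10g`. Library columns are encoded
`<condition>_<assay>_rep<k>` with condition ∈ {base, alt} and assay ∈
{RPF, mRNA}.

| file | columns |
|---|---|
| `annotation.tsv` | gene_id, utr5_len, cds_len, utr3_len (nt) |
| `counts.tsv` | gene_id + one integer column per library |
| `truth.tsv` | gene_id, base_expression, base_te, te_fold_change, class_truth |
| `footprints.tsv` | gene_id, start (0-based), end (half-open), read_id, length, strand (always `+`) |
| `sequences.fasta` | one record per region, header `gene|region`, region ∈ {utr5, cds, utr3} |
| `motif_truth.tsv` | gene_id, n_uorf, has_top, n_cpe (planted census) |
| `rpkm.tsv` | gene_id + one RPKM column per library |
| `filter_report.tsv` | gene_id, kept (True/False under the 128-read rule) |
| `te.tsv` | gene_id, te_base, te_alt, rpkm_mrna_base, rpkm_mrna_alt, rpkm_rpf_base, rpkm_rpf_alt |
| `dte_results.tsv` | gene_id, log2_ratio, log10_intensity, window_index, z, p, fdr, label |
| `windows.tsv` | window_index, rank_start, rank_stop (half-open intensity ranks), mean_log10_intensity, mean_log2_ratio, sd_log2_ratio |
| `length_histogram.tsv` | length (nt), count |
| `frame_fractions.tsv` | frame (0/1/2), fraction |
| `r2.tsv` | symmetric library × library matrix of squared Pearson correlations of log10(RPKM+1) |
| `pca_transcription.tsv`, `pca_translation.tsv` | sample id + PC1..PCk sample coordinates |
| `dendrogram_*.txt` | nested parentheses, `(left,right):height` per merge |
| `utr_features.tsv` | gene_id, region, length_bp, gc_percent, n_uorf, has_top, n_cpe, external_elements (comma-joined) |
| `group_comparison.tsv` | metric, kind (element/continuous), group, n_group, value_group, [sem_group], n_control, value_control, [sem_control], statistic, p, [p_vs_control], underrepresented |
| `manifest.json` | config_sha256, seed, per-file path and row counts, partial flag |
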
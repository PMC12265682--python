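# Input and output schemas

A pipeline bundle is a directory of plain-text files. `antigenforge
make-fixtures` writes a complete synthetic bundle; real data in the same
schemas runs identically. Wide expression tables use `t_<sample>` columns
for tumor samples and `n_<tissue>` columns for normal tissues.

## Inputs

| file | format | columns / content |
|---|---|---|
| `genome.fasta` | FASTA | contigs, uppercase A/C/G/T/N |
| `models.gtf` | GTF | `exon` features with `gene_id`, `transcript_id` |
| `expression_self_gene.tsv` | TSV | `entity_id`, `t_*` (TPM), `n_*` (TPM) |
| `gene_safety.tsv` | TSV | `gene_id`, `bayes_ts`, `normal_max_median_tpm`, `de_adj_p`, `de_lfc` (last two may be empty) |
| `junctions.tsv` | TSV | `contig`, `donor_end`, `acceptor_start` (0-based half-open), `strand`, `donor_annotated`, `acceptor_annotated`, `t_*`/`n_*` read counts |
| `introns.tsv` | TSV | `gene_id`, `contig`, `start`, `end`, `readthrough_support`, `exon_tpm_proxy`, `normal_detected`, `recurrence_freq` |
| `te_loci.bed` | BED6 | TE locus intervals, `name` = locus id |
| `te_expression.tsv` | TSV | `entity_id` (locus name), `t_*`/`n_*` CPM |
| `fusions.tsv` | TSV | `fusion_id`, `gene5`, `gene3`, `bp5`/`bp3` (`contig:pos:strand`), `frame_label`, `labels` (comma-separated annotations) |
| `fusion_cds.fasta` | FASTA | `<fusion_id>\|5p` in-frame CDS ending at the breakpoint; `<fusion_id>\|3p` continuing in frame |
| `variants.vcf` | VCF 4.2 | INFO keys `CSQ` (consequence), `DBSNP_AF`, `REDI`, `COSMIC`, `VAF` |
| `mapped_variants.tsv` | TSV | `variant_id`, `cds_id`, `kind`, `cds_pos` (0-based on CDS), `ref`, `alt` |
| `variant_cds.fasta` | FASTA | coding sequences referenced by `mapped_variants.tsv` |
| `microbiome_reads.tsv` | TSV | `read_id`, `sample_id`, `taxon_id` (species), `kmer_confidence` |
| `taxonomy.tsv` | TSV | `species`, `genus` |
| `normal_species.tsv` | TSV | `species` detected in the normal control |
| `normal_genus.tsv` | TSV | `genus`, `reads` (normal-cohort read counts) |
| `microbial_cds.fasta` | FASTA | CDS records, ids `<species>\|<cds_id>` |
| `nuorf.fasta` | FASTA | peptide entries, headers `<class>\|<id>` with class ∈ {lncRNA, pseudogene, cryptic_orf} |
| `hla_alleles.tsv` | TSV | `sample_id`, `alleles` (semicolon-separated) |
| `engine1_psms.tsv` | TSV | `RawFile`, `ScanNumber`, `Sequence`, `Score` (Andromeda), `PEP`, `Qvalue` (rescored), `Intensity` |
| `engine2_psms.tsv` | TSV | `spectrum_id`, `sample_id`, `sequence`, `score`, `qvalue`, `intensity` |
| `normal_immunopeptidome.tsv` | TSV | `sequence`, `tissue` |

## Outputs (`run-all`)

| file | content |
|---|---|
| `events.tsv` | every event call: class, id, recurrence frequency, status, reason, config hash |
| `space.fasta` | deduplicated peptide search space, headers `class\|event_id\|meta` |
| `space_manifest.tsv` | sequence → provenance records |
| `peptide_table.tsv` | reconciled peptides: samples, engines, status/reason, best binding rank, normalized log2 abundance |
| `scorecards.tsv` | seven-criterion scorecard per retained peptide |
| `report.json` | config hash and overrides, per-stage counts, rejection-reason tallies |
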
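# antigenforge

Discovery of tumor-specific HLA class I antigens from transcriptome-derived
evidence and immunopeptidome search results.

Cancer cells present short peptides (8–15-mers) on HLA class I molecules.
Beyond canonical over-expressed self-proteins, presentable peptides arise
from many non-canonical sources: tumor-specific splice junctions, retained
introns, transposable-element (TE) transcripts and TE-chimeric splice
products, gene fusions, somatic and germline coding variants,
tumor-resident microbes, and translatable lncRNAs / pseudogenes / cryptic
ORFs. `antigenforge` implements the desk side of that discovery workflow
for computational immunologists: it consumes the evidence tables that
upstream aligners, quantifiers and search engines produce, and performs the
event calling, in-silico translation, peptide-spectrum-match (PSM)
reconciliation and target triage in a reproducible, testable form.

## What it computes

**Event calling.** Each molecular class has a tumor-specificity filter with
strict thresholds against a panel of normal tissues:

| class | retained iff |
|---|---|
| self-gene | median tumor TPM > 20, above max normal-tissue median; BayesTS < 0.3; adj. p < 0.05 and log2FC > 0.58 when DE data exist |
| splice junction | mean tumor reads > 10; mean normal reads < 1; log2((t+ε)/(n+ε)) > 4; ≥ 1 annotated splice site |
| intron retention | read-through transcript support over a constitutive intron; absolutely absent in normal tissue |
| autonomous TE | median tumor CPM > 1; mean normal CPM < 0.5; log2FC > 5 |
| TE-chimeric | a retained junction whose donor/acceptor falls in an annotated TE locus |
| fusion | in-frame, not carrying any of the 7 normal/paralog blocklist labels |
| variant | missense / in-frame indel / frameshift; all retained, labelled likely-somatic iff (dbSNP AF < 1e-4 ∧ ∉ REDIportal ∧ max VAF < 0.95) ∨ COSMIC; A>G flagged as likely RNA editing |
| microbiome | reads with > 90% unambiguous k-mers; species absent from normal control and genus below the normal-read threshold |

In cohort mode a recurrence gate then requires class-specific detection
frequencies (> 20% for junctions, TEs and microbes, > 15% for intron
retention); ε = 0.01 is the log-fold-change pseudocount.

**Search-space construction.** Retained events are translated: 33-nt
junction flanks in three frames keeping stop-free products; retained-intron
transcripts via most-probable-ORF selection (longest ORF; near-ties < 8 nt
re-ranked by GC then human codon potential; peptide kept only when the ORF
overlaps the intron); TE loci in six frames with ≥ 8-aa fragments; variant
windows of 14 residues per side (frameshifts emit the novel tail); fusion
junctions as 14 codons per side; microbial proteomes from frame-consistent,
stop-free CDS under NCBI codon table 11. Everything is deduplicated into a
provenance-tracked FASTA.

**PSM post-processing.** Identifications from a MaxQuant-style engine
(PEP < 0.05 ∧ rescored q < 0.05, 8–11-mers) and a Tesorai-style engine
(q < 0.01, 8–15-mers) are unioned; spectra the engines assign to different
peptides are resolved by the score-quadrant table at Andromeda 70 /
Tesorai 5 (both high → ambiguous, both low → low-confidence, both
excluded). Survivors are filtered to predicted HLA binders (percentile rank
< 2, strong < 0.5), screened against the normal immunopeptidome (detection
in any essential tissue excludes; adrenal gland, ovary, prostate, testis
and thymus are exempt), and quantified as max precursor intensity with
upper-quartile log2 normalization per run.

**Prioritization.** Each surviving target gets a seven-criterion scorecard
(abundance, recurrence, normal RNA/immunopeptidome absence, binding rank,
gene dependency, single-cell homogeneity percentile, identification
confidence), plus cohort patient-coverage computation and a
personalized-vaccine triage step that cross-matches predicted neoantigens
against cohort immunopeptidome evidence with cosine/Pearson spectral
similarity.

## Worked example

The package ships seeded generators for every input, so a complete run
needs no external data:

```bash
antigenforge make-fixtures --seed 42 --out demo/
antigenforge run-all --input-dir demo/ --out-dir demo_out/
```

The run report (excerpt) shows the planted cohort being recovered —
36 candidate events of which 13 survive the tumor-specificity filters,
a 36-peptide search space, and 141 simulated PSMs reconciled to 57:

```json
{
 "call_events": {
  "n_events": 36,
  "by_class_status": {
   "fusion:retained": 1, "intron_retention:retained": 1,
   "microbiome:retained": 1, "self_gene:retained": 2,
   "splicing:retained": 2, "te_chimeric:retained": 1,
   "te_self:retained": 1, "variant:retained": 5, "...rejected": "..."
  }
 },
 "build_space": {"n_unique_peptides": 36},
 "postprocess": {
  "n_psms_input": 141, "n_psms_reconciled": 57,
  "peptide_status": {
   "excluded:non_binder": 27, "excluded:normal_tissue": 1,
   "retained": 26, "retained:exempt_tissue_only": 1
  }
 },
 "prioritize": {"n_scorecards": 27}
}
```

Every rejected event carries one machine-readable reason
(`tumor_median_low`, `normal_expressed`, `lfc`, `no_annotated_site`,
`blocklist`, `recurrence`, ...). `demo_out/space.fasta` holds the peptide
search space with provenance headers, e.g.

```
>splicing|chr1|1600|2000|+|frame0
DSTYSDVILKSADRLSIMYGDP
```

and `demo_out/scorecards.tsv` the per-target criteria:

```
target_id   abundance  recurrence  normal_ip_ok  binding_rank  id_confidence
CDLISDNFK   -5.176     0.1         False         0.678         high
```

(the peptide detected in the planted normal liver sample is excluded; the
one found only in testis is retained with an annotation).

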
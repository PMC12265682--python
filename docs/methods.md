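# Methods

## Scope and model of the problem

`antigenforge` operates strictly downstream of read processing: alignment,
transcript assembly, variant calling, taxonomic classification, spectral
searching and rescoring, HLA typing and binding prediction are all external
and consumed as tables, FASTA/VCF/BED/GTF files, or pluggable scoring
callables. The package's own substance is (i) the per-class
tumor-specificity decision rules, (ii) the translation of retained events
into a searchable peptide space, (iii) the reconciliation of two search
engines' peptide-spectrum matches into one high-confidence list, and (iv)
the prioritization arithmetic. Each of those is deterministic given its
inputs, which is what makes the whole pipeline property-testable.

Coordinates are 0-based half-open internally; GTF (1-based closed) and VCF
(1-based POS) are converted at the I/O boundary. A splice junction is keyed
by (contig, donor_end, acceptor_start, strand), matching the intron span a
read-spanning alignment (N in the CIGAR) defines.

## Event-calling rules

All threshold comparisons are strict (`>`, `<`) exactly as published;
boundary equality rejects. Each rejected event carries exactly one primary
reason code — the first failing criterion in documented order — so planted
threshold-adjacent fixtures can assert both the status and its cause.

Log fold changes are computed on means (medians are available by
configuration) with a pseudocount ε added to both numerator and
denominator, since normal-tissue means are legitimately zero. ε defaults to
0.01 and is configurable; the decision rules publish no pseudocount, and
any small ε preserves the intended behaviour at the published operating
points (for example mean tumor 12 vs mean normal 0.5 gives
log2(12.01/0.51) ≈ 4.56).

Two rules need numbers the published criteria leave qualitative:

- *Genus background for microbes*: "appreciable" normal-cohort reads at
  genus level defaults to ≥ 10 reads, configurable. Species-level absence
  is exact.
- *Read confidence*: a read counts only when strictly more than 90% of its
  consecutive k-mers map unambiguously (confidence > 0.9).

Variants of unsupported consequence classes are the only rejected variant
calls; everything else is retained for search-space construction because
germline polymorphisms also change protein sequence. The likely-somatic
label is a heuristic (dbSNP frequency, editing-database membership, VAF
ceiling, COSMIC rescue) and is carried as evidence, not used as a filter.

The cohort-mode recurrence gate divides by all tumor samples in the cohort
manifest, including samples contributing zero events. Per-sample mode
bypasses the gate. Sample support is defined per class: any read for
junctions, CPM > 1 for TE loci, at least one confident read for microbial
species; intron-retention support frequencies arrive precomputed in the
evidence table because they originate in per-sample transcript assembly.

## Search-space construction

- Junction peptides: the 33-nt flanks each side of the junction are
  concatenated (66 nt) and translated in all three frames; only stop-free
  products survive. Junctions matching an annotated isoform emit the
  documented full protein instead. Minus-strand flanks are
  reverse-complemented before translation, a strand-symmetric convention
  (the orientation convention is not externally specified).
- Intron ORF selection enumerates all complete ATG→stop ORFs (stop codon
  inside the interval, outside the peptide). Ranking is by length
  descending; if the runner-up is within 8 nt, the near-tied set re-ranks
  by GC fraction, then mean log human codon-usage frequency ("codon
  potential", from a shipped static usage table — any monotone
  codon-frequency score serves this tie-break), then leftmost start, then
  peptide lexicographic as the final deterministic tie-break. The
  translated peptide is *causal* only when the winning ORF overlaps the
  retained intron.
- TE loci are translated in six frames (both strands), split at stops;
  fragments shorter than 8 aa — the minimum searched peptide length — are
  dropped.
- Variant windows are 14 residues per side, covering every 8–15-mer that
  can span the altered position (widest searched peptide minus one);
  frameshifts translate the new frame to its first stop and emit the novel
  tail with 14 upstream wild-type residues. Tails shorter than 8 aa are
  dropped (configurable).
- Fusion junction peptides use 14 codons per side of the breakpoint,
  clamped at short CDS ends, truncated at the first stop. A 5' segment not
  ending on a codon boundary is a frame-unresolvable error.
- Microbial proteomes keep only CDS with length divisible by three,
  translate with NCBI codon table 11, strip the trailing stop and drop any
  protein with a premature stop.

Assembly deduplicates identical sequences while merging provenance, drops
anything containing `X` (from N bases) or `*` as unsearchable, enforces the
8-aa floor except for full proteins, and is idempotent.

## PSM post-processing

Engine 1 (MaxQuant-style) peptides pass at PEP < 0.05 and rescored
q-value < 0.05 with length 8–11; engine 2 (Tesorai-style) at q < 0.01 with
length 8–15. Spectra assigned different peptides by the two engines resolve
by the four-quadrant score table at Andromeda 70 / Tesorai 5; equality at
either cutoff falls on the low side, per the strict published wording. More
than two candidate peptides on one spectrum is excluded as
multiway-ambiguous.

Peptide abundance is the maximum precursor intensity over a peptide's PSMs
in a run (zero-intensity PSMs still count as identifications — match-
between-runs rows can lack intensities). The run base is the 75th
percentile of *peptide* abundances under numpy's linear-interpolation
convention (nearest-rank is a configuration away; the published description
says only "upper quantile (75%)"), and reported values are
log2(abundance/base), which is invariant to global intensity scaling.

Binding prediction is a pluggable `(peptide, allele) → percentile rank`
callable; retained iff the best rank over the sample's alleles is < 2
(strong < 0.5). The packaged default is a deterministic hash-based mock
(clearly labelled synthetic) so no external model is required; swap in a
real predictor for production use. The safety screen excludes any peptide
detected in a normal-tissue immunopeptidome outside the exempt set
{adrenal gland, ovary, prostate, testis, thymus}; exempt-only detections
are annotated but retained.

## Prioritization

The scorecard reports seven criteria without forming a composite score —
how to weight them is application-specific. Identification confidence is
*high* when any supporting PSM clears either high-confidence score cutoff
(Andromeda > 70 or Tesorai > 5). Single-cell homogeneity is the
ascending-rank percentile (rank/n, ties averaged) of a gene's mean
expression across malignant cells, over all detected genes. Patient
coverage is the fraction of patients expressing at least one target gene
and carrying its restricting allele when one is specified.

Spectral similarity aligns observed and predicted peaks by greedy
closest-first one-to-one matching within 0.02 Da (tolerance and scheme are
package choices; the published account names only the two statistics),
zero-fills unmatched peaks and returns cosine and Pearson of the aligned
intensity vectors. Vaccine triage ranks candidate neoantigens by binding
tier (rank < 2), then immunopeptidome evidence, then predicted
immunogenicity descending, with the variant identifier as deterministic
tie-break; the binding tier dominates so an evidenced non-binder sits below
every rank-passing candidate.

## Synthetic data

The fixture generators emulate the *shape* of real inputs, not their
biology: random uniform-composition genomes with a fixed two-gene-family
exon layout per contig, expression values jittered around planted
operating points (positives clear every threshold with margin; each
negative fails exactly one criterion, threshold-adjacent), PSM tables
covering the four conflict quadrants and both engines' FDR boundaries,
log-normal intensities, and schematic normal-tissue plants for the safety
screen. Default problem sizes — 2 contigs × 10 kb, 10 tumor samples,
5 normal tissues, ~50 planted events, ~140 PSMs per bundle — keep any run
of the full pipeline in seconds while exercising every decision branch.

What passing on these fixtures shows: the decision logic, translation
arithmetic and bookkeeping are exactly right. What it cannot show:
robustness to real alignment artifacts, expression dispersion, chimeric
misassembly, search-engine score miscalibration, or binding-predictor
error — those live upstream of this package's contract.

One global seed drives everything through per-component child streams
(`default_rng([seed, crc32(component)])`), so any table can be regenerated
independently and every artifact is byte-identical across runs.

## Known limitations

- Junction recurrence uses any-read support per sample; very low-coverage
  cohorts may want a minimum read cutoff instead.
- The intron-retention translation path requires an isoform whose exons
  flank the retained intron exactly; introns without such an isoform are
  skipped with a warning.
- TE-chimeric translation covers the full annotated TE locus in six frames
  rather than assembling the exact chimeric transcript; this is a superset
  of the true peptide space.
- Circular-RNA and RNA-editing antigen classes are out of scope; A>G
  variants are annotated as likely editing events but not treated as a
  separate class.
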
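"""Tumor-specificity filters producing :class:`EventCall` records.

Each filter encodes one class of molecular aberration (self-gene, splice
junction, intron retention, autonomous or chimeric transposable element,
gene fusion, coding variant, tumor-resident microbe). Thresholds are strict
inequalities; boundary equality rejects. Every rejected call carries exactly
one primary machine-readable reason code (the first failing criterion, in
the documented order).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .reference import CollapsedIntron, SpliceJunction

EVENT_CLASSES = frozenset(
    {
        "self_gene",
        "splicing",
        "intron_retention",
        "te_chimeric",
        "te_self",
        "fusion",
        "variant",
        "microbiome",
        "lncRNA",
        "pseudogene",
        "cryptic_orf",
    }
)

#: default pseudocount for every log-fold-change; the upstream tables can
#: contain exact zeros in normal tissue.
DEFAULT_PSEUDOCOUNT = 0.01

FUSION_BLOCKLIST = frozenset(
    {
        "GTEx_recurrent_StarF2019",
        "BodyMap",
        "DGD_PARALOGS",
        "HGNC_GENEFAM",
        "Greger_Normal",
        "Babiceanu_Normal",
        "ConjoinG",
    }
)

RECURRENCE_DEFAULTS = {
    "splicing": 0.20,
    "intron_retention": 0.15,
    "te_chimeric": 0.20,
    "te_self": 0.20,
    "microbiome": 0.20,
}


@dataclass
class ExpressionProfile:
    entity_id: str
    tumor_values: list[float]
    normal_values: list[float]
    unit: str  # TPM | CPM

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "CPM"):
            raise ValueError(f"unit must be TPM or CPM, got {self.unit!r}")
        if any(v < 0 for v in list(self.tumor_values) + list(self.normal_values)):
            raise ValueError("expression values must be non-negative")


@dataclass
class GeneSafetyRecord:
    gene_id: str
    bayes_ts: float
    normal_max_median_tpm: float
    de_adj_p: float | None = None
    de_lfc: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bayes_ts <= 1.0:
            raise ValueError("bayes_ts must lie in [0,1]")


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    consequence: str
    vaf_per_sample: list[float]
    dbsnp_freq: float | None = None
    in_rediportal: bool = False
    in_cosmic: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if any(not 0.0 <= v <= 1.0 for v in self.vaf_per_sample):
            raise ValueError("VAF outside [0,1]")

    @property
    def variant_id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FusionRecord:
    gene5: str
    gene3: str
    breakpoint5: tuple[str, int, str]
    breakpoint3: tuple[str, int, str]
    frame_label: str  # in-frame | frameshift | unknown
    annotation_labels: set[str] = field(default_factory=set)

    @property
    def fusion_id(self) -> str:
        return f"{self.gene5}--{self.gene3}"


@dataclass
class ClassifiedRead:
    read_id: str
    taxon_id: str | None
    kmer_confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.kmer_confidence <= 1.0:
            raise ValueError("kmer_confidence outside [0,1]")


@dataclass
class EventCall:
    event_class: str
    event_id: str
    recurrence_freq: float = 0.0
    evidence: dict = field(default_factory=dict)
    status: str = "retained"  # retained | rejected
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if not 0.0 <= self.recurrence_freq <= 1.0:
            raise ValueError("recurrence_freq outside [0,1]")
        if self.status == "rejected" and not self.reason:
            raise ValueError("rejected call requires a reason code")

    @property
    def retained(self) -> bool:
        return self.status == "retained"


def _call(event_class, event_id, evidence, reason=None, recurrence=0.0) -> EventCall:
    return EventCall(
        event_class=event_class,
        event_id=event_id,
        recurrence_freq=recurrence,
        evidence=evidence,
        status="rejected" if reason else "retained",
        reason=reason,
    )


def _lfc(numer: float, denom: float, pseudocount: float) -> float:
    return math.log2((numer + pseudocount) / (denom + pseudocount))


def filter_self_gene(
    expr: ExpressionProfile, safety: GeneSafetyRecord | None
) -> EventCall:
    """Tumor-specific self-gene: tumor median TPM > 20, above the maximum
    per-tissue normal median, BayesTS < 0.3 for therapeutic safety, and
    significant upregulation when differential-expression data exist
    (adjusted p < 0.05 and log2 fold change > 0.58)."""
    if expr.unit != "TPM":
        raise ValueError("self-gene filter requires TPM units")
    med_t = float(np.median(expr.tumor_values))
    evidence = {"tumor_median_tpm": med_t}
    if safety is None:
        return _call("self_gene", expr.entity_id, evidence, "no_safety_profile")
    evidence.update(
        normal_max_median_tpm=safety.normal_max_median_tpm, bayes_ts=safety.bayes_ts
    )
    reason = None
    if not med_t > 20:
        reason = "tumor_median_low"
    elif not med_t > safety.normal_max_median_tpm:
        reason = "normal_expressed"
    elif not safety.bayes_ts < 0.3:
        reason = "bayes_ts"
    elif safety.de_adj_p is not None and safety.de_lfc is not None and not (
        safety.de_adj_p < 0.05 and safety.de_lfc > 0.58
    ):
        reason = "not_upregulated"
    return _call("self_gene", expr.entity_id, evidence, reason)


def filter_junction(
    j: SpliceJunction,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    use_median: bool = False,
) -> EventCall:
    """Tumor-specific splice junction: tumor mean read count > 10, normal
    mean < 1, log2 fold change > 4, and at least one annotated splice site
    (junctions with neither site annotated are treated as alignment
    artifacts)."""
    if not j.tumor_counts:
        return _call("splicing", "|".join(map(str, j.key)), {}, "no_tumor_samples")
    agg = np.median if use_median else np.mean
    mean_t = float(agg(j.tumor_counts))
    mean_n = float(agg(j.normal_counts)) if j.normal_counts else 0.0
    lfc = _lfc(mean_t, mean_n, pseudocount)
    evidence = {"tumor_mean": mean_t, "normal_mean": mean_n, "lfc": lfc}
    reason = None
    if not mean_t > 10:
        reason = "tumor_count_low"
    elif not mean_n < 1:
        reason = "normal_expressed"
    elif not lfc > 4:
        reason = "lfc"
    elif not (j.donor_annotated or j.acceptor_annotated):
        reason = "no_annotated_site"
    return _call("splicing", "|".join(map(str, j.key)), evidence, reason)


def call_intron_retention(
    intron: CollapsedIntron,
    readthrough_support: bool,
    exon_tpm_proxy: float,
    normal_detected: bool,
) -> EventCall:
    """Intron retention: requires a predicted read-through transcript over a
    constitutive intron and absolute absence in normal tissue. Expression of
    the covering exon is stored as an abundance proxy."""
    if intron.flag_cross_gene_exon_overlap:
        raise ValueError("intron overlaps another gene's exon; excluded upstream")
    event_id = f"{intron.gene_id}:{intron.interval[0]}-{intron.interval[1]}"
    evidence = {"exon_tpm_proxy": exon_tpm_proxy, "interval": intron.interval}
    reason = None
    if not readthrough_support:
        reason = "no_readthrough"
    elif normal_detected:
        reason = "normal_presence"
    return _call("intron_retention", event_id, evidence, reason)


def filter_autonomous_te(
    expr: ExpressionProfile, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> EventCall:
    """Autonomous (self-translating) TE locus: tumor median CPM > 1, normal
    mean CPM < 0.5, log2 fold change > 5."""
    if expr.unit != "CPM":
        raise ValueError("autonomous-TE filter requires CPM units")
    med_t = float(np.median(expr.tumor_values))
    mean_n = float(np.mean(expr.normal_values)) if len(expr.normal_values) else 0.0
    lfc = _lfc(med_t, mean_n, pseudocount)
    evidence = {"tumor_median_cpm": med_t, "normal_mean_cpm": mean_n, "lfc": lfc}
    reason = None
    if not med_t > 1:
        reason = "tumor_median_low"
    elif not mean_n < 0.5:
        reason = "normal_expressed"
    elif not lfc > 5:
        reason = "lfc"
    return _call("te_self", expr.entity_id, evidence, reason)


def classify_te_chimeric(
    j: SpliceJunction, te_loci: Sequence[tuple[str, int, int, str]]
) -> EventCall | None:
    """Annotate a retained junction as TE-chimeric when its donor or
    acceptor falls inside an annotated TE locus. Both strands of the TE
    region are flagged for downstream translation.

    ``te_loci``: (contig, start, end, name) half-open intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, start, end, name in te_loci:
        trees.setdefault(contig, IntervalTree())[start:end] = (start, end, name)
    tree = trees.get(j.contig)
    if tree is None:
        return None
    sides = []
    # donor_end is exclusive: the last exonic base is donor_end - 1
    for side, coord in (("donor", j.donor_end - 1), ("acceptor", j.acceptor_start)):
        for iv in sorted(tree[coord]):
            sides.append({"side": side, "locus": iv.data})
    if not sides:
        return None
    event_id = "te|" + "|".join(map(str, j.key))
    return _call(
        "te_chimeric",
        event_id,
        {"sides": sides, "junction": j.key, "translate_both_strands": True},
    )


SUPPORTED_CONSEQUENCES = frozenset(
    {"missense", "frameshift", "inframe_insertion", "inframe_deletion"}
)


def classify_variant(v: VariantRecord) -> EventCall:
    """Label a coding variant as likely somatic or germline/clonal.

    Likely somatic: (dbSNP frequency absent or < 1e-4) AND not in the
    REDIportal editing database AND max tumor VAF < 0.95 — or confirmed in
    COSMIC. All supported-consequence variants are retained for the search
    space regardless of label (germline polymorphisms also alter protein
    sequence); A>G substitutions carry a likely-RNA-editing annotation.
    """
    if v.consequence not in SUPPORTED_CONSEQUENCES:
        return _call("variant", v.variant_id, {"consequence": v.consequence}, "consequence")
    max_vaf = max(v.vaf_per_sample) if v.vaf_per_sample else 0.0
    heuristic = (
        (v.dbsnp_freq is None or v.dbsnp_freq < 0.0001)
        and not v.in_rediportal
        and max_vaf < 0.95
    )
    likely_somatic = heuristic or v.in_cosmic
    evidence = {
        "label": "likely_somatic" if likely_somatic else "germline_or_clonal",
        "consequence": v.consequence,
        "max_vaf": max_vaf,
        "likely_rna_editing": v.ref == "A" and v.alt == "G",
    }
    return _call("variant", v.variant_id, evidence)


def filter_fusion(
    f: FusionRecord, blocklist: frozenset[str] = FUSION_BLOCKLIST
) -> EventCall:
    """Retain in-frame fusions not labelled by any normal-tissue /
    paralog-artifact annotation on the blocklist."""
    evidence = {"frame": f.frame_label, "labels": sorted(f.annotation_labels)}
    reason = None
    if f.frame_label != "in-frame":
        reason = "frame"
    elif f.annotation_labels & blocklist:
        reason = "blocklist"
    return _call("fusion", f.fusion_id, evidence, reason)


def filter_microbiome(
    reads: Iterable[ClassifiedRead],
    normal_species: set[str],
    normal_genus_read_counts: Mapping[str, int],
    taxonomy: Mapping[str, str],
    confidence_min: float = 0.9,
    genus_read_threshold: int = 10,
) -> list[EventCall]:
    """Call tumor-specific microbial species from classified reads.

    Reads are counted only when more than ``confidence_min`` of their
    consecutive k-mers map unambiguously. A species is retained when it is
    undetected at species level in the normal control and its genus shows
    fewer than ``genus_read_threshold`` normal reads.
    """
    tallies: Counter[str] = Counter()
    for r in reads:
        if r.taxon_id is None or not r.kmer_confidence > confidence_min:
            continue
        tallies[r.taxon_id] += 1
    calls = []
    for species in sorted(tallies):
        if species not in taxonomy:
            raise ValueError(f"species {species!r} missing from taxonomy map")
        genus = taxonomy[species]
        reason = None
        if species in normal_species:
            reason = "normal_species"
        elif normal_genus_read_counts.get(genus, 0) >= genus_read_threshold:
            reason = "genus_background"
        calls.append(
            _call(
                "microbiome",
                species,
                {"read_count": tallies[species], "genus": genus},
                reason,
            )
        )
    return calls


def recurrence_gate(
    events: Iterable[EventCall],
    n_tumor_samples: int,
    min_freq_by_class: Mapping[str, float] | None = None,
    per_sample_mode: bool = False,
) -> list[EventCall]:
    """Cohort-mode recurrence filter: reject events whose supporting-sample
    frequency does not exceed the class threshold. Per-sample mode bypasses
    the gate. The denominator is all tumor samples in the cohort manifest.
    """
    if n_tumor_samples < 1:
        raise ValueError("need at least one tumor sample")
    thresholds = dict(RECURRENCE_DEFAULTS)
    if min_freq_by_class:
        unknown = set(min_freq_by_class) - EVENT_CLASSES
        if unknown:
            raise ValueError(f"unknown event class in recurrence config: {sorted(unknown)}")
        thresholds.update(min_freq_by_class)
    out = []
    for ev in events:
        if per_sample_mode or not ev.retained:
            out.append(ev)
            continue
        thr = thresholds.get(ev.event_class)
        if thr is not None and not ev.recurrence_freq > thr:
            out.append(
                EventCall(
                    ev.event_class,
                    ev.event_id,
                    ev.recurrence_freq,
                    ev.evidence,
                    "rejected",
                    "recurrence",
                )
            )
        else:
            out.append(ev)
    return out
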
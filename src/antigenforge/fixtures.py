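"""Seeded synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: a toy genome with
multi-isoform gene models, TE loci and microbial CDS; per-class evidence
tables containing positives that clear every tumor-specificity threshold
with margin and negatives that fail exactly one criterion each
(threshold-adjacent); and two-engine PSM tables covering all four
score-conflict quadrants and the FDR boundaries. A manifest records the
expected decision for every planted item so end-to-end runs can be checked
against ground truth.

One global seed governs everything; each generator draws from a child
stream ``numpy.random.default_rng([seed, crc32(name)])`` so components can
be regenerated independently and byte-identically.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as afio
from .events import ClassifiedRead, FusionRecord, VariantRecord
from .reference import (
    GenomeRef,
    SpliceJunction,
    TranscriptModel,
    collapse_introns,
    translate_nt,
)

NT = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def rng_for(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NT, size=n))


def random_orf_nt(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free codons + stop: a clean complete ORF."""
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    return "ATG" + body + rng.choice(["TAA", "TAG", "TGA"])


@dataclass
class FixtureManifest:
    seed: int
    n_tumor_samples: int
    n_normal_tissues: int
    planted_events: list[dict] = field(default_factory=list)
    planted_psm_truth: dict[str, dict] = field(default_factory=dict)

    def expect(self, event_class: str, event_id: str, status: str, reason: str | None = None) -> None:
        self.planted_events.append(
            {"class": event_class, "event_id": event_id,
             "expected_status": status, "expected_reason": reason}
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# fixed gene architecture per contig (sequence content is random, structure
# is not; planted events reference these coordinates)
_GENE_LAYOUT = {
    "a": {"isoA": [(1000, 1600), (2000, 2600), (3000, 3600)],
          "isoB": [(1000, 1600), (2200, 2600), (3000, 3600)]},
    "b": {"iso1": [(5000, 5600)]},
    "c": {"iso1": [(7000, 7300), (7700, 8000)]},
    "d": {"iso1": [(7400, 7600)]},
}

TE_LAYOUT = [(8200, 8500, "LINE1"), (8600, 8800, "LTR_HERV")]


def make_toy_genome(
    seed: int, n_contigs: int = 2, contig_len: int = 10_000
) -> tuple[GenomeRef, list[TranscriptModel], pd.DataFrame, list[tuple[str, str]]]:
    """Random genome plus gene models, TE loci (BED-like frame) and a
    microbial CDS set. ``contig_len`` must be at least 10 kb so the fixed
    gene layout fits."""
    if contig_len < 10_000:
        raise ValueError("contig_len must be >= 10000 (fixed gene layout)")
    rng = rng_for(seed, "genome")
    contigs = {f"chr{i + 1}": random_nt(rng, contig_len) for i in range(n_contigs)}
    genome = GenomeRef(contigs)

    models = []
    for contig in sorted(contigs):
        for gene_key, isoforms in _GENE_LAYOUT.items():
            gid = f"{contig}_g{gene_key}"
            for tid, exons in isoforms.items():
                models.append(TranscriptModel(gid, f"{gid}_{tid}", contig, "+", list(exons)))

    te_rows = []
    for contig in sorted(contigs):
        for start, end, name in TE_LAYOUT:
            te_rows.append((contig, start, end, f"{name}_{contig}", 0, "+"))
    te_loci = pd.DataFrame(te_rows, columns=afio.BED6_COLUMNS)

    crng = rng_for(seed, "microbial_cds")
    cds: list[tuple[str, str]] = []
    for i in range(12):
        cds.append((f"cds_ok_{i}", random_orf_nt(crng, int(crng.integers(30, 120)))))
    for i in range(4):  # off-frame: length not divisible by three
        cds.append((f"cds_offframe_{i}", random_orf_nt(crng, 40) + "G"))
    for i in range(4):  # premature stop inside the frame
        good = random_orf_nt(crng, 40)
        cds.append((f"cds_stop_{i}", good[:33] + "TAA" + good[36:]))
    return genome, models, te_loci, cds


def _wide_expr(entity: str, tumor: list[float], normal: list[float],
               samples: list[str], tissues: list[str]) -> dict:
    row = {"entity_id": entity}
    row.update({f"t_{s}": v for s, v in zip(samples, tumor)})
    row.update({f"n_{t}": v for t, v in zip(tissues, normal)})
    return row


def plant_events(
    genome: GenomeRef,
    models: list[TranscriptModel],
    te_loci: pd.DataFrame,
    seed: int,
    n_tumor_samples: int = 10,
    n_normal_tissues: int = 5,
) -> tuple[dict, FixtureManifest]:
    """Evidence tables for all event classes with threshold-adjacent planted
    truth. Returns (tables, manifest); tables is a dict of DataFrames /
    sequence collections keyed by output file stem."""
    rng = rng_for(seed, "events")
    samples = [f"s{i + 1}" for i in range(n_tumor_samples)]
    tissues = [f"tissue{i + 1}" for i in range(n_normal_tissues)]
    man = FixtureManifest(seed, n_tumor_samples, n_normal_tissues)
    contig = sorted(genome.contigs)[0]
    tables: dict = {}

    def jitter(base, n, scale=0.05):
        return list(np.round(base * (1 + scale * rng.standard_normal(n)), 4).clip(0))

    # ---- self-gene ------------------------------------------------------
    expr_rows, safety_rows = [], []

    def add_gene(gid, med_t, max_n, bayes, de_p, de_lfc, status, reason, safety=True):
        expr_rows.append(_wide_expr(gid, jitter(med_t, n_tumor_samples) if med_t else [0.0] * n_tumor_samples,
                                    jitter(max_n, n_normal_tissues), samples, tissues))
        if safety:
            safety_rows.append({"gene_id": gid, "bayes_ts": bayes,
                                "normal_max_median_tpm": max_n,
                                "de_adj_p": de_p, "de_lfc": de_lfc})
        man.expect("self_gene", gid, status, reason)

    add_gene("GPOS1", 60, 2.0, 0.10, 0.001, 2.0, "retained", None)
    add_gene("GPOS2", 45, 1.0, 0.05, None, None, "retained", None)  # no DE data
    add_gene("GNEG_median", 15, 2.0, 0.10, 0.001, 2.0, "rejected", "tumor_median_low")
    add_gene("GNEG_normal", 60, 80.0, 0.10, 0.001, 2.0, "rejected", "normal_expressed")
    add_gene("GNEG_bayes", 60, 2.0, 0.45, 0.001, 2.0, "rejected", "bayes_ts")
    add_gene("GNEG_de", 60, 2.0, 0.10, 0.3, 0.1, "rejected", "not_upregulated")
    add_gene("GNEG_nosafety", 60, 2.0, 0.0, None, None, "rejected", "no_safety_profile",
             safety=False)
    tables["expression_self_gene"] = pd.DataFrame(expr_rows)
    tables["gene_safety"] = pd.DataFrame(safety_rows)

    # ---- splice junctions ----------------------------------------------
    gid = f"{contig}_ga"

    def junction_row(donor, acceptor, t_counts, n_counts, d_ann, a_ann):
        row = {"contig": contig, "donor_end": donor, "acceptor_start": acceptor,
               "strand": "+", "donor_annotated": d_ann, "acceptor_annotated": a_ann}
        row.update({f"t_{s}": c for s, c in zip(samples, t_counts)})
        row.update({f"n_{t}": c for t, c in zip(tissues, n_counts)})
        return row

    def counts(nonzero, value):
        c = [0] * n_tumor_samples
        for i in range(nonzero):
            c[i] = value
        return c

    zeros_n = [0] * n_normal_tissues
    j_rows = [
        junction_row(1600, 2000, counts(8, 60), zeros_n, True, True),
        junction_row(2600, 3000, counts(2, 60), zeros_n, True, True),           # freq 0.2
        junction_row(1600, 2200, counts(10, 5), zeros_n, True, True),           # low counts
        junction_row(1600, 3000, counts(10, 50), [2] * n_normal_tissues, True, True),
        junction_row(2600, 3200, counts(10, 11), [1, 0, 0, 0, 0][:n_normal_tissues] if n_normal_tissues >= 1 else [], True, True),
        junction_row(4000, 4400, counts(10, 60), zeros_n, False, False),        # unannotated
    ]
    # lfc-only failure: mean_t just above 10, normal mean just under 1
    j_rows[4] = junction_row(2600, 3200, counts(10, 11),
                             [0.9] * n_normal_tissues, True, True)
    tables["junctions"] = pd.DataFrame(j_rows)

    def jid(d, a):
        return f"{contig}|{d}|{a}|+"

    man.expect("splicing", jid(1600, 2000), "retained", None)
    man.expect("splicing", jid(2600, 3000), "rejected", "recurrence")
    man.expect("splicing", jid(1600, 2200), "rejected", "tumor_count_low")
    man.expect("splicing", jid(1600, 3000), "rejected", "normal_expressed")
    man.expect("splicing", jid(2600, 3200), "rejected", "lfc")
    man.expect("splicing", jid(4000, 4400), "rejected", "no_annotated_site")

    # ---- TE-chimeric: a retained junction whose acceptor lands in a TE --
    te_start = int(te_loci.iloc[0]["start"])
    chim = junction_row(2600, te_start, counts(8, 80), zeros_n, True, False)
    tables["junctions"] = pd.concat(
        [tables["junctions"], pd.DataFrame([chim])], ignore_index=True
    )
    man.expect("splicing", jid(2600, te_start), "retained", None)
    man.expect("te_chimeric", f"te|{jid(2600, te_start)}", "retained", None)

    # ---- intron retention ----------------------------------------------
    gene_models = [m for m in models if m.gene_id == gid]
    introns = [i for i in collapse_introns(gene_models, models)
               if not i.flag_cross_gene_exon_overlap]
    iv0, iv1 = introns[0].interval, introns[1].interval
    ir_rows = [
        {"gene_id": gid, "contig": contig, "start": iv0[0], "end": iv0[1],
         "readthrough_support": True, "exon_tpm_proxy": 30.0,
         "normal_detected": False, "recurrence_freq": 0.30},
        {"gene_id": gid, "contig": contig, "start": iv1[0], "end": iv1[1],
         "readthrough_support": False, "exon_tpm_proxy": 30.0,
         "normal_detected": False, "recurrence_freq": 0.30},
        {"gene_id": f"{contig}_gc", "contig": contig, "start": 7300, "end": 7700,
         "readthrough_support": True, "exon_tpm_proxy": 25.0,
         "normal_detected": True, "recurrence_freq": 0.30},
        {"gene_id": f"{contig}_gb", "contig": contig, "start": iv0[0], "end": iv0[1],
         "readthrough_support": True, "exon_tpm_proxy": 25.0,
         "normal_detected": False, "recurrence_freq": 0.10},
    ]
    tables["introns"] = pd.DataFrame(ir_rows)
    man.expect("intron_retention", f"{gid}:{iv0[0]}-{iv0[1]}", "retained", None)
    man.expect("intron_retention", f"{gid}:{iv1[0]}-{iv1[1]}", "rejected", "no_readthrough")
    man.expect("intron_retention", f"{contig}_gc:7300-7700", "rejected", "normal_presence")
    man.expect("intron_retention", f"{contig}_gb:{iv0[0]}-{iv0[1]}", "rejected", "recurrence")

    # ---- autonomous TE --------------------------------------------------
    te_names = sorted(te_loci["name"])
    te_rows = [
        _wide_expr(te_names[0], jitter(5.0, n_tumor_samples),
                   [0.0] * n_normal_tissues, samples, tissues),
        _wide_expr(te_names[1], jitter(0.8, n_tumor_samples, 0.02),
                   [0.0] * n_normal_tissues, samples, tissues),
        _wide_expr(te_names[2], jitter(5.0, n_tumor_samples),
                   [0.7] * n_normal_tissues, samples, tissues),
        _wide_expr(te_names[3], [1.5] * n_tumor_samples,
                   [0.4] * n_normal_tissues, samples, tissues),
    ]
    tables["te_expression"] = pd.DataFrame(te_rows)
    man.expect("te_self", te_names[0], "retained", None)
    man.expect("te_self", te_names[1], "rejected", "tumor_median_low")
    man.expect("te_self", te_names[2], "rejected", "normal_expressed")
    man.expect("te_self", te_names[3], "rejected", "lfc")
    tables["te_loci"] = te_loci

    # ---- fusions --------------------------------------------------------
    frng = rng_for(seed, "fusion_cds")
    fusion_rows = [
        {"fusion_id": "FPOS--PART", "gene5": "FPOS", "gene3": "PART",
         "bp5": f"{contig}:1500:+", "bp3": f"{contig}:5200:+",
         "frame_label": "in-frame", "labels": ""},
        {"fusion_id": "FNEG--FRAME", "gene5": "FNEG", "gene3": "FRAME",
         "bp5": f"{contig}:1500:+", "bp3": f"{contig}:5200:+",
         "frame_label": "frameshift", "labels": ""},
        {"fusion_id": "FNEG--BLOCK", "gene5": "FNEG", "gene3": "BLOCK",
         "bp5": f"{contig}:1500:+", "bp3": f"{contig}:5200:+",
         "frame_label": "in-frame", "labels": "BodyMap"},
    ]
    tables["fusions"] = pd.DataFrame(fusion_rows)
    fusion_cds = []
    for row in fusion_rows:
        fid = row["fusion_id"]
        n5 = int(frng.integers(20, 40)) * 3
        fusion_cds.append((f"{fid}|5p", "".join(frng.choice(_NONSTOP_CODONS, n5 // 3))))
        fusion_cds.append((f"{fid}|3p", "".join(frng.choice(_NONSTOP_CODONS, 30))))
    tables["fusion_cds"] = fusion_cds
    man.expect("fusion", "FPOS--PART", "retained", None)
    man.expect("fusion", "FNEG--FRAME", "rejected", "frame")
    man.expect("fusion", "FNEG--BLOCK", "rejected", "blocklist")

    # ---- variants -------------------------------------------------------
    vrng = rng_for(seed, "variant_cds")
    variants, mapped_rows, variant_cds = [], [], []

    def add_variant(name, pos, ref, alt, consequence, vafs, dbsnp, redi, cosmic,
                    status, reason, kind=None, cds_pos=None):
        v = VariantRecord(contig, pos, ref, alt, consequence, vafs, dbsnp, redi, cosmic)
        variants.append(v)
        man.expect("variant", v.variant_id, status, reason)
        if kind:
            cds_id = f"cds_{name}"
            cds = random_orf_nt(vrng, 60)
            # force the reference base(s) at the mapped position
            cds = cds[:cds_pos] + ref + cds[cds_pos + len(ref):]
            # keep a complete ORF: repair the codon if the edit created a stop
            ci = cds_pos // 3 * 3
            if cds[ci : ci + 3] in ("TAA", "TAG", "TGA"):
                fix = ci if ci != cds_pos else ci + 2
                cds = cds[:fix] + "C" + cds[fix + 1:]
            variant_cds.append((cds_id, cds))
            mapped_rows.append({"variant_id": v.variant_id, "cds_id": cds_id,
                                "kind": kind, "cds_pos": cds_pos,
                                "ref": ref, "alt": alt})

    add_variant("som", 1501, "C", "T", "missense", [0.4, 0.5], None, False, False,
                "retained", None, kind="missense", cds_pos=31)
    add_variant("edit", 1601, "A", "G", "missense", [0.3], None, False, False,
                "retained", None, kind="missense", cds_pos=34)
    add_variant("germ", 1701, "G", "A", "missense", [0.97], 0.2, False, False,
                "retained", None, kind="missense", cds_pos=37)
    add_variant("cosmic", 1801, "C", "A", "missense", [0.97], 0.2, False, True,
                "retained", None, kind="missense", cds_pos=40)
    add_variant("fs", 1901, "T", "TG", "frameshift", [0.4], None, False, False,
                "retained", None, kind="frameshift", cds_pos=43)
    add_variant("cons", 2001, "G", "C", "other", [0.4], None, False, False,
                "rejected", "consequence")
    tables["variants"] = variants
    tables["mapped_variants"] = pd.DataFrame(mapped_rows)
    tables["variant_cds"] = variant_cds

    # ---- microbiome -----------------------------------------------------
    mrng = rng_for(seed, "microbiome")
    taxonomy = {"S_pos": "G_clean", "S_lowconf": "G_clean2", "S_innormal": "G_clean3",
                "S_genusbg": "G_background", "S_rare": "G_clean4"}
    read_rows = []

    def add_reads(species, n, conf, n_samples_spread):
        for i in range(n):
            read_rows.append({
                "read_id": f"{species}_r{i}",
                "sample_id": samples[i % n_samples_spread],
                "taxon_id": species,
                "kmer_confidence": conf,
            })

    add_reads("S_pos", 30, 0.95, 6)
    add_reads("S_lowconf", 30, 0.85, 6)
    add_reads("S_innormal", 30, 0.95, 6)
    add_reads("S_genusbg", 30, 0.95, 6)
    add_reads("S_rare", 12, 0.95, 1)
    tables["microbiome_reads"] = pd.DataFrame(read_rows)
    tables["taxonomy"] = pd.DataFrame(
        sorted(taxonomy.items()), columns=["species", "genus"]
    )
    tables["normal_species"] = pd.DataFrame({"species": ["S_innormal"]})
    tables["normal_genus"] = pd.DataFrame(
        [{"genus": "G_background", "reads": 50}]
    )
    man.expect("microbiome", "S_pos", "retained", None)
    man.expect("microbiome", "S_lowconf", "absent", "low_confidence_reads")
    man.expect("microbiome", "S_innormal", "rejected", "normal_species")
    man.expect("microbiome", "S_genusbg", "rejected", "genus_background")
    man.expect("microbiome", "S_rare", "rejected", "recurrence")

    # microbial proteomes for species-level search spaces
    prng = rng_for(seed, "species_proteomes")
    species_cds = []
    for sp in sorted(taxonomy):
        for i in range(3):
            species_cds.append((f"{sp}|cds{i}", random_orf_nt(prng, int(prng.integers(40, 90)))))
    tables["microbial_cds"] = species_cds

    # ---- nuORF-style database (lncRNA / pseudogene / cryptic ORF) ------
    nrng = rng_for(seed, "nuorf")
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    nuorf = {}
    for cls, n in (("lncRNA", 2), ("pseudogene", 2), ("cryptic_orf", 2)):
        for i in range(n):
            pep = "".join(nrng.choice(aa, size=int(nrng.integers(20, 60))))
            nuorf[f"{cls}|{cls}_{i}"] = pep
            man.expect(cls, f"{cls}_{i}", "retained", None)
    tables["nuorf"] = nuorf

    # per-sample HLA alleles
    alleles = ["HLA-A*02:01", "HLA-B*08:01", "HLA-C*07:02"]
    tables["hla_alleles"] = pd.DataFrame(
        [{"sample_id": s, "alleles": ";".join(alleles)} for s in samples]
    )
    return tables, man


def mock_rank(peptide: str, allele: str) -> float:
    """Deterministic stand-in binding predictor: percentile rank in [0, 10)
    from a hash of (peptide, allele). Synthetic; not a trained model."""
    return (zlib.crc32(f"{peptide}|{allele}".encode()) % 10_000) / 1_000.0


def mock_immunogenicity(peptide: str) -> float:
    """Deterministic stand-in immunogenicity score in [0, 1). Synthetic."""
    return (zlib.crc32(f"immuno|{peptide}".encode()) % 10_000) / 10_000.0


def _subpeptides(rng: np.random.Generator, sequence: str, length: int) -> str:
    start = int(rng.integers(0, max(1, len(sequence) - length + 1)))
    return sequence[start : start + length]


def simulate_psm_tables(
    space_entries: list, seed: int, samples: list[str] | None = None,
    alleles: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, dict]]:
    """Two-engine PSM tables drawn from a search space, plus planted
    normal-immunopeptidome hits and per-spectrum expected decisions.

    Spectra are planted in named categories: engine agreement, the four
    conflict quadrants (scores straddling Andromeda 70 / Tesorai 5), and
    FDR-boundary rejections for each engine. Intensities are log-normal.
    """
    rng = rng_for(seed, "psm")
    samples = samples or ["s1", "s2", "s3"]
    alleles = alleles or ["HLA-A*02:01", "HLA-B*08:01", "HLA-C*07:02"]
    pool = [e.sequence for e in space_entries if len(e.sequence) >= 16]
    if not pool:
        raise ValueError("search space has no sequence long enough to sample")

    e1_rows, e2_rows, truth = [], [], {}
    scan = 0

    def draw(length):
        return _subpeptides(rng, pool[int(rng.integers(len(pool)))], length)

    def intensity():
        return float(np.round(np.exp(rng.normal(14, 1.5)), 1))

    def add_e1(sample, pep, score, pep_stat, q, inten=None):
        nonlocal scan
        scan += 1
        sid = f"scan{scan:05d}"
        e1_rows.append({"RawFile": f"{sample}.raw", "ScanNumber": sid, "Sequence": pep,
                        "Score": score, "PEP": pep_stat, "Qvalue": q,
                        "Intensity": intensity() if inten is None else inten})
        return sid

    def add_e2(sample, sid, pep, score, q):
        e2_rows.append({"spectrum_id": sid, "sample_id": sample, "sequence": pep,
                        "score": score, "qvalue": q,
                        "intensity": intensity()})

    n_per_sample = 16
    for sample in samples:
        for _ in range(n_per_sample):
            pep = draw(9)
            sid = add_e1(sample, pep, 90.0, 0.001, 0.001)
            add_e2(sample, sid, pep, 8.0, 0.001)
            truth[f"{sample}/{sid}"] = {"category": "agree", "peptide": pep}
        # conflict quadrants: two engines, different peptides
        quads = [("keep_engine1", 80.0, 3.0), ("keep_engine2", 65.0, 7.0),
                 ("ambiguous", 80.0, 7.0), ("low_confidence", 65.0, 3.0),
                 ("low_confidence", 70.0, 5.0)]  # boundary equality -> low side
        for outcome, a_score, t_score in quads:
            p1, p2 = draw(9), draw(10)
            while p2 == p1:
                p2 = draw(10)
            sid = add_e1(sample, p1, a_score, 0.001, 0.001)
            add_e2(sample, sid, p2, t_score, 0.001)
            truth[f"{sample}/{sid}"] = {
                "category": outcome,
                "peptide": p1 if outcome == "keep_engine1"
                else (p2 if outcome == "keep_engine2" else None),
            }
        # FDR-boundary rejections (engine 1: PEP/q at 0.05; engine 2: q at 0.01)
        sid = add_e1(sample, draw(9), 90.0, 0.05, 0.001)
        truth[f"{sample}/{sid}"] = {"category": "e1_fdr_pep", "peptide": None}
        sid = add_e1(sample, draw(9), 90.0, 0.001, 0.05)
        truth[f"{sample}/{sid}"] = {"category": "e1_fdr_q", "peptide": None}
        sid = add_e1(sample, draw(12), 90.0, 0.001, 0.001)
        truth[f"{sample}/{sid}"] = {"category": "e1_length", "peptide": None}
        scan += 1
        sid = f"scan{scan:05d}"
        add_e2(sample, sid, draw(9), 8.0, 0.01)
        truth[f"{sample}/{sid}"] = {"category": "e2_fdr_q", "peptide": None}
        scan += 1
        sid = f"scan{scan:05d}"
        add_e2(sample, sid, draw(15), 8.0, 0.001)
        truth[f"{sample}/{sid}"] = {"category": "e2_longmer_ok", "peptide": e2_rows[-1]["sequence"]}

    # normal-immunopeptidome hits: one retained peptide into an essential
    # tissue (must be excluded) and one into an exempt tissue (annotated)
    agree_peps = sorted({t["peptide"] for t in truth.values()
                         if t["category"] == "agree"})
    # only binders reach the safety screen, so plant hits on peptides the
    # mock predictor scores below the weak-binder cutoff
    binders = [p for p in agree_peps
               if min(mock_rank(p, a) for a in alleles) < 2.0]
    normal_rows = []
    if len(binders) >= 2:
        normal_rows.append({"sequence": binders[0], "tissue": "liver"})
        normal_rows.append({"sequence": binders[1], "tissue": "testis"})
        truth["normal_excluded_peptide"] = {"category": "normal_essential",
                                            "peptide": binders[0]}
        truth["normal_exempt_peptide"] = {"category": "normal_exempt",
                                          "peptide": binders[1]}
    return (pd.DataFrame(e1_rows), pd.DataFrame(e2_rows),
            pd.DataFrame(normal_rows, columns=["sequence", "tissue"]), truth)


def write_fixture_bundle(outdir: str | Path, seed: int,
                         n_contigs: int = 2, contig_len: int = 10_000,
                         n_tumor_samples: int = 10, n_normal_tissues: int = 5) -> Path:
    """Generate and write the complete input bundle + manifest JSON."""
    from .space import assemble_search_space, junction_peptides  # cycle guard

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, models, te_loci, cds = make_toy_genome(seed, n_contigs, contig_len)
    afio.write_fasta(sorted(genome.contigs.items()), out / "genome.fasta")
    afio.write_gtf(models, out / "models.gtf")
    afio.write_bed6(te_loci, out / "te_loci.bed")
    afio.write_fasta(cds, out / "microbial_cds_raw.fasta")

    tables, man = plant_events(genome, models, te_loci, seed,
                               n_tumor_samples, n_normal_tissues)
    for key in ("expression_self_gene", "gene_safety", "junctions", "introns",
                "te_expression", "fusions", "mapped_variants",
                "microbiome_reads", "taxonomy", "normal_species",
                "normal_genus", "hla_alleles"):
        tables[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    afio.write_bed6(tables["te_loci"], out / "te_loci.bed")
    afio.write_fasta(tables["fusion_cds"], out / "fusion_cds.fasta")
    afio.write_fasta(tables["variant_cds"], out / "variant_cds.fasta")
    afio.write_fasta(tables["microbial_cds"], out / "microbial_cds.fasta")
    afio.write_fasta(sorted(tables["nuorf"].items()), out / "nuorf.fasta")
    contig_lengths = {c: len(s) for c, s in sorted(genome.contigs.items())}
    afio.write_variant_vcf(tables["variants"], contig_lengths, out / "variants.vcf")

    # PSM tables are simulated against a provisional space built from the
    # planted retained junction so spectra always map back to the space
    from .pipeline import build_space_from_bundle  # deferred import
    events_by_class = None
    space = build_space_from_bundle(out)
    e1, e2, normal_ip, psm_truth = simulate_psm_tables(
        space.entries, seed, samples=[f"s{i + 1}" for i in range(min(3, n_tumor_samples))]
    )
    e1.to_csv(out / "engine1_psms.tsv", sep="\t", index=False)
    e2.to_csv(out / "engine2_psms.tsv", sep="\t", index=False)
    normal_ip.to_csv(out / "normal_immunopeptidome.tsv", sep="\t", index=False)
    man.planted_psm_truth = psm_truth
    (out / "manifest.json").write_text(man.to_json() + "\n")
    return out
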
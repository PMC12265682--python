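"""Stage orchestration over a file bundle: call-events -> build-space ->
postprocess -> prioritize, with a JSON run report of per-stage counts and
every rejection-reason tally.

The bundle directory layout is the one :func:`antigenforge.fixtures.
write_fixture_bundle` produces; real data in the same schemas is accepted
identically.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as afio
from .config import RunConfig
from .events import (
    ClassifiedRead,
    EventCall,
    ExpressionProfile,
    FusionRecord,
    GeneSafetyRecord,
    call_intron_retention,
    classify_te_chimeric,
    classify_variant,
    filter_autonomous_te,
    filter_fusion,
    filter_junction,
    filter_microbiome,
    filter_self_gene,
    recurrence_gate,
)
from .fixtures import mock_rank
from .prioritize import score_target
from .psm import (
    PSMRecord,
    merge_engines,
    merge_peptides,
    hla_binding_filter,
    normal_screen,
    quantile_normalize,
)
from .reference import CollapsedIntron, SpliceJunction, translate_nt
from .space import (
    MappedVariant,
    PeptideEntry,
    SearchSpace,
    assemble_search_space,
    build_microbial_proteome,
    fusion_peptides,
    junction_peptides,
    mutation_peptides,
    select_intron_orf,
    te_peptides,
)

log = logging.getLogger(__name__)


def _split_expr(row: pd.Series) -> tuple[list[float], list[float]]:
    tumor = [float(v) for k, v in row.items() if str(k).startswith("t_")]
    normal = [float(v) for k, v in row.items() if str(k).startswith("n_")]
    return tumor, normal


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_junctions(bundle: Path) -> list[SpliceJunction]:
    df = _read_tsv(bundle / "junctions.tsv")
    out = []
    for _, row in df.iterrows():
        tumor, normal = _split_expr(row)
        out.append(
            SpliceJunction(
                contig=row["contig"],
                donor_end=int(row["donor_end"]),
                acceptor_start=int(row["acceptor_start"]),
                strand=row["strand"],
                tumor_counts=tumor,
                normal_counts=normal,
                donor_annotated=bool(row["donor_annotated"]),
                acceptor_annotated=bool(row["acceptor_annotated"]),
            )
        )
    return out


def call_events(bundle: str | Path, config: RunConfig | None = None) -> list[EventCall]:
    """Run every enabled per-class tumor-specificity filter over the bundle's
    evidence tables and apply the cohort recurrence gate."""
    config = config or RunConfig()
    bundle = Path(bundle)
    n_samples = len(_read_tsv(bundle / "hla_alleles.tsv"))
    events: list[EventCall] = []

    if "self_gene" in config.classes and (bundle / "expression_self_gene.tsv").exists():
        expr_df = _read_tsv(bundle / "expression_self_gene.tsv")
        safety_df = _read_tsv(bundle / "gene_safety.tsv")
        safety = {
            r["gene_id"]: GeneSafetyRecord(
                r["gene_id"], float(r["bayes_ts"]), float(r["normal_max_median_tpm"]),
                None if pd.isna(r["de_adj_p"]) else float(r["de_adj_p"]),
                None if pd.isna(r["de_lfc"]) else float(r["de_lfc"]),
            )
            for _, r in safety_df.iterrows()
        }
        for _, row in expr_df.iterrows():
            tumor, normal = _split_expr(row)
            prof = ExpressionProfile(row["entity_id"], tumor, normal, "TPM")
            ev = filter_self_gene(prof, safety.get(row["entity_id"]))
            ev.recurrence_freq = float(np.mean([v > 0 for v in tumor]))
            events.append(ev)

    junctions = []
    if "splicing" in config.classes and (bundle / "junctions.tsv").exists():
        junctions = load_junctions(bundle)
        for j in junctions:
            ev = filter_junction(j, config.pseudocount, config.use_median_junction_counts)
            ev.recurrence_freq = float(np.mean([c > 0 for c in j.tumor_counts]))
            events.append(ev)

    if "te_chimeric" in config.classes and junctions and (bundle / "te_loci.bed").exists():
        te_df = afio.read_bed6(bundle / "te_loci.bed")
        loci = [
            (r["contig"], int(r["start"]), int(r["end"]), r["name"])
            for _, r in te_df.iterrows()
        ]
        retained_j = {
            ev.event_id for ev in events
            if ev.event_class == "splicing" and ev.retained
        }
        for j in junctions:
            jid = "|".join(map(str, j.key))
            if jid not in retained_j:
                continue
            ev = classify_te_chimeric(j, loci)
            if ev is not None:
                ev.recurrence_freq = float(np.mean([c > 0 for c in j.tumor_counts]))
                events.append(ev)

    if "intron_retention" in config.classes and (bundle / "introns.tsv").exists():
        for _, row in _read_tsv(bundle / "introns.tsv").iterrows():
            intron = CollapsedIntron(
                row["gene_id"], row["contig"], (int(row["start"]), int(row["end"]))
            )
            ev = call_intron_retention(
                intron, bool(row["readthrough_support"]),
                float(row["exon_tpm_proxy"]), bool(row["normal_detected"]),
            )
            ev.recurrence_freq = float(row["recurrence_freq"])
            events.append(ev)

    if "te_self" in config.classes and (bundle / "te_expression.tsv").exists():
        for _, row in _read_tsv(bundle / "te_expression.tsv").iterrows():
            tumor, normal = _split_expr(row)
            prof = ExpressionProfile(row["entity_id"], tumor, normal, "CPM")
            ev = filter_autonomous_te(prof, config.pseudocount)
            ev.recurrence_freq = float(np.mean([v > 1 for v in tumor]))
            events.append(ev)

    if "fusion" in config.classes and (bundle / "fusions.tsv").exists():
        for _, row in _read_tsv(bundle / "fusions.tsv").iterrows():
            labels = set(str(row["labels"]).split(",")) - {"", "nan"}
            c5, p5, s5 = str(row["bp5"]).split(":")
            c3, p3, s3 = str(row["bp3"]).split(":")
            f = FusionRecord(row["gene5"], row["gene3"], (c5, int(p5), s5),
                             (c3, int(p3), s3), row["frame_label"], labels)
            ev = filter_fusion(f)
            ev.recurrence_freq = 1.0 / n_samples
            events.append(ev)

    if "variant" in config.classes and (bundle / "variants.vcf").exists():
        for v in afio.read_variant_vcf(bundle / "variants.vcf"):
            ev = classify_variant(v)
            ev.recurrence_freq = 1.0 / n_samples
            events.append(ev)

    if "microbiome" in config.classes and (bundle / "microbiome_reads.tsv").exists():
        reads_df = _read_tsv(bundle / "microbiome_reads.tsv")
        taxonomy = dict(
            _read_tsv(bundle / "taxonomy.tsv")[["species", "genus"]].itertuples(
                index=False, name=None
            )
        )
        normal_species = set(_read_tsv(bundle / "normal_species.tsv")["species"])
        genus_counts = dict(
            _read_tsv(bundle / "normal_genus.tsv")[["genus", "reads"]].itertuples(
                index=False, name=None
            )
        )
        reads = [
            ClassifiedRead(r["read_id"], r["taxon_id"], float(r["kmer_confidence"]))
            for _, r in reads_df.iterrows()
        ]
        calls = filter_microbiome(
            reads, normal_species, genus_counts, taxonomy,
            genus_read_threshold=config.genus_read_threshold,
        )
        confident = reads_df[reads_df["kmer_confidence"] > 0.9]
        support = confident.groupby("taxon_id")["sample_id"].nunique()
        for ev in calls:
            ev.recurrence_freq = float(support.get(ev.event_id, 0)) / n_samples
            events.append(ev)

    return recurrence_gate(
        events, n_samples, config.recurrence,
        per_sample_mode=(config.mode == "per_sample"),
    )


def _retained(events: list[EventCall], cls: str) -> list[EventCall]:
    return [e for e in events if e.event_class == cls and e.retained]


def _intron_transcript(models, gene_id, interval, genome):
    """Sequence of an intron-retained transcript plus the intron's interval
    on it, using the first isoform whose exons flank the intron."""
    lo, hi = interval
    for m in sorted((m for m in models if m.gene_id == gene_id),
                    key=lambda m: m.transcript_id):
        ends = {e for _, e in m.exons}
        starts = {s for s, _ in m.exons}
        if lo in ends and hi in starts:
            parts, offset = [], None
            for s, e in m.exons:
                parts.append(genome.fetch(m.contig, s, e))
                if e == lo:
                    offset = sum(len(p) for p in parts)
                    parts.append(genome.fetch(m.contig, lo, hi))
            return "".join(parts), (offset, offset + (hi - lo))
    return None, None


def build_space_from_bundle(
    bundle: str | Path,
    config: RunConfig | None = None,
    events: list[EventCall] | None = None,
) -> SearchSpace:
    """Translate every retained event into peptides and assemble the FASTA
    search space."""
    config = config or RunConfig()
    bundle = Path(bundle)
    if events is None:
        events = call_events(bundle, config)
    genome = afio.read_genome(bundle / "genome.fasta")
    models = afio.read_gtf_models(bundle / "models.gtf")
    junctions = {"|".join(map(str, j.key)): j for j in load_junctions(bundle)} \
        if (bundle / "junctions.tsv").exists() else {}

    entry_lists: list[list[PeptideEntry]] = []
    for ev in _retained(events, "splicing"):
        j = junctions.get(ev.event_id)
        if j is not None:
            entry_lists.append(junction_peptides(genome, j, ev.event_id, config.flank_nt))

    for ev in _retained(events, "te_chimeric"):
        for side in ev.evidence["sides"]:
            start, end, _name = side["locus"]
            pseudo = EventCall("te_chimeric", ev.event_id,
                               evidence={"contig": ev.evidence["junction"][0],
                                         "interval": (start, end)})
            entry_lists.append(te_peptides(genome, pseudo))

    if (bundle / "te_loci.bed").exists():
        te_df = afio.read_bed6(bundle / "te_loci.bed")
        by_name = {r["name"]: r for _, r in te_df.iterrows()}
        for ev in _retained(events, "te_self"):
            row = by_name.get(ev.event_id)
            if row is not None:
                pseudo = EventCall("te_self", ev.event_id,
                                   evidence={"contig": row["contig"],
                                             "interval": (int(row["start"]), int(row["end"]))})
                entry_lists.append(te_peptides(genome, pseudo))

    for ev in _retained(events, "intron_retention"):
        gene_id, iv = ev.event_id.rsplit(":", 1)
        lo, hi = map(int, iv.split("-"))
        tx, tx_iv = _intron_transcript(models, gene_id, (lo, hi), genome)
        if tx is None:
            log.warning("no flanking isoform for intron %s; skipped", ev.event_id)
            continue
        _best, causal = select_intron_orf(tx, tx_iv, config.tie_window_nt)
        entry_lists.append(
            [PeptideEntry(p, "intron_retention", ev.event_id) for p in causal]
        )

    if (bundle / "fusion_cds.fasta").exists():
        cds = afio.read_fasta(bundle / "fusion_cds.fasta")
        fusions_df = _read_tsv(bundle / "fusions.tsv")
        meta = {r["fusion_id"]: r for _, r in fusions_df.iterrows()}
        for ev in _retained(events, "fusion"):
            row = meta.get(ev.event_id)
            if row is None:
                continue
            c5, p5, s5 = str(row["bp5"]).split(":")
            c3, p3, s3 = str(row["bp3"]).split(":")
            f = FusionRecord(row["gene5"], row["gene3"], (c5, int(p5), s5),
                             (c3, int(p3), s3), row["frame_label"], set())
            pe = fusion_peptides(f, cds[f"{ev.event_id}|5p"], cds[f"{ev.event_id}|3p"])
            if pe:
                entry_lists.append([pe])

    if (bundle / "mapped_variants.tsv").exists():
        mv = _read_tsv(bundle / "mapped_variants.tsv")
        vcds = afio.read_fasta(bundle / "variant_cds.fasta")
        retained_var = {e.event_id for e in _retained(events, "variant")}
        for _, row in mv.iterrows():
            if row["variant_id"] not in retained_var:
                continue
            cds_nt = vcds[row["cds_id"]]
            protein = translate_nt(cds_nt).rstrip("*").split("*")[0]
            v = MappedVariant(row["kind"], int(row["cds_pos"]),
                              row["ref"], row["alt"], row["variant_id"])
            entry_lists.append(
                mutation_peptides(protein, cds_nt, v, config.mutation_window,
                                  config.min_tail_aa)
            )

    if (bundle / "microbial_cds.fasta").exists():
        micro = afio.read_fasta(bundle / "microbial_cds.fasta")
        retained_sp = {e.event_id for e in _retained(events, "microbiome")}
        records = [
            (rid, seq) for rid, seq in sorted(micro.items())
            if rid.split("|")[0] in retained_sp
        ]
        entry_lists.append(build_microbial_proteome(records))

    nuorf = None
    if "nuorf" in config.classes and (bundle / "nuorf.fasta").exists():
        nuorf = afio.read_fasta(bundle / "nuorf.fasta")
    return assemble_search_space(entry_lists, include_nuorf=nuorf)


def load_psms(bundle: Path) -> list[PSMRecord]:
    psms = []
    e1 = _read_tsv(bundle / "engine1_psms.tsv")
    for _, r in e1.iterrows():
        psms.append(PSMRecord(
            spectrum_id=str(r["ScanNumber"]),
            sample_id=str(r["RawFile"]).removesuffix(".raw"),
            peptide=r["Sequence"], engine="engine1", score=float(r["Score"]),
            pep=float(r["PEP"]), qvalue=float(r["Qvalue"]),
            precursor_intensity=float(r["Intensity"]),
        ))
    e2 = _read_tsv(bundle / "engine2_psms.tsv")
    for _, r in e2.iterrows():
        psms.append(PSMRecord(
            spectrum_id=str(r["spectrum_id"]), sample_id=str(r["sample_id"]),
            peptide=r["sequence"], engine="engine2", score=float(r["score"]),
            qvalue=float(r["qvalue"]),
            precursor_intensity=float(r["intensity"]),
        ))
    return psms


def postprocess(bundle: str | Path, config: RunConfig | None = None,
                predictor=mock_rank):
    """Two-engine reconciliation, binding and safety filters, abundance
    normalization. Returns (peptide table DataFrame, stage tallies)."""
    config = config or RunConfig()
    bundle = Path(bundle)
    psms = load_psms(bundle)
    final, decisions = merge_engines(psms)
    merged = merge_peptides(final)

    alleles_df = _read_tsv(bundle / "hla_alleles.tsv")
    alleles_by_sample = {
        str(r["sample_id"]): str(r["alleles"]).split(";")
        for _, r in alleles_df.iterrows()
    }
    for m in merged.values():
        alleles = sorted({a for s in m.samples for a in alleles_by_sample.get(s, [])})
        hla_binding_filter([m], alleles, predictor)

    normal_path = bundle / "normal_immunopeptidome.tsv"
    normal_hits: dict[str, set[str]] = defaultdict(set)
    if normal_path.exists():
        ndf = _read_tsv(normal_path)
        for _, r in ndf.iterrows():
            normal_hits[r["sequence"]].add(r["tissue"])
    for m in merged.values():
        if m.status == "retained":
            normal_screen(m, normal_hits.get(m.peptide, set()))

    normalized: dict[str, dict[str, float]] = {}
    for sample in sorted({p.sample_id for p in final}):
        run = [p for p in final if p.sample_id == sample]
        try:
            normalized[sample] = quantile_normalize(run, config.quantile)
        except ValueError:
            normalized[sample] = {}

    rows = []
    for pep in sorted(merged):
        m = merged[pep]
        norm_vals = [normalized[s].get(pep) for s in m.samples
                     if normalized.get(s, {}).get(pep) is not None]
        rows.append({
            "peptide": pep,
            "n_samples": len(m.samples),
            "samples": ";".join(sorted(m.samples)),
            "engines": ";".join(sorted(m.engines_supporting)),
            "status": m.status,
            "reason": m.reason or "",
            "best_rank": m.hla_assignments[0][1] if m.hla_assignments else np.nan,
            "binder_class": m.hla_assignments[0][2] if m.hla_assignments else "",
            "normal_tissues": ";".join(sorted(m.normal_flags)),
            "log2_abundance": max(norm_vals) if norm_vals else np.nan,
        })
    table = pd.DataFrame(rows)
    tallies = {
        "n_psms_input": len(psms),
        "n_psms_reconciled": len(final),
        "conflict_outcomes": dict(sorted(Counter(
            d.outcome if d.outcome != "excluded" else f"excluded:{d.reason}"
            for d in decisions.values()
        ).items())),
        "peptide_status": dict(sorted(Counter(
            r["status"] + (f":{r['reason']}" if r["reason"] else "")
            for r in rows
        ).items())),
    }
    return table, tallies, final


def prioritize_targets(peptide_table: pd.DataFrame, final_psms, n_cohort_samples: int,
                       homogeneity: dict[str, float] | None = None,
                       dependency: dict[str, float] | None = None) -> pd.DataFrame:
    """Seven-criterion scorecards for retained peptides."""
    scores_by_pep: dict[str, list[tuple]] = defaultdict(list)
    for p in final_psms:
        a = p.score if p.engine == "engine1" else None
        t = p.score if p.engine == "engine2" else None
        scores_by_pep[p.peptide].append((a, t))
    rows = []
    retained = peptide_table[peptide_table["status"] == "retained"]
    for _, r in retained.iterrows():
        pep = r["peptide"]
        card = score_target(
            target_id=pep,
            abundance=None if pd.isna(r["log2_abundance"]) else float(r["log2_abundance"]),
            sample_hits=set(str(r["samples"]).split(";")),
            n_cohort_samples=n_cohort_samples,
            psm_scores=scores_by_pep[pep],
            normal_rna_ok=True,
            normal_ip_ok=not r["normal_tissues"],
            binding_rank=None if pd.isna(r["best_rank"]) else float(r["best_rank"]),
            dependency=(dependency or {}).get(pep),
            homogeneity=(homogeneity or {}).get(pep),
        )
        rows.append(vars(card))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Full run: call-events -> build-space -> postprocess -> prioritize.
    Writes events.tsv, space.fasta, peptide_table.tsv, scorecards.tsv and
    report.json under ``config.out_dir``; returns the report dict."""
    bundle = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash

    events = call_events(bundle, config)
    events_df = pd.DataFrame([
        {"event_class": e.event_class, "event_id": e.event_id,
         "recurrence_freq": round(e.recurrence_freq, 6), "status": e.status,
         "reason": e.reason or "", "config_hash": chash}
        for e in events
    ]).sort_values(["event_class", "event_id"], kind="stable")
    events_df.to_csv(out / "events.tsv", sep="\t", index=False)

    space = build_space_from_bundle(bundle, config, events)
    afio.write_fasta(space.to_fasta_records(), out / "space.fasta")
    manifest_rows = [
        {"sequence": seq, "n_sources": len(heads), "sources": ";".join(heads)}
        for seq, heads in sorted(space.index.items())
    ]
    pd.DataFrame(manifest_rows, columns=["sequence", "n_sources", "sources"]).to_csv(
        out / "space_manifest.tsv", sep="\t", index=False
    )

    has_psms = (bundle / "engine1_psms.tsv").exists()
    if has_psms:
        peptide_table, psm_tallies, final = postprocess(bundle, config)
        peptide_table.insert(len(peptide_table.columns), "config_hash", chash)
        peptide_table.to_csv(out / "peptide_table.tsv", sep="\t", index=False)
        n_cohort = len(_read_tsv(bundle / "hla_alleles.tsv"))
        cards = prioritize_targets(peptide_table, final, n_cohort)
        if not cards.empty:
            cards.insert(len(cards.columns), "config_hash", chash)
        cards.to_csv(out / "scorecards.tsv", sep="\t", index=False)
    else:
        peptide_table, psm_tallies, cards = pd.DataFrame(), {}, pd.DataFrame()

    report = {
        "config_hash": chash,
        "config_overrides": config.overrides(),
        "stages": {
            "call_events": {
                "n_events": len(events),
                "by_class_status": dict(sorted(Counter(
                    f"{e.event_class}:{e.status}" for e in events
                ).items())),
                "rejection_reasons": dict(sorted(Counter(
                    f"{e.event_class}:{e.reason}" for e in events if not e.retained
                ).items())),
            },
            "build_space": {
                "n_unique_peptides": len(space.entries),
                "by_class": dict(sorted(Counter(
                    e.event_class for e in space.entries
                ).items())),
            },
            "postprocess": psm_tallies,
            "prioritize": {"n_scorecards": 0 if cards is None or len(cards) == 0 else len(cards)},
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
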
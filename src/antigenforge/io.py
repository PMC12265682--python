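"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Biopython, GTF via pyranges (which performs the 1-based-closed to
0-based-half-open conversion), VCF via pysam, BED6 as plain TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import pyranges
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import GenomeRef, TranscriptModel


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=header, description="") for header, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_genome(path: str | Path) -> GenomeRef:
    return GenomeRef(read_fasta(path))


def read_gtf_models(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from a GTF with exon features carrying
    gene_id and transcript_id attributes."""
    df = pyranges.read_gtf(str(path)).df
    if df.empty:
        return []
    exons = df[df["Feature"] == "exon"]
    if {"gene_id", "transcript_id"} - set(exons.columns):
        raise ValueError("GTF exons lack gene_id/transcript_id attributes")
    models = []
    for (gid, tid), grp in exons.groupby(["gene_id", "transcript_id"], sort=True):
        contig = grp["Chromosome"].iloc[0]
        strand = grp["Strand"].iloc[0]
        ivs = sorted(zip(grp["Start"].astype(int), grp["End"].astype(int)))
        models.append(TranscriptModel(gid, tid, str(contig), str(strand), ivs))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    lines = []
    for m in models:
        for s, e in m.exons:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            lines.append(
                f"{m.contig}\tantigenforge\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_variant_vcf(path: str | Path):
    """Yield variant dictionaries from a VCF annotated with DBSNP_AF, REDI,
    COSMIC and CSQ (consequence) INFO keys; VAFs are taken from the sample
    FORMAT field VAF when present, else from the INFO key VAF."""
    from .events import VariantRecord

    vcf = pysam.VariantFile(str(path))
    out: list[VariantRecord] = []
    for rec in vcf:
        info = rec.info
        vafs = []
        for sample in rec.samples.values():
            if "VAF" in sample and sample["VAF"] is not None:
                v = sample["VAF"]
                vafs.extend(v if isinstance(v, tuple) else [v])
        if not vafs and "VAF" in info:
            v = info["VAF"]
            vafs = list(v) if isinstance(v, tuple) else [v]
        out.append(
            VariantRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0] if rec.alts else "",
                consequence=str(info.get("CSQ", "other")),
                vaf_per_sample=[float(v) for v in vafs],
                dbsnp_freq=(
                    float(info["DBSNP_AF"]) if "DBSNP_AF" in info else None
                ),
                in_rediportal=bool(info.get("REDI", False)),
                in_cosmic=bool(info.get("COSMIC", False)),
            )
        )
    return out


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DBSNP_AF,Number=1,Type=Float,Description="dbSNP population allele frequency">
##INFO=<ID=REDI,Number=0,Type=Flag,Description="Present in REDIportal RNA-editing database">
##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Confirmed somatic in COSMIC">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=VAF,Number=.,Type=Float,Description="Variant allele fractions across tumor samples">
"""


def write_variant_vcf(variants, contig_lengths: dict[str, int], path: str | Path) -> None:
    lines = [VCF_HEADER.rstrip()]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        info = [f"CSQ={v.consequence}"]
        if v.dbsnp_freq is not None:
            info.append(f"DBSNP_AF={v.dbsnp_freq}")
        if v.in_rediportal:
            info.append("REDI")
        if v.in_cosmic:
            info.append("COSMIC")
        if v.vaf_per_sample:
            info.append("VAF=" + ",".join(f"{x:g}" for x in v.vaf_per_sample))
        lines.append(
            f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
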
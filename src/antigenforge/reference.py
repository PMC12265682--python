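"""Genomic data model and core sequence operations.

Coordinates are 0-based half-open internally. GTF input (1-based closed) is
converted on read; VCF positions stay 1-based in :class:`VariantRecord`-style
records and are converted where arithmetic is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_NT = frozenset("ACGTN")

_RC = str.maketrans("ACGTN", "TGCAN")

#: codon -> amino acid maps; tables 1 (standard) and 11 (bacterial/archaeal)
#: share internal codon assignments but are kept distinct for clarity.
_TABLES = {
    "standard": CodonTable.unambiguous_dna_by_id[1],
    "prokaryotic-11": CodonTable.unambiguous_dna_by_id[11],
}


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T,N}."""


def _check_nt(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_NT
    if bad:
        raise SequenceError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def translate_nt(seq: str, frame: int = 0, table: str = "standard") -> str:
    """Translate ``seq`` from codon offset ``frame`` (0, 1 or 2).

    Stop codons are rendered ``*`` and translation does not stop at them;
    any codon containing N yields ``X``. Trailing bases short of a codon
    are ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = _check_nt(seq)
    tbl = _TABLES[table]
    fwd = tbl.forward_table
    stops = set(tbl.stop_codons)
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            out.append("*")
        else:
            out.append(fwd[codon])
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return _check_nt(seq).translate(_RC)[::-1]


@dataclass
class GenomeRef:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            cleaned[name] = _check_nt(seq)
        self.contigs = cleaned

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError("exons overlap")
            prev_end = e
        if self.cds_start is not None and not any(
            s <= self.cds_start < e for s, e in self.exons
        ):
            raise ValueError("cds_start outside exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class CollapsedIntron:
    gene_id: str
    contig: str
    interval: tuple[int, int]
    flag_cross_gene_exon_overlap: bool = False


@dataclass
class SpliceJunction:
    """A splice junction keyed by (contig, donor_end, acceptor_start, strand).

    ``donor_end`` is the exclusive end of the upstream exon and
    ``acceptor_start`` the inclusive start of the downstream exon, both
    0-based; the intervening interval is the spliced-out intron.
    """

    contig: str
    donor_end: int
    acceptor_start: int
    strand: str
    tumor_counts: list[int] = field(default_factory=list)
    normal_counts: list[int] = field(default_factory=list)
    donor_annotated: bool = False
    acceptor_annotated: bool = False

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("donor_end must precede acceptor_start")
        if any(c < 0 for c in self.tumor_counts + self.normal_counts):
            raise ValueError("negative read count")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.donor_end, self.acceptor_start, self.strand)


def collapse_introns(
    models: list[TranscriptModel],
    all_models: Iterable[TranscriptModel] = (),
) -> list[CollapsedIntron]:
    """Collapse a gene's isoforms into constitutive introns.

    A base belongs to an intron only if it lies within the gene span and in
    no exon of any isoform. Introns overlapping an exon of a *different*
    gene are flagged ``flag_cross_gene_exon_overlap`` (excluded downstream,
    since read coverage there is ambiguous).
    """
    if not models:
        raise ValueError("no isoforms supplied")
    gene_id = models[0].gene_id
    contig = models[0].contig
    if any(m.gene_id != gene_id or m.contig != contig for m in models):
        raise ValueError("collapse_introns expects isoforms of one gene")

    span_start = min(m.span[0] for m in models)
    span_end = max(m.span[1] for m in models)
    exon_tree = IntervalTree()
    for m in models:
        for s, e in m.exons:
            exon_tree[s:e] = m.transcript_id
    exon_tree.merge_overlaps()
    covered = sorted((iv.begin, iv.end) for iv in exon_tree)

    other_tree = IntervalTree()
    for m in all_models:
        if m.gene_id == gene_id or m.contig != contig:
            continue
        for s, e in m.exons:
            other_tree[s:e] = m.gene_id

    introns: list[CollapsedIntron] = []
    cursor = span_start
    for s, e in covered:
        if s > cursor:
            flagged = bool(other_tree.overlap(cursor, s))
            introns.append(CollapsedIntron(gene_id, contig, (cursor, s), flagged))
        cursor = max(cursor, e)
    if cursor < span_end:  # cannot happen with sorted exons, kept defensive
        flagged = bool(other_tree.overlap(cursor, span_end))
        introns.append(CollapsedIntron(gene_id, contig, (cursor, span_end), flagged))
    return introns


def extract_junction_flanks(
    genome: GenomeRef, j: SpliceJunction, flank_nt: int = 33
) -> str:
    """Concatenate the ``flank_nt`` bases ending at the donor with the
    ``flank_nt`` bases starting at the acceptor.

    Minus-strand junctions are returned reverse-complemented so the result
    reads 5'->3' on the transcribed strand. Flanks are truncated (with a
    warning) at contig edges.
    """
    if j.contig not in genome:
        raise ValueError(f"unknown contig {j.contig!r}")
    contig_len = len(genome.contigs[j.contig])
    if not (0 < j.donor_end <= contig_len and 0 <= j.acceptor_start < contig_len):
        raise ValueError(f"junction {j.key} outside contig bounds")
    lo = max(0, j.donor_end - flank_nt)
    hi = min(contig_len, j.acceptor_start + flank_nt)
    if lo != j.donor_end - flank_nt or hi != j.acceptor_start + flank_nt:
        log.warning("junction %s flanks truncated at contig edge", j.key)
    seq = genome.fetch(j.contig, lo, j.donor_end) + genome.fetch(
        j.contig, j.acceptor_start, hi
    )
    return reverse_complement(seq) if j.strand == "-" else seq
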
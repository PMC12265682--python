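"""Translate retained events into candidate HLA-I peptides and assemble the
per-sample or per-tumor FASTA search space.

The minimum emitted peptide length is 8 aa, the shortest peptide the MS
searches consider; full proteins (annotated isoforms, microbial proteomes)
are exempt from that floor. Peptides containing 'X' (from N bases) or an
internal stop are dropped at assembly because they are unsearchable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .events import EventCall, FusionRecord
from .reference import (
    GenomeRef,
    SpliceJunction,
    extract_junction_flanks,
    reverse_complement,
    translate_nt,
)

log = logging.getLogger(__name__)

MIN_PEPTIDE_LEN = 8

with resources.files("antigenforge.data").joinpath("codon_usage.json").open() as _fh:
    #: human codon usage, frequency per thousand codons
    CODON_USAGE: dict[str, float] = json.load(_fh)

_USAGE_TOTAL = sum(CODON_USAGE.values())
_LOG_USAGE = {c: math.log(v / _USAGE_TOTAL) for c, v in CODON_USAGE.items()}


@dataclass
class PeptideEntry:
    sequence: str
    event_class: str
    event_id: str
    header: str = ""
    full_protein: bool = False

    def __post_init__(self) -> None:
        if not self.header:
            self.header = f"{self.event_class}|{self.event_id}"


@dataclass
class OrfCandidate:
    start: int
    end: int  # half-open on the transcript, stop codon included
    gc_fraction: float
    codon_potential: float
    peptide: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class SearchSpace:
    entries: list[PeptideEntry] = field(default_factory=list)
    index: dict[str, list[str]] = field(default_factory=dict)

    def to_fasta_records(self) -> list[tuple[str, str]]:
        return [(e.header, e.sequence) for e in self.entries]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "GC") / len(seq)


def codon_potential(seq: str) -> float:
    """Mean natural-log human codon-usage frequency per codon; any monotone
    codon-frequency score serves the ORF tie-break role."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
    vals = [_LOG_USAGE[c] for c in codons if c in _LOG_USAGE]
    return sum(vals) / len(vals) if vals else float("-inf")


def junction_peptides(
    genome: GenomeRef,
    j: SpliceJunction,
    event_id: str | None = None,
    flank_nt: int = 33,
    isoform_table: Mapping[tuple, str] | None = None,
) -> list[PeptideEntry]:
    """Three-frame translation of the junction's concatenated exon flanks;
    only stop-free translations are kept. A junction matching an annotated
    isoform yields the documented full isoform protein instead."""
    event_id = event_id or "|".join(map(str, j.key))
    if isoform_table and j.key in isoform_table:
        protein = isoform_table[j.key]
        return [
            PeptideEntry(protein, "splicing", event_id,
                         f"splicing|{event_id}|isoform", full_protein=True)
        ]
    try:
        seq = extract_junction_flanks(genome, j, flank_nt)
    except ValueError as exc:
        log.warning("skipping junction %s: %s", event_id, exc)
        return []
    out = []
    for frame in (0, 1, 2):
        pep = translate_nt(seq, frame)
        if pep and "*" not in pep:
            out.append(
                PeptideEntry(pep, "splicing", event_id, f"splicing|{event_id}|frame{frame}")
            )
    return out


def enumerate_orfs(transcript_nt: str) -> list[OrfCandidate]:
    """All complete ATG->stop ORFs on the given strand, stop codon included
    in the interval, excluded from the peptide."""
    seq = transcript_nt.upper()
    orfs = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in ("TAA", "TAG", "TGA"):
                coding = seq[start:pos]
                orfs.append(
                    OrfCandidate(
                        start=start,
                        end=pos + 3,
                        gc_fraction=gc_fraction(seq[start : pos + 3]),
                        codon_potential=codon_potential(coding),
                        peptide=translate_nt(coding) if coding else "",
                    )
                )
                break
    return orfs


def _orf_sort_key(o: OrfCandidate) -> tuple:
    # deterministic total order: length desc, then start asc, then sequence
    return (-o.length_nt, o.start, o.peptide)


def _tie_key(o: OrfCandidate) -> tuple:
    return (-o.gc_fraction, -o.codon_potential, o.start, o.peptide)


def select_intron_orf(
    transcript_nt: str,
    intron_interval_on_transcript: tuple[int, int],
    tie_window_nt: int = 8,
) -> tuple[OrfCandidate | None, list[str]]:
    """Pick the most probable ORF of an intron-retained transcript.

    Ranking is primarily by ORF length; when the top two lengths differ by
    less than ``tie_window_nt`` the near-tied set is re-ranked by GC
    fraction, then human codon potential, then leftmost start. The
    translated peptide is causal only when the ORF overlaps the retained
    intron interval.
    """
    lo, hi = intron_interval_on_transcript
    if not (0 <= lo < hi <= len(transcript_nt)):
        raise ValueError("intron interval outside transcript")
    orfs = sorted(enumerate_orfs(transcript_nt), key=_orf_sort_key)
    if not orfs:
        return None, []
    best = orfs[0]
    if len(orfs) > 1 and best.length_nt - orfs[1].length_nt < tie_window_nt:
        tied = [o for o in orfs if best.length_nt - o.length_nt < tie_window_nt]
        best = min(tied, key=_tie_key)
    overlaps = best.start < hi and best.end > lo
    return best, ([best.peptide] if overlaps and best.peptide else [])


def six_frame_fragments(seq: str, min_len: int = MIN_PEPTIDE_LEN) -> list[tuple[str, str]]:
    """(frame_tag, fragment) for all stop-split fragments >= min_len over
    3 frames x 2 strands."""
    out = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in (0, 1, 2):
            pep = translate_nt(s, frame)
            for k, frag in enumerate(pep.split("*")):
                if len(frag) >= min_len:
                    out.append((f"{strand}{frame}.{k}", frag))
    return out


def te_peptides(
    genome: GenomeRef, locus: EventCall, min_len: int = MIN_PEPTIDE_LEN
) -> list[PeptideEntry]:
    """Six-frame translation of a retained TE locus (sense and antisense),
    split at stops, fragments >= ``min_len`` aa emitted."""
    contig = locus.evidence["contig"]
    start, end = locus.evidence["interval"]
    if contig not in genome or end > len(genome.contigs[contig]) or start < 0:
        raise ValueError(f"TE locus {locus.event_id} outside contig")
    seq = genome.fetch(contig, start, end)
    return [
        PeptideEntry(frag, locus.event_class, locus.event_id,
                     f"{locus.event_class}|{locus.event_id}|{tag}")
        for tag, frag in six_frame_fragments(seq, min_len)
    ]


@dataclass
class MappedVariant:
    """A retained variant projected onto a coding sequence.

    ``cds_pos`` is the 0-based offset of the first reference base of the
    edit within ``cds_nt``; ``ref``/``alt`` are the edited nucleotides.
    """

    kind: str  # missense | inframe_insertion | inframe_deletion | frameshift
    cds_pos: int
    ref: str
    alt: str
    variant_id: str = ""


def mutation_peptides(
    protein: str,
    cds_nt: str,
    v: MappedVariant,
    window: int = 14,
    min_tail_aa: int = 8,
) -> list[PeptideEntry]:
    """Peptides carrying a coding variant.

    Missense and in-frame indels emit a window of up to ``window`` residues
    each side of the altered segment (enough to cover every 8-15-mer
    spanning it). Frameshifts translate the new frame to the first stop and
    emit the novel tail plus ``window`` upstream wild-type residues; tails
    shorter than ``min_tail_aa`` are dropped.
    """
    if cds_nt[v.cds_pos : v.cds_pos + len(v.ref)] != v.ref:
        raise ValueError(
            f"reference mismatch at CDS position {v.cds_pos}: "
            f"expected {v.ref!r}, found {cds_nt[v.cds_pos : v.cds_pos + len(v.ref)]!r}"
        )
    mutant_cds = cds_nt[: v.cds_pos] + v.alt + cds_nt[v.cds_pos + len(v.ref) :]
    mutant_full = translate_nt(mutant_cds)
    mutant = mutant_full.split("*")[0]
    aa_pos = v.cds_pos // 3
    vid = v.variant_id or f"cds{v.cds_pos}:{v.ref}>{v.alt}"

    if v.kind == "missense":
        if aa_pos >= len(mutant):
            return []
        lo = max(0, aa_pos - window)
        hi = min(len(mutant), aa_pos + window + 1)
        pep = mutant[lo:hi]
        return [PeptideEntry(pep, "variant", vid, f"variant|{vid}|missense")]

    if v.kind in ("inframe_insertion", "inframe_deletion"):
        shift = len(v.alt) - len(v.ref)
        if shift % 3 != 0:
            raise ValueError(f"{v.kind} with frame-shifting length change")
        altered_len = max(1, 1 + max(0, shift) // 3)
        lo = max(0, aa_pos - window)
        hi = min(len(mutant), aa_pos + altered_len + window)
        pep = mutant[lo:hi]
        return [PeptideEntry(pep, "variant", vid, f"variant|{vid}|{v.kind}")] if pep else []

    if v.kind == "frameshift":
        tail = mutant[aa_pos:]
        if len(tail) < min_tail_aa:
            return []
        lo = max(0, aa_pos - window)
        pep = protein[lo:aa_pos] + tail
        return [PeptideEntry(pep, "variant", vid, f"variant|{vid}|frameshift")]

    raise ValueError(f"unsupported variant kind {v.kind!r}")


class FrameUnresolvableError(ValueError):
    pass


def fusion_peptides(
    f: FusionRecord, cds5_nt: str, cds3_nt: str, flank_codons: int = 14
) -> PeptideEntry | None:
    """Junction-spanning fusion peptide: ``flank_codons`` codons upstream of
    the 5' breakpoint concatenated in frame with the same downstream of the
    3' breakpoint, translated, truncated at the first stop.

    ``cds5_nt`` is the in-frame coding sequence ending at the breakpoint;
    ``cds3_nt`` continues in frame from the breakpoint.
    """
    if len(cds5_nt) % 3 != 0:
        raise FrameUnresolvableError(
            f"5' segment of {f.fusion_id} does not end at a codon boundary"
        )
    up = cds5_nt[-3 * flank_codons :]
    down = cds3_nt[: 3 * flank_codons]
    pep = translate_nt(up + down).split("*")[0]
    if not pep:
        return None
    return PeptideEntry(pep, "fusion", f.fusion_id, f"fusion|{f.fusion_id}|junction")


def build_microbial_proteome(
    cds_records: Iterable[tuple[str, str]]
) -> list[PeptideEntry]:
    """Prokaryotic proteome from CDS records: keep only sequences with
    length divisible by three, translate with NCBI codon table 11, keep
    only full-length proteins free of premature stops (trailing stop
    stripped)."""
    out = []
    n_len = n_stop = 0
    for cds_id, seq in cds_records:
        if len(seq) % 3 != 0:
            n_len += 1
            continue
        pep = translate_nt(seq, 0, table="prokaryotic-11")
        if pep.endswith("*"):
            pep = pep[:-1]
        if not pep or "*" in pep:
            n_stop += 1
            continue
        out.append(
            PeptideEntry(pep, "microbiome", cds_id, f"microbiome|{cds_id}|cds",
                         full_protein=True)
        )
    if n_len or n_stop:
        log.info("microbial proteome: dropped %d CDS off-frame, %d with premature stops",
                 n_len, n_stop)
    return out


_NUORF_CLASSES = {"cryptic_orf", "lncRNA", "pseudogene"}


def assemble_search_space(
    entry_lists: Iterable[Iterable[PeptideEntry]],
    include_nuorf: Mapping[str, str] | None = None,
    min_len: int = MIN_PEPTIDE_LEN,
) -> SearchSpace:
    """Concatenate per-class peptide lists into a deduplicated search space.

    Entries containing 'X' or '*' are dropped; identical sequences merge
    their provenance. ``include_nuorf`` maps FASTA headers to sequences from
    a ribosome-profiling-informed database of translatable lncRNAs,
    pseudogenes and cryptic ORFs; the leading |-separated header field names
    the class. Assembly is idempotent.
    """
    flat: list[PeptideEntry] = [e for lst in entry_lists for e in lst]
    if include_nuorf:
        for header, seq in include_nuorf.items():
            first = header.split("|")[0]
            cls = first if first in _NUORF_CLASSES else "cryptic_orf"
            eid = header.split("|")[1] if "|" in header else header
            flat.append(PeptideEntry(seq.upper(), cls, eid,
                                     f"{cls}|{eid}", full_protein=True))
    space = SearchSpace()
    for e in flat:
        if "*" in e.sequence or "X" in e.sequence:
            continue
        if len(e.sequence) < min_len and not e.full_protein:
            continue
        if e.sequence in space.index:
            if e.header not in space.index[e.sequence]:
                space.index[e.sequence].append(e.header)
        else:
            space.index[e.sequence] = [e.header]
            space.entries.append(e)
    if not space.entries:
        log.warning("assembled search space is empty")
    return space
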
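import numpy as np
import pytest
from Bio.Seq import Seq

from antigenforge.events import EventCall, FusionRecord
from antigenforge.reference import GenomeRef, SpliceJunction
from antigenforge.space import (
    FrameUnresolvableError,
    MappedVariant,
    PeptideEntry,
    assemble_search_space,
    build_microbial_proteome,
    enumerate_orfs,
    fusion_peptides,
    junction_peptides,
    mutation_peptides,
    select_intron_orf,
    six_frame_fragments,
    te_peptides,
)

NONSTOP = [c for c in
           ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
           if c not in ("TAA", "TAG", "TGA")]


def random_genome(rng, n=2000):
    return GenomeRef({"c1": "".join(rng.choice(list("ACGT"), size=n))})


class TestJunctionPeptides:
    def test_matches_slice_and_translate_oracle(self, rng):
        genome = random_genome(rng)
        seq = genome.contigs["c1"]
        j = SpliceJunction("c1", 400, 900, "+", [50], [], True, True)
        flank = seq[400 - 33 : 400] + seq[900 : 900 + 33]
        expected = [
            str(Seq(flank[f : f + (66 - f) // 3 * 3]).translate())
            for f in (0, 1, 2)
        ]
        expected = [p for p in expected if "*" not in p]
        got = [e.sequence for e in junction_peptides(genome, j)]
        assert got == expected

    def test_all_frames_stopped_is_empty(self):
        # "TAAGTAAGTAA" holds a stop in every frame; period 11 keeps the
        # flank start aligned so each of the three translations hits one
        genome = GenomeRef({"c1": "TAAGTAAGTAA" * 30})
        j = SpliceJunction("c1", 99, 150, "+", [50], [], True, True)
        assert junction_peptides(genome, j) == []

    def test_annotated_isoform_replaces_local_translation(self, rng):
        genome = random_genome(rng)
        j = SpliceJunction("c1", 400, 900, "+", [50], [], True, True)
        table = {j.key: "MSPLENDIDISOFORM"}
        out = junction_peptides(genome, j, isoform_table=table)
        assert [e.sequence for e in out] == ["MSPLENDIDISOFORM"]
        assert out[0].full_protein


def _oracle_orfs(seq):
    """Independent enumeration: regex-free scan for ATG..stop in each offset."""
    found = []
    for start in range(len(seq)):
        if seq[start : start + 3] != "ATG":
            continue
        pos = start
        while pos + 3 <= len(seq):
            c = seq[pos : pos + 3]
            if c in ("TAA", "TAG", "TGA"):
                found.append((start, pos + 3))
                break
            pos += 3
    return sorted(found)


class TestIntronOrfSelection:
    def test_longest_orf_wins(self):
        orf_a = "ATG" + "GAA" * 38 + "TAA"   # 120 nt
        orf_b = "ATG" + "GGC" * 18 + "TGA"   # 60 nt
        tx = orf_a + "CCCCCCC" + orf_b
        best, _ = select_intron_orf(tx, (0, 10))
        assert (best.start, best.length_nt) == (0, 120)

    def test_gc_tiebreak_inside_window(self):
        orf_a = "ATG" + "GAA" * 38 + "TAA"   # 120 nt, GC 0.325
        orf_b = "ATG" + "GGC" * 36 + "TGA"   # 114 nt, GC ~0.965, gap 6 < 8
        tx = orf_a + "CCCCCCC" + orf_b
        best, _ = select_intron_orf(tx, (0, len(tx)))
        assert best.start == len(orf_a) + 7
        assert best.gc_fraction > 0.9

    def test_causal_requires_intron_overlap(self):
        orf = "ATG" + "GAA" * 38 + "TAA"
        tx = orf + "CCCCCCC" + "ATGGGCTGA"
        best, causal = select_intron_orf(tx, (len(tx) - 2, len(tx)))
        assert best.length_nt == 120
        assert causal == []
        _, causal2 = select_intron_orf(tx, (0, 10))
        assert causal2 == [best.peptide]

    def test_no_orf_is_empty_result(self):
        best, causal = select_intron_orf("CCCCCCCCCC", (0, 5))
        assert best is None and causal == []

    def test_enumeration_matches_oracle(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 600))))
            got = sorted((o.start, o.end) for o in enumerate_orfs(seq))
            assert got == _oracle_orfs(seq)


def _sixframe_oracle(seq, min_len=8):
    frags = []
    for s in (seq, str(Seq(seq).reverse_complement())):
        for f in (0, 1, 2):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            for frag in str(Seq(sub).translate()).split("*"):
                if len(frag) >= min_len:
                    frags.append(frag)
    return sorted(frags)


class TestTEPeptides:
    def locus(self, contig="c1", interval=(100, 400)):
        return EventCall("te_self", "LTR_x",
                         evidence={"contig": contig, "interval": interval})

    def test_sixty_nt_stop_free_in_all_frames_gives_six_entries(self):
        # poly-GGC is stop-free in every frame on both strands
        genome = GenomeRef({"c1": "A" * 100 + "GGC" * 20 + "A" * 100})
        out = te_peptides(genome, self.locus(interval=(100, 160)), min_len=1)
        assert len(out) == 6

    def test_short_fragments_dropped(self):
        # a 21-nt locus cannot yield any 8-aa fragment
        genome = GenomeRef({"c1": "GGC" * 30})
        assert te_peptides(genome, self.locus(interval=(0, 21))) == []

    def test_matches_sixframe_oracle(self, rng):
        genome = random_genome(rng)
        out = te_peptides(genome, self.locus(interval=(300, 900)))
        assert sorted(e.sequence for e in out) == _sixframe_oracle(
            genome.contigs["c1"][300:900]
        )

    def test_locus_outside_contig_errors(self):
        genome = GenomeRef({"c1": "ACGT" * 50})
        with pytest.raises(ValueError):
            te_peptides(genome, self.locus(interval=(100, 900)))


def make_cds(rng, n_codons=100):
    return "ATG" + "".join(rng.choice([c for c in NONSTOP if c != "ATG"],
                                      size=n_codons - 2)) + "TAA"


class TestMutationPeptides:
    def setup_variant(self, rng, aa_index, kind="missense", alt=None):
        cds = make_cds(rng)
        protein = str(Seq(cds).translate()).rstrip("*")
        pos = aa_index * 3
        ref = cds[pos]
        if alt is None:
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        return protein, cds, MappedVariant(kind, pos, ref, alt, "v1")

    def test_missense_window_29aa_centered(self, rng):
        protein, cds, v = self.setup_variant(rng, 19)  # residue 20, 1-based
        (entry,) = mutation_peptides(protein, cds, v)
        assert len(entry.sequence) == 29
        mutant_protein = str(Seq(cds[:v.cds_pos] + v.alt + cds[v.cds_pos + 1:])
                             .translate()).rstrip("*")
        assert entry.sequence == mutant_protein[5:34]
        assert entry.sequence[14] == mutant_protein[19]

    def test_missense_near_start_clamps(self, rng):
        protein, cds, v = self.setup_variant(rng, 2)  # residue 3
        (entry,) = mutation_peptides(protein, cds, v)
        assert len(entry.sequence) == 2 + 1 + 14

    def test_frameshift_immediate_stop_emits_nothing(self, rng):
        cds = make_cds(rng)
        protein = str(Seq(cds).translate()).rstrip("*")
        # insert one base creating a stop right at the shift site
        pos = 30
        v = MappedVariant("frameshift", pos, cds[pos], "T" + "AA", "v2")
        # TAA directly after shift: mutant codon at aa 10 becomes stop
        mutant = cds[:pos] + v.alt + cds[pos + 1:]
        if "*" in str(Seq(mutant[: len(mutant) // 3 * 3]).translate())[10:11]:
            assert mutation_peptides(protein, cds, v) == []

    def test_frameshift_tail_with_upstream_context(self, rng):
        cds = make_cds(rng)
        protein = str(Seq(cds).translate()).rstrip("*")
        pos = 60
        v = MappedVariant("frameshift", pos, cds[pos], cds[pos] + "G", "v3")
        out = mutation_peptides(protein, cds, v)
        if out:  # tail length depends on where the new frame hits a stop
            (entry,) = out
            assert entry.sequence.startswith(protein[6:20])

    def test_reference_mismatch_errors(self, rng):
        protein, cds, v = self.setup_variant(rng, 10)
        v.ref = "A" if v.ref != "A" else "C"
        if cds[v.cds_pos] != v.ref:
            with pytest.raises(ValueError):
                mutation_peptides(protein, cds, v)


class TestFusionPeptides:
    def f(self):
        return FusionRecord("A", "B", ("c1", 1, "+"), ("c2", 2, "+"), "in-frame", set())

    def test_clean_fusion_matches_translate_oracle(self, rng):
        cds5 = "".join(rng.choice(NONSTOP, size=30))
        cds3 = "".join(rng.choice(NONSTOP, size=30))
        entry = fusion_peptides(self.f(), cds5, cds3)
        expected = str(Seq(cds5[-42:] + cds3[:42]).translate()).split("*")[0]
        assert entry.sequence == expected
        assert len(entry.sequence) == 28

    def test_stop_after_junction_truncates(self, rng):
        cds5 = "".join(rng.choice(NONSTOP, size=20))
        cds3 = "".join(rng.choice(NONSTOP, size=2)) + "TAA" + "".join(
            rng.choice(NONSTOP, size=10))
        entry = fusion_peptides(self.f(), cds5, cds3)
        assert len(entry.sequence) == 14 + 2

    def test_short_5p_clamps(self, rng):
        cds5 = "".join(rng.choice(NONSTOP, size=5))  # 15 nt < 42
        cds3 = "".join(rng.choice(NONSTOP, size=30))
        entry = fusion_peptides(self.f(), cds5, cds3)
        assert len(entry.sequence) == 5 + 14

    def test_off_frame_5p_is_unresolvable(self):
        with pytest.raises(FrameUnresolvableError):
            fusion_peptides(self.f(), "ATGGC", "ATGGCA")


class TestMicrobialProteome:
    def test_examples(self):
        out = build_microbial_proteome([("a", "ATGGCAGGTTAA")])
        assert [e.sequence for e in out] == ["MAG"]
        assert build_microbial_proteome([("b", "ATGGCAGGTT")]) == []  # 10 nt
        assert build_microbial_proteome([("c", "ATGTAGGGTTAA")]) == []  # internal stop

    def test_gtg_start_is_not_special_internally(self):
        # table 11 translates GTG as valine when not treated as a start
        (entry,) = build_microbial_proteome([("d", "ATGGTGGGTTAA")])
        assert entry.sequence == "MVG"


class TestAssemble:
    def e(self, seq, cls="splicing", eid="e1"):
        return PeptideEntry(seq, cls, eid)

    def test_dedup_merges_provenance(self):
        space = assemble_search_space([
            [self.e("PEPTIDEKL", "splicing", "j1")],
            [self.e("PEPTIDEKL", "te_self", "t1")],
        ])
        assert len(space.entries) == 1
        assert space.index["PEPTIDEKL"] == ["splicing|j1", "te_self|t1"]

    def test_drops_x_stop_and_short(self):
        space = assemble_search_space([[
            self.e("PEPXTIDEK"), self.e("PEP*TIDEK"), self.e("SHORT"),
            self.e("GOODPEPTIDE"),
        ]])
        assert [x.sequence for x in space.entries] == ["GOODPEPTIDE"]

    def test_nuorf_classes_from_header_tag(self):
        space = assemble_search_space(
            [], include_nuorf={"lncRNA|l1": "AAAAAAAAAA",
                               "pseudogene|p1": "CCCCCCCCCC",
                               "unknowntag|u1": "DDDDDDDDDD"})
        classes = {e.event_id: e.event_class for e in space.entries}
        assert classes == {"l1": "lncRNA", "p1": "pseudogene", "u1": "cryptic_orf"}

    def test_idempotent(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        entries = [self.e("".join(rng.choice(aa, size=12)), "te_self", f"t{i}")
                   for i in range(30)]
        once = assemble_search_space([entries])
        twice = assemble_search_space([once.entries])
        assert [e.sequence for e in twice.entries] == [e.sequence for e in once.entries]

    def test_empty_space_warns_via_empty_result(self):
        assert assemble_search_space([]).entries == []
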
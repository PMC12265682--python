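import itertools
import math

import numpy as np
import pytest

from antigenforge.events import (
    ClassifiedRead,
    ExpressionProfile,
    FusionRecord,
    GeneSafetyRecord,
    VariantRecord,
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
from antigenforge.events import EventCall
from antigenforge.reference import CollapsedIntron, SpliceJunction


def tpm(entity, tumor, normal):
    return ExpressionProfile(entity, tumor, normal, "TPM")


def cpm(entity, tumor, normal):
    return ExpressionProfile(entity, tumor, normal, "CPM")


def safety(bayes=0.1, normal_max=2.0, p=0.01, lfc=1.0):
    return GeneSafetyRecord("g", bayes, normal_max, p, lfc)


class TestSelfGene:
    def test_clear_positive(self):
        assert filter_self_gene(tpm("g", [25, 25, 25], [1]), safety()).retained

    @pytest.mark.parametrize(
        "kwargs,tumor,reason",
        [
            (dict(), [20, 20, 20], "tumor_median_low"),      # boundary: strict >20
            (dict(normal_max=30.0), [25, 25, 25], "normal_expressed"),
            (dict(bayes=0.3), [25, 25, 25], "bayes_ts"),     # boundary: strict <0.3
            (dict(p=0.5), [25, 25, 25], "not_upregulated"),
            (dict(lfc=0.58), [25, 25, 25], "not_upregulated"),  # boundary: strict >0.58
        ],
    )
    def test_single_criterion_failures(self, kwargs, tumor, reason):
        ev = filter_self_gene(tpm("g", tumor, [1]), safety(**kwargs))
        assert (ev.status, ev.reason) == ("rejected", reason)

    def test_absent_de_data_is_not_rejection(self):
        ev = filter_self_gene(tpm("g", [25] * 3, [1]), safety(p=None, lfc=None))
        assert ev.retained

    def test_missing_safety_record(self):
        ev = filter_self_gene(tpm("g", [25] * 3, [1]), None)
        assert ev.reason == "no_safety_profile"


def junction(t, n, d_ann=True, a_ann=True):
    return SpliceJunction("c1", 100, 200, "+", t, n, d_ann, a_ann)


class TestJunctionFilter:
    def test_hand_computed_lfc_with_pseudocount(self):
        # mean_t=12, mean_n=0.5: log2(12.01/0.51) = 4.558 > 4 -> retained
        ev = filter_junction(junction([12, 12], [0.5, 0.5]))
        assert ev.retained
        assert ev.evidence["lfc"] == pytest.approx(math.log2(12.01 / 0.51))

    def test_no_annotated_site_discarded(self):
        ev = filter_junction(junction([50] * 4, [0] * 2, False, False))
        assert ev.reason == "no_annotated_site"

    def test_normal_expression_strict(self):
        assert filter_junction(junction([12] * 4, [1.2] * 2)).reason == "normal_expressed"
        assert filter_junction(junction([12] * 4, [1.0] * 2)).reason == "normal_expressed"

    def test_tumor_count_boundary(self):
        assert filter_junction(junction([10] * 4, [0] * 2)).reason == "tumor_count_low"

    def test_tumor_monotonicity(self, rng):
        # raising tumor counts (normals fixed) never flips retained->rejected
        for _ in range(50):
            t = list(rng.integers(0, 40, size=5).astype(float))
            n = list(np.round(rng.uniform(0, 2, size=3), 2))
            before = filter_junction(junction(t, n)).retained
            after = filter_junction(junction([x * 3 for x in t], n)).retained
            assert after or not before


class TestIntronRetention:
    def intron(self, flagged=False):
        return CollapsedIntron("g1", "c1", (100, 200), flagged)

    def test_decision_table(self):
        assert call_intron_retention(self.intron(), True, 30.0, False).retained
        assert call_intron_retention(self.intron(), False, 30.0, False).reason == "no_readthrough"
        assert call_intron_retention(self.intron(), True, 30.0, True).reason == "normal_presence"

    def test_cross_gene_flag_is_input_error(self):
        with pytest.raises(ValueError):
            call_intron_retention(self.intron(flagged=True), True, 30.0, False)

    def test_tpm_proxy_stored(self):
        ev = call_intron_retention(self.intron(), True, 17.5, False)
        assert ev.evidence["exon_tpm_proxy"] == 17.5


class TestAutonomousTE:
    def test_hand_computed_positive(self):
        ev = filter_autonomous_te(cpm("te", [2, 2, 2], [0.0]))
        assert ev.retained
        assert ev.evidence["lfc"] == pytest.approx(math.log2(2.01 / 0.01))

    def test_lfc_only_failure(self):
        ev = filter_autonomous_te(cpm("te", [1.5] * 3, [0.4]))
        assert ev.reason == "lfc"
        assert ev.evidence["lfc"] == pytest.approx(math.log2(1.51 / 0.41))

    def test_median_boundary_strict(self):
        assert filter_autonomous_te(cpm("te", [1.0] * 3, [0.0])).reason == "tumor_median_low"

    def test_unit_mismatch(self):
        with pytest.raises(ValueError):
            filter_autonomous_te(tpm("te", [2] * 3, [0.0]))

    def test_normal_monotonicity(self, rng):
        for _ in range(50):
            t = list(np.round(rng.uniform(0, 4, size=5), 2))
            n = list(np.round(rng.uniform(0, 1, size=3), 2))
            before = filter_autonomous_te(cpm("te", t, n)).retained
            after = filter_autonomous_te(cpm("te", t, [x + 1 for x in n])).retained
            assert before or not after


class TestTEChimeric:
    LOCI = [("c1", 150, 400, "LINE1_a"), ("c1", 500, 600, "LTR_b")]

    def test_acceptor_inside_te(self):
        j = SpliceJunction("c1", 100, 200, "+")
        ev = classify_te_chimeric(j, self.LOCI)
        assert ev is not None
        assert [s["side"] for s in ev.evidence["sides"]] == ["acceptor"]

    def test_no_side_in_te(self):
        assert classify_te_chimeric(SpliceJunction("c1", 50, 700, "+"), self.LOCI) is None

    def test_both_sides_recorded(self):
        j = SpliceJunction("c1", 300, 550, "+")
        ev = classify_te_chimeric(j, self.LOCI)
        assert sorted(s["side"] for s in ev.evidence["sides"]) == ["acceptor", "donor"]


def variant(ref="C", alt="T", consequence="missense", vafs=(0.4,),
            dbsnp=None, redi=False, cosmic=False):
    return VariantRecord("c1", 100, ref, alt, consequence, list(vafs),
                         dbsnp, redi, cosmic)


class TestVariant:
    def test_likely_somatic(self):
        ev = classify_variant(variant(dbsnp=0.00005, vafs=(0.9,)))
        assert ev.retained and ev.evidence["label"] == "likely_somatic"

    def test_high_vaf_without_cosmic_is_germline_but_retained(self):
        ev = classify_variant(variant(vafs=(0.97,)))
        assert ev.retained and ev.evidence["label"] == "germline_or_clonal"

    def test_a_to_g_flagged_as_editing(self):
        ev = classify_variant(variant(ref="A", alt="G", vafs=(0.3,)))
        assert ev.retained and ev.evidence["likely_rna_editing"]

    def test_unsupported_consequence(self):
        assert classify_variant(variant(consequence="other")).reason == "consequence"

    def test_exhaustive_decision_grid(self):
        # 2x2x2x2 grid over (dbsnp-low, rediportal, vaf-ok, cosmic)
        for dbl, redi, vaf_ok, cosmic in itertools.product([True, False], repeat=4):
            v = variant(
                dbsnp=0.00005 if dbl else 0.5,
                redi=redi,
                vafs=(0.5,) if vaf_ok else (0.97,),
                cosmic=cosmic,
            )
            ev = classify_variant(v)
            expected = (dbl and not redi and vaf_ok) or cosmic
            assert ev.retained
            assert (ev.evidence["label"] == "likely_somatic") == expected


class TestFusion:
    def f(self, frame="in-frame", labels=()):
        return FusionRecord("A", "B", ("c1", 10, "+"), ("c2", 20, "+"),
                            frame, set(labels))

    def test_clean_in_frame_retained(self):
        assert filter_fusion(self.f()).retained

    def test_blocklist_label(self):
        assert filter_fusion(self.f(labels={"BodyMap"})).reason == "blocklist"

    def test_frameshift(self):
        assert filter_fusion(self.f(frame="frameshift")).reason == "frame"


class TestMicrobiome:
    TAX = {"S1": "G1", "S2": "G2", "S3": "G3"}

    def reads(self, species, n, conf):
        return [ClassifiedRead(f"{species}_{i}", species, conf) for i in range(n)]

    def test_confidence_gate(self):
        calls = filter_microbiome(
            self.reads("S1", 5, 0.95) + self.reads("S2", 5, 0.85),
            set(), {}, self.TAX)
        assert [c.event_id for c in calls] == ["S1"]
        assert calls[0].evidence["read_count"] == 5

    def test_normal_species_and_genus_background(self):
        calls = filter_microbiome(
            self.reads("S1", 5, 0.95) + self.reads("S2", 5, 0.95),
            normal_species={"S1"},
            normal_genus_read_counts={"G2": 50},
            taxonomy=self.TAX,
        )
        by_id = {c.event_id: c for c in calls}
        assert by_id["S1"].reason == "normal_species"
        assert by_id["S2"].reason == "genus_background"

    def test_missing_taxonomy_errors(self):
        with pytest.raises(ValueError):
            filter_microbiome(self.reads("S9", 2, 0.95), set(), {}, self.TAX)

    def test_tallies_match_groupby_oracle(self, rng):
        species = [f"S{i}" for i in range(6)]
        tax = {s: f"G{i % 3}" for i, s in enumerate(species)}
        reads = [
            ClassifiedRead(f"r{i}", str(rng.choice(species)), float(rng.uniform(0.5, 1)))
            for i in range(300)
        ]
        calls = filter_microbiome(reads, set(), {}, tax)
        oracle = {}
        for r in reads:
            if r.kmer_confidence > 0.9:
                oracle[r.taxon_id] = oracle.get(r.taxon_id, 0) + 1
        assert {c.event_id: c.evidence["read_count"] for c in calls} == oracle


class TestRecurrenceGate:
    def ev(self, cls, freq):
        return EventCall(cls, f"{cls}_x", recurrence_freq=freq)

    def test_thresholds(self):
        out = recurrence_gate(
            [self.ev("splicing", 0.30), self.ev("intron_retention", 0.10),
             self.ev("splicing", 0.20)],
            n_tumor_samples=10,
        )
        assert out[0].retained
        assert out[1].reason == "recurrence"
        assert out[2].reason == "recurrence"  # boundary equality rejects

    def test_per_sample_mode_bypasses(self):
        out = recurrence_gate([self.ev("splicing", 0.0)], 1, per_sample_mode=True)
        assert out[0].retained

    def test_unknown_class_key_is_config_error(self):
        with pytest.raises(ValueError):
            recurrence_gate([self.ev("splicing", 0.5)], 10, {"bogus": 0.1})
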
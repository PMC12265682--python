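"""Reconciliation and filtering of peptide-spectrum matches from two search
engines, followed by HLA-binding, normal-tissue safety and abundance steps.

Engine 1 is a MaxQuant-style search (Andromeda score, posterior error
probability, rescored q-value, 8-11-mer HLA-I setting); engine 2 is a
deep-learning search (Tesorai-style score and q-value, 8-15-mer). The
conflict table and its score cutoffs (Andromeda 70, Tesorai 5) treat
boundary equality as the low side of each strict comparison.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)

ENGINE1 = "engine1"
ENGINE2 = "engine2"

ANDROMEDA_HIGH = 70.0
TESORAI_HIGH = 5.0

ESSENTIAL_EXEMPT = frozenset({"adrenal gland", "ovary", "prostate", "testis", "thymus"})


@dataclass
class PSMRecord:
    spectrum_id: str
    sample_id: str
    peptide: str
    engine: str
    score: float
    pep: float | None = None
    qvalue: float | None = None
    precursor_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.engine not in (ENGINE1, ENGINE2):
            raise ValueError(f"unknown engine {self.engine!r}")
        for name, v in (("pep", self.pep), ("qvalue", self.qvalue)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        if self.score < 0 or self.precursor_intensity < 0:
            raise ValueError("score and intensity must be non-negative")


@dataclass
class MergedPeptide:
    peptide: str
    samples: set[str] = field(default_factory=set)
    max_intensity_per_sample: dict[str, float] = field(default_factory=dict)
    engines_supporting: set[str] = field(default_factory=set)
    hla_assignments: list[tuple[str, float, str]] = field(default_factory=list)
    normal_flags: dict[str, bool] = field(default_factory=dict)
    status: str = "retained"
    reason: str | None = None


@dataclass
class BindingPrediction:
    peptide: str
    allele: str
    percentile_rank: float


def fdr_decision(psm: PSMRecord) -> tuple[bool, str | None]:
    """Peptide-level FDR and length gate for a single PSM.

    Engine 1: PEP < 0.05 and rescored q-value < 0.05, 8-11-mers.
    Engine 2: q-value < 0.01, 8-15-mers.
    """
    n = len(psm.peptide)
    if psm.engine == ENGINE1:
        if psm.pep is None or psm.qvalue is None:
            return False, "missing_statistic"
        if not (psm.pep < 0.05 and psm.qvalue < 0.05):
            return False, "fdr"
        if not 8 <= n <= 11:
            return False, "length"
    else:
        if psm.qvalue is None:
            return False, "missing_statistic"
        if not psm.qvalue < 0.01:
            return False, "fdr"
        if not 8 <= n <= 15:
            return False, "length"
    return True, None


def apply_fdr(psms: Iterable[PSMRecord]) -> list[PSMRecord]:
    return [p for p in psms if fdr_decision(p)[0]]


@dataclass
class ConflictDecision:
    spectrum_id: str
    outcome: str  # keep_engine1 | keep_engine2 | agree | excluded
    reason: str | None
    kept_peptide: str | None


def resolve_conflicts(
    spectrum_groups: Mapping[str, list[PSMRecord]]
) -> dict[str, ConflictDecision]:
    """Resolve spectra matched to different peptides by the two engines.

    With Andromeda A and Tesorai T on the same spectrum:
    A>70 and T<5 keeps the engine-1 peptide; A<70 and T>5 keeps engine 2;
    both high is ambiguous and both low is low-confidence — excluded either
    way. Agreement on the peptide bypasses the table; more than two
    candidate peptides is excluded as multiway-ambiguous.
    """
    decisions = {}
    for sid, group in spectrum_groups.items():
        peptides = {p.peptide for p in group}
        if len(peptides) == 1:
            decisions[sid] = ConflictDecision(sid, "agree", None, group[0].peptide)
            continue
        if len(peptides) > 2:
            log.warning("spectrum %s matched %d peptides", sid, len(peptides))
            decisions[sid] = ConflictDecision(sid, "excluded", "multiway_ambiguous", None)
            continue
        e1 = [p for p in group if p.engine == ENGINE1]
        e2 = [p for p in group if p.engine == ENGINE2]
        if not e1 or not e2:
            decisions[sid] = ConflictDecision(sid, "excluded", "multiway_ambiguous", None)
            continue
        a_high = max(p.score for p in e1) > ANDROMEDA_HIGH
        t_high = max(p.score for p in e2) > TESORAI_HIGH
        if a_high and not t_high:
            decisions[sid] = ConflictDecision(sid, "keep_engine1", None, e1[0].peptide)
        elif t_high and not a_high:
            decisions[sid] = ConflictDecision(sid, "keep_engine2", None, e2[0].peptide)
        elif a_high and t_high:
            decisions[sid] = ConflictDecision(sid, "excluded", "ambiguous", None)
        else:
            decisions[sid] = ConflictDecision(sid, "excluded", "low_confidence", None)
    return decisions


def merge_engines(psms: Iterable[PSMRecord]) -> tuple[list[PSMRecord], dict[str, ConflictDecision]]:
    """FDR-filter each engine, then resolve per-spectrum conflicts; returns
    the reconciled PSM list (union of engines, one peptide per spectrum)
    and the conflict decisions."""
    retained = apply_fdr(psms)
    by_spectrum: dict[str, list[PSMRecord]] = defaultdict(list)
    for p in retained:
        by_spectrum[(p.sample_id, p.spectrum_id)].append(p)
    final = []
    decisions = {}
    for (sample, sid), group in sorted(by_spectrum.items()):
        dec_map = resolve_conflicts({sid: group})
        dec = dec_map[sid]
        decisions[(sample, sid)] = dec
        if dec.outcome == "agree":
            final.append(group[0])
        elif dec.outcome == "keep_engine1":
            final.append(next(p for p in group if p.engine == ENGINE1))
        elif dec.outcome == "keep_engine2":
            final.append(next(p for p in group if p.engine == ENGINE2))
    return final, decisions


def merge_peptides(psms: Iterable[PSMRecord]) -> dict[str, MergedPeptide]:
    """Collapse reconciled PSMs to peptides; per-sample abundance is the
    maximum precursor intensity over that peptide's PSMs in the sample."""
    merged: dict[str, MergedPeptide] = {}
    for p in psms:
        m = merged.setdefault(p.peptide, MergedPeptide(p.peptide))
        m.samples.add(p.sample_id)
        m.engines_supporting.add(p.engine)
        if p.precursor_intensity > 0:
            cur = m.max_intensity_per_sample.get(p.sample_id, 0.0)
            m.max_intensity_per_sample[p.sample_id] = max(cur, p.precursor_intensity)
    return merged


def hla_binding_filter(
    peptides: Iterable[MergedPeptide],
    alleles_of_sample: list[str],
    predictor: Callable[[str, str], float],
    weak_cutoff: float = 2.0,
    strong_cutoff: float = 0.5,
) -> list[MergedPeptide]:
    """Keep peptides whose best percentile rank over the sample's alleles is
    below the weak-binder cutoff; assignments below the strong cutoff are
    labelled strong. Predictor failures exclude the peptide as unscored."""
    out = []
    n_unscored = 0
    for m in peptides:
        try:
            ranks = [(a, float(predictor(m.peptide, a))) for a in alleles_of_sample]
        except Exception:
            ranks = None
        if not ranks:
            m.status, m.reason = "excluded", "unscored"
            n_unscored += 1
            out.append(m)
            continue
        m.hla_assignments = [
            (a, r, "strong" if r < strong_cutoff else "weak")
            for a, r in sorted(ranks, key=lambda x: x[1])
            if r < weak_cutoff
        ]
        if not m.hla_assignments:
            m.status, m.reason = "excluded", "non_binder"
        out.append(m)
    if n_unscored:
        log.warning("%d peptides excluded as unscored", n_unscored)
    return out


def normal_screen(
    peptide: MergedPeptide,
    normal_hits: set[str],
    essential_exempt: frozenset[str] = ESSENTIAL_EXEMPT,
) -> MergedPeptide:
    """Safety screen against the normal immunopeptidome: a peptide detected
    in any essential tissue (anything outside the exempt immune-privileged
    or dispensable set) is excluded; detection only in exempt tissues is
    annotated but retained."""
    peptide.normal_flags = {t: True for t in sorted(normal_hits)}
    essential = normal_hits - essential_exempt
    if essential:
        peptide.status, peptide.reason = "excluded", "normal_tissue"
    elif normal_hits:
        peptide.reason = "exempt_tissue_only"
    return peptide


def quantile_normalize(
    sample_psms: Iterable[PSMRecord], quantile: float = 75.0
) -> dict[str, float]:
    """Upper-quartile log2 normalization of one run's peptide abundances.

    Abundance per peptide is the maximum precursor intensity over its PSMs;
    the run's 75th-percentile abundance (linear-interpolation convention) is
    the base and each abundance maps to log2(abundance / base).
    """
    abundances: dict[str, float] = {}
    for p in sample_psms:
        if p.precursor_intensity > 0:
            abundances[p.peptide] = max(
                abundances.get(p.peptide, 0.0), p.precursor_intensity
            )
    if not abundances:
        raise ValueError("no peptide with positive intensity in this run")
    base = float(np.percentile(list(abundances.values()), quantile))
    return {pep: float(np.log2(v / base)) for pep, v in abundances.items()}
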
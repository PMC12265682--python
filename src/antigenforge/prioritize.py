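"""Seven-criterion target scoring, cohort coverage, single-cell homogeneity
and the personalized-vaccine triage step with spectral similarity.

The seven criteria per candidate target: (1) peptide abundance, (2)
recurrence across samples, (3) absence in normal tissue RNA and
immunopeptidome, (4) HLA binding rank, (5) dependency of the parent gene,
(6) homogeneity of expression across malignant cells, (7) confidence of the
MS identification. No composite score is formed; criteria are reported and
missing ones stay absent, never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class TargetScoreCard:
    target_id: str
    abundance: float | None = None
    recurrence: float | None = None
    normal_rna_ok: bool | None = None
    normal_ip_ok: bool | None = None
    binding_rank: float | None = None
    dependency: float | None = None
    homogeneity: float | None = None
    id_confidence: str | None = None  # high | medium

    def __post_init__(self) -> None:
        for name in ("recurrence", "homogeneity"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]")


@dataclass
class PatientRecord:
    patient_id: str
    expressed_tumor_genes: set[str]
    hla_alleles: set[str]


@dataclass
class SpectrumPeaks:
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")


def score_target(
    target_id: str,
    abundance: float | None,
    sample_hits: set[str],
    n_cohort_samples: int,
    psm_scores: Sequence[tuple[float | None, float | None]],
    normal_rna_ok: bool | None = None,
    normal_ip_ok: bool | None = None,
    binding_rank: float | None = None,
    dependency: float | None = None,
    homogeneity: float | None = None,
) -> TargetScoreCard:
    """Build the scorecard; identification confidence is high when any
    supporting PSM clears either engine's high-confidence score cutoff
    (Andromeda > 70 or Tesorai > 5)."""
    if not psm_scores:
        raise ValueError(f"target {target_id}: no supporting peptide evidence")
    high = any(
        (a is not None and a > 70) or (t is not None and t > 5) for a, t in psm_scores
    )
    return TargetScoreCard(
        target_id=target_id,
        abundance=abundance,
        recurrence=len(sample_hits) / n_cohort_samples,
        normal_rna_ok=normal_rna_ok,
        normal_ip_ok=normal_ip_ok,
        binding_rank=binding_rank,
        dependency=dependency,
        homogeneity=homogeneity,
        id_confidence="high" if high else "medium",
    )


def homogeneity_percentile(mean_expr_by_gene: Mapping[str, float]) -> dict[str, float]:
    """Single-cell coverage: mean expression over malignant cells is ranked
    ascending across detected genes and reported as rank/n percentiles; ties
    share the average rank."""
    genes = sorted(mean_expr_by_gene)
    if len(genes) < 2:
        raise ValueError("need at least two detected genes")
    values = np.array([mean_expr_by_gene[g] for g in genes], dtype=float)
    ranks = stats.rankdata(values, method="average")
    return {g: float(r / len(genes)) for g, r in zip(genes, ranks)}


def patient_coverage(
    cohort: Sequence[PatientRecord],
    targets: Sequence[tuple[str, str | None]],
) -> float:
    """Fraction of patients with at least one actionable target: the target
    gene is expressed in the patient's tumor and, if the target is
    HLA-restricted, the patient carries the allele."""
    if not cohort:
        raise ValueError("empty cohort")
    if not targets:
        warnings.warn("no targets supplied; coverage is 0", stacklevel=2)
        return 0.0
    covered = 0
    for patient in cohort:
        for gene, allele in targets:
            if gene in patient.expressed_tumor_genes and (
                allele is None or allele in patient.hla_alleles
            ):
                covered += 1
                break
    return covered / len(cohort)


def _match_peaks(
    observed: SpectrumPeaks, predicted: SpectrumPeaks, tol_da: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy closest-first one-to-one matching within tol_da; unmatched
    peaks contribute zero to the other vector."""
    pairs = []
    for i, (mo, _) in enumerate(observed.peaks):
        for k, (mp, _) in enumerate(predicted.peaks):
            d = abs(mo - mp)
            if d <= tol_da:
                pairs.append((d, i, k))
    pairs.sort()
    used_o: set[int] = set()
    used_p: set[int] = set()
    matches = {}
    for _, i, k in pairs:
        if i in used_o or k in used_p:
            continue
        matches[i] = k
        used_o.add(i)
        used_p.add(k)
    xs, ys = [], []
    for i, (_, inten) in enumerate(observed.peaks):
        xs.append(inten)
        ys.append(predicted.peaks[matches[i]][1] if i in matches else 0.0)
    for k, (_, inten) in enumerate(predicted.peaks):
        if k not in used_p:
            xs.append(0.0)
            ys.append(inten)
    return np.array(xs), np.array(ys)


def spectral_similarity(
    observed: SpectrumPeaks, predicted: SpectrumPeaks, tol_da: float = 0.02
) -> tuple[float, float]:
    """Cosine similarity and Pearson correlation of intensity vectors
    aligned by greedy one-to-one peak matching within ``tol_da``."""
    if not observed.peaks or not predicted.peaks:
        raise ValueError("empty spectrum")
    x, y = _match_peaks(observed, predicted, tol_da)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    cosine = float(x @ y / (nx * ny)) if nx > 0 and ny > 0 else 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(x, y)[0, 1])
    return cosine, pearson


@dataclass
class TriageRow:
    variant_id: str
    peptides: list[str]
    evidenced: bool
    binding_rank: float | None
    immunogenicity: float | None
    cosine: float | None = None
    pearson: float | None = None


def _triage_key(row: TriageRow) -> tuple:
    # binding tier dominates: an evidenced peptide failing the weak-binder
    # cutoff sits below every rank-passing entry, then evidence, then
    # predicted immunogenicity
    binds = row.binding_rank is not None and row.binding_rank < 2.0
    immuno = row.immunogenicity if row.immunogenicity is not None else float("-inf")
    return (not binds, not row.evidenced, -immuno, row.variant_id)


def triage_neoantigens(
    expressed_variants: Mapping[str, list[str]],
    evidence_table: set[str],
    alleles: Sequence[str],
    predictor: Callable[[str, str], float],
    immunogenicity: Callable[[str], float] | None = None,
    spectra: Mapping[str, tuple[SpectrumPeaks, SpectrumPeaks]] | None = None,
) -> list[TriageRow]:
    """Personalized-vaccine triage: variants whose predicted peptides appear
    in the cohort immunopeptidome are flagged evidenced; rows are ranked by
    (evidenced, binding rank < 2, immunogenicity descending) with a
    deterministic final tie-break on the variant identifier.

    ``expressed_variants`` maps variant id -> its candidate peptides (from
    the mutation-peptide generator); ``evidence_table`` is the set of
    peptide sequences observed in the reference immunopeptidome cohort.
    """
    if not evidence_table:
        warnings.warn("empty evidence table; ranking by prediction only", stacklevel=2)
    rows = []
    for vid in sorted(expressed_variants):
        peptides = expressed_variants[vid]
        evidenced = any(p in evidence_table for p in peptides)
        ranks = [predictor(p, a) for p in peptides for a in alleles]
        best_rank = min(ranks) if ranks else None
        immuno = (
            max(immunogenicity(p) for p in peptides)
            if immunogenicity and peptides
            else None
        )
        row = TriageRow(vid, list(peptides), evidenced, best_rank, immuno)
        if spectra and vid in spectra:
            row.cosine, row.pearson = spectral_similarity(*spectra[vid])
        rows.append(row)
    return sorted(rows, key=_triage_key)
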
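"""Per-locus candidate selection, genotyping, and call filtering.

At most one SNV and one indel allele is reported per genomic position: when
several candidates compete, the one with the greatest read support wins,
with SNV ties broken by the higher model score and any remaining ties by
allele order. Indels are genotyped by variant-allele-fraction cutoffs; SNVs
by the maximum-likelihood diploid genotype under a binomial allele model
with a fixed per-base error rate. Calls scoring at or below the report
cutoff (default 0.25) are not reported at all; reported calls may still
carry quality filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple, Union

from .discovery import DEL, INS, SNV, CandidateVariant
from .features import IndelFeatures, SnvFeatures

HOM_REF = "0/0"
HET = "0/1"
HOM_ALT = "1/1"


@dataclass
class CallThresholds:
    """Reporting, genotyping, and filtering cutoffs (all user-adjustable)."""

    report_cutoff: float = 0.25
    min_alt_reads: int = 2
    indel_het_min_vaf: float = 0.2
    indel_hom_min_vaf: float = 0.8
    snv_error_rate: float = 0.01
    min_site_mapq_mean: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.report_cutoff < 1.0:
            raise ValueError("report_cutoff must be in (0, 1)")
        if not 0.0 < self.indel_het_min_vaf < self.indel_hom_min_vaf <= 1.0:
            raise ValueError("require 0 < het VAF cutoff < hom VAF cutoff <= 1")
        if not 0.0 < self.snv_error_rate < 0.5:
            raise ValueError("snv_error_rate must be in (0, 0.5)")


@dataclass
class VariantCall:
    """A scored, genotyped, filtered variant ready for VCF serialization."""

    candidate: CandidateVariant
    features: Union[SnvFeatures, IndelFeatures]
    score: float
    genotype: str
    genotype_likelihoods: Optional[Tuple[float, float, float]]  # SNVs only
    filters: Set[str] = field(default_factory=set)
    site_mean_mapq: float = 0.0

    @property
    def is_pass(self) -> bool:
        return not self.filters

    @property
    def gq(self) -> int:
        """Phred-like confidence proxy derived from the model score."""
        return score_to_gq(self.score)


def score_to_gq(score: float) -> int:
    """round(-10*log10(1 - score)), capped at 100."""
    err = max(1.0 - score, 1e-10)
    return min(100, int(round(-10.0 * math.log10(err))))


def select_site_variant(cands: Sequence[CandidateVariant]) -> CandidateVariant:
    """Pick the single reportable candidate among same-locus, same-type rivals.

    Greatest supporting-read count wins; ties go to the candidate whose
    ``score`` attribute is highest (set by the caller before selection);
    remaining ties break on (ref, alt) lexicographic order so the choice is
    deterministic under input permutation.
    """
    if not cands:
        raise ValueError("no candidates to select from")

    def sort_key(c: CandidateVariant):
        score = getattr(c, "score", 0.0)
        return (-c.alt_count, -score, c.ref_allele, c.alt_allele)

    return min(cands, key=sort_key)


def genotype_indel(c: CandidateVariant, t: CallThresholds) -> str:
    """VAF-cutoff diploid genotype for an insertion or deletion."""
    if c.vtype not in (INS, DEL):
        raise ValueError(f"expected indel, got {c.vtype}")
    vaf = c.alt_count / c.site_depth
    if vaf >= t.indel_hom_min_vaf:
        return HOM_ALT
    if vaf >= t.indel_het_min_vaf:
        return HET
    return HOM_REF


def _binom_logpmf(k: int, n: int, p: float) -> float:
    coef = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    return coef + k * math.log(p) + (n - k) * math.log1p(-p)


def genotype_snv(
    c: CandidateVariant, t: CallThresholds
) -> Tuple[str, Tuple[float, float, float]]:
    """Maximum-likelihood diploid genotype for an SNV.

    The alt-read count is modeled as binomial in the site depth with
    success probability epsilon (hom-ref), 0.5 (het), or 1 - epsilon
    (hom-alt), epsilon being the per-base error rate. Returns the argmax
    genotype (ties resolve toward the fewer-alt genotype) and the
    log-likelihood triple in (hom-ref, het, hom-alt) order.
    """
    if c.vtype != SNV:
        raise ValueError(f"expected SNV, got {c.vtype}")
    k, n = c.alt_count, c.site_depth
    eps = t.snv_error_rate
    lls = (
        _binom_logpmf(k, n, eps),
        _binom_logpmf(k, n, 0.5),
        _binom_logpmf(k, n, 1.0 - eps),
    )
    best = max(range(3), key=lambda i: (lls[i], -i))
    return (HOM_REF, HET, HOM_ALT)[best], lls


def apply_filters(call: VariantCall, t: CallThresholds) -> Set[str]:
    """Assign quality-filter tags to a reported call (empty set means PASS).

    ``low_cov``: too few supporting reads; ``low_mapq``: mean mapping
    quality of covering reads below threshold; ``no_var``: hom-ref
    genotype; ``low_qual``: score at or below the report cutoff (reported
    calls normally clear the cutoff before reaching this stage).
    """
    filters: Set[str] = set()
    if call.score <= t.report_cutoff:
        filters.add("low_qual")
    if call.candidate.alt_count < t.min_alt_reads:
        filters.add("low_cov")
    if call.site_mean_mapq < t.min_site_mapq_mean:
        filters.add("low_mapq")
    if call.genotype == HOM_REF:
        filters.add("no_var")
    call.filters = filters
    return filters
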
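"""Feature vectors for candidate scoring.

SNV candidates are described by five features: the supporting-read fraction
(ratio_score), mean base quality at the site across supporting reads
(base_qual), mean base quality within 5 bases of the site (mean_avnqs), the
mean relative in-read position of the variant (rel_pos), and a
transition/transversion indicator (titv). Indel candidates use the
supporting-read fraction, a both-strands indicator (strand_dir), the
flanking-window quality (mean_avnqs), the Shannon entropy of the inserted
or deleted sequence (seq_entropy), and the mean per-read variation rate
(mean_var_rate). All features are computed on raw scales — fractions in
[0, 1], qualities in phred units — matching the default model coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

from .discovery import DEL, INS, SNV, CandidateVariant

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class SnvFeatures:
    ratio_score: float
    base_qual: float
    mean_avnqs: float
    rel_pos: float
    titv: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "ratio_score": self.ratio_score,
            "base_qual": self.base_qual,
            "mean_avnqs": self.mean_avnqs,
            "rel_pos": self.rel_pos,
            "titv": float(self.titv),
        }


@dataclass
class IndelFeatures:
    ratio_score: float
    strand_dir: int
    mean_avnqs: float
    seq_entropy: float
    mean_var_rate: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "ratio_score": self.ratio_score,
            "strand_dir": float(self.strand_dir),
            "mean_avnqs": self.mean_avnqs,
            "seq_entropy": self.seq_entropy,
            "mean_var_rate": self.mean_var_rate,
        }


def is_transition(ref_base: str, alt_base: str) -> int:
    """1 for a transition (A<->G, C<->T), 0 for a transversion."""
    if ref_base == alt_base:
        raise ValueError("identical bases do not form a substitution")
    if {ref_base, alt_base} - (_PURINES | _PYRIMIDINES):
        raise ValueError(f"non-ACGT base in ({ref_base}, {alt_base})")
    both_pur = ref_base in _PURINES and alt_base in _PURINES
    both_pyr = ref_base in _PYRIMIDINES and alt_base in _PYRIMIDINES
    return 1 if (both_pur or both_pyr) else 0


def sequence_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the mononucleotide composition of `seq`."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    h = 0.0
    for base in "ACGT":
        c = seq.count(base)
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h


def _mean(vals) -> float:
    vals = list(vals)
    return sum(vals) / len(vals)


def snv_features(c: CandidateVariant) -> SnvFeatures:
    """Compute the SNV model features for one candidate.

    Requires at least one supporting read and positive site depth.
    """
    if c.vtype != SNV:
        raise ValueError(f"expected SNV candidate, got {c.vtype}")
    if c.alt_count < 1 or c.site_depth < 1:
        raise ValueError("SNV candidate without support or depth")
    return SnvFeatures(
        ratio_score=c.alt_count / c.site_depth,
        base_qual=_mean(s.site_qual for s in c.supporting),
        mean_avnqs=_mean(s.window_qual for s in c.supporting),
        rel_pos=_mean(s.rel_pos for s in c.supporting),
        titv=is_transition(c.ref_allele, c.alt_allele),
    )


def indel_features(c: CandidateVariant) -> IndelFeatures:
    """Compute the indel model features for one candidate.

    mean_var_rate averages, across supporting reads, the read's total count
    of observed variations divided by its reference-aligned length.
    """
    if c.vtype not in (INS, DEL):
        raise ValueError(f"expected indel candidate, got {c.vtype}")
    if c.alt_count < 1 or c.site_depth < 1:
        raise ValueError("indel candidate without support or depth")
    fwd, rev = c.strands_seen
    return IndelFeatures(
        ratio_score=c.alt_count / c.site_depth,
        strand_dir=1 if (fwd and rev) else 0,
        mean_avnqs=_mean(s.window_qual for s in c.supporting),
        seq_entropy=sequence_entropy(c.alt_allele if c.vtype == INS else c.ref_allele),
        mean_var_rate=_mean(
            s.var_count / s.aligned_length for s in c.supporting if s.aligned_length > 0
        ),
    )


def features_for(c: CandidateVariant):
    """Dispatch to the SNV or indel feature computation by candidate type."""
    return snv_features(c) if c.vtype == SNV else indel_features(c)
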
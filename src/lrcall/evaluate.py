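"""Truth-concordance evaluation on synthetic data.

A lightweight site-level concordance checker: called and truth variants
are reduced to normalized (contig, pos, ref, alt) keys — using the same
left-alignment as candidate discovery — and compared within evaluation
regions. This supports recall/precision measurement on simulations; it is
not a haplotype-aware comparison engine and makes no attempt to match
complex representations across call sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import pysam

from .alignment_io import load_reference
from .discovery import normalize_variant

SiteKey = Tuple[str, int, str, str]


@dataclass
class Concordance:
    n_truth: int
    n_called: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_called if self.n_called else float("nan")


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1


def vcf_site_keys(
    vcf_path: str,
    reference_path: str,
    pass_only: bool = False,
    vclass: Optional[str] = None,
    regions: Optional[Sequence[Tuple[str, int, int]]] = None,
    indel_size_range: Optional[Tuple[int, int]] = None,
) -> Set[SiteKey]:
    """Normalized site keys from a VCF, optionally restricted.

    ``vclass`` is "snv" or "indel"; ``regions`` are 0-based half-open;
    ``indel_size_range`` restricts indels by allele-length difference.
    """
    refs: Dict[str, str] = {}
    keys: Set[SiteKey] = set()
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            if pass_only and "PASS" not in rec.filter:
                continue
            if not rec.alts:
                continue
            for alt in rec.alts:
                if alt.startswith("<"):
                    continue
                snv = _is_snv(rec.ref, alt)
                if vclass == "snv" and not snv:
                    continue
                if vclass == "indel":
                    if snv:
                        continue
                    size = abs(len(rec.ref) - len(alt))
                    if indel_size_range and not (
                        indel_size_range[0] <= size <= indel_size_range[1]
                    ):
                        continue
                ref_seq = refs.setdefault(
                    rec.contig, load_reference(reference_path, rec.contig)
                )
                pos, r, a = normalize_variant(rec.start, rec.ref, alt, ref_seq)
                if regions is not None and not any(
                    c == rec.contig and s <= pos < e for c, s, e in regions
                ):
                    continue
                keys.add((rec.contig, pos, r, a))
    return keys


def concordance(
    calls_vcf: str,
    truth_vcf: str,
    reference_path: str,
    vclass: Optional[str] = None,
    pass_only: bool = True,
    regions: Optional[Sequence[Tuple[str, int, int]]] = None,
    indel_size_range: Optional[Tuple[int, int]] = None,
) -> Concordance:
    """Site-level recall/precision of `calls_vcf` against `truth_vcf`."""
    called = vcf_site_keys(
        calls_vcf, reference_path, pass_only, vclass, regions, indel_size_range
    )
    truth = vcf_site_keys(
        truth_vcf, reference_path, False, vclass, regions, indel_size_range
    )
    return Concordance(len(truth), len(called), len(called & truth))
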
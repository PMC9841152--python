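"""End-to-end single-sample calling pipeline.

Orchestrates the deterministic call path: stream filtered reads, extract
and normalize per-read variations, aggregate candidates with depth
bookkeeping, compute features and model scores, select one SNV and one
indel allele per locus, genotype, filter, and hand sorted calls to the VCF
writer. Processing is per contig (or per BED interval), fully in memory —
the intended scale is a single sample region or small genome at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alignment_io import ReadFilterConfig, load_reference, reference_contigs, stream_reads
from .discovery import (
    DEL,
    INS,
    SNV,
    CandidateVariant,
    DepthProfile,
    ReadVariant,
    aggregate_candidates,
    extract_read_variants,
    left_align_parsimonious,
)
from .features import features_for, is_transition
from .genotype import (
    CallThresholds,
    VariantCall,
    apply_filters,
    genotype_indel,
    genotype_snv,
    select_site_variant,
)
from .model import LogisticModel, load_model_config, logistic_score
from .vcf_writer import write_vcf

logger = logging.getLogger(__name__)


@dataclass
class CallSummary:
    """Counts reported at the end of a calling run."""

    n_candidates: int = 0
    n_reported: int = 0
    n_pass: int = 0
    n_pass_snv: int = 0
    n_pass_indel: int = 0
    transitions: int = 0
    transversions: int = 0

    @property
    def titv(self) -> Optional[float]:
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def read_bed_regions(path: str) -> List[Tuple[str, int, int]]:
    """Parse a BED file into (contig, start, end) 0-based half-open tuples."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


def discover_region(
    alignment_path: str,
    ref: str,
    region: Tuple[str, int, int],
    read_cfg: Optional[ReadFilterConfig] = None,
    reference_path: Optional[str] = None,
) -> Tuple[List[CandidateVariant], DepthProfile]:
    """Candidate discovery over one region: all aggregated candidates, no cutoffs."""
    contig, start, end = region
    depth = DepthProfile(contig, start, end)
    variants: List[ReadVariant] = []
    for read in stream_reads(
        alignment_path, (contig, start, end), read_cfg, reference_path=reference_path
    ):
        depth.add_read(read)
        for v in extract_read_variants(read, ref):
            v = left_align_parsimonious(v, ref)
            # boundary-overlapping reads may carry variants outside the region
            if start <= v.pos < end:
                variants.append(v)
    return aggregate_candidates(variants, depth), depth


def score_candidates(
    cands: Sequence[CandidateVariant],
    snv_model: LogisticModel,
    indel_model: LogisticModel,
):
    """Attach features and model score to every candidate (in place)."""
    for c in cands:
        f = features_for(c)
        m = snv_model if c.vtype == SNV else indel_model
        c.features = f  # type: ignore[attr-defined]
        c.score = logistic_score(m, f.as_dict())  # type: ignore[attr-defined]


def call_region(
    cands: Sequence[CandidateVariant],
    depth: DepthProfile,
    thresholds: CallThresholds,
    summary: Optional[CallSummary] = None,
) -> List[VariantCall]:
    """Select, genotype, and filter scored candidates into reportable calls."""
    summary = summary if summary is not None else CallSummary()
    by_locus: Dict[Tuple[int, str], List[CandidateVariant]] = {}
    for c in cands:
        kind = SNV if c.vtype == SNV else "INDEL"
        by_locus.setdefault((c.pos, kind), []).append(c)

    calls: List[VariantCall] = []
    for (pos, kind), rivals in sorted(by_locus.items(), key=lambda kv: kv[0][0]):
        c = select_site_variant(rivals)
        score = c.score  # type: ignore[attr-defined]
        if score <= thresholds.report_cutoff:
            continue
        if c.vtype == SNV:
            gt, lls = genotype_snv(c, thresholds)
        else:
            gt, lls = genotype_indel(c, thresholds), None
        call = VariantCall(
            candidate=c,
            features=c.features,  # type: ignore[attr-defined]
            score=score,
            genotype=gt,
            genotype_likelihoods=lls,
            site_mean_mapq=depth.mean_mapq_at(c.pos),
        )
        apply_filters(call, thresholds)
        calls.append(call)
        summary.n_reported += 1
        if call.is_pass:
            summary.n_pass += 1
            if c.vtype == SNV:
                summary.n_pass_snv += 1
                if is_transition(c.ref_allele, c.alt_allele):
                    summary.transitions += 1
                else:
                    summary.transversions += 1
            else:
                summary.n_pass_indel += 1
    return calls


def run_call(
    alignment_path: str,
    reference_path: str,
    out_prefix: str,
    regions_bed: Optional[str] = None,
    region: Optional[Tuple[str, Optional[int], Optional[int]]] = None,
    model_config: Optional[str] = None,
    thresholds: Optional[CallThresholds] = None,
    read_cfg: Optional[ReadFilterConfig] = None,
    sample: str = "SAMPLE",
    gvcf: bool = False,
    bgzf: bool = False,
) -> Tuple[str, str, CallSummary]:
    """Run the full calling pipeline; returns (snv_vcf, indel_vcf, summary).

    The pipeline is deterministic: no step consumes randomness, so repeated
    runs on the same inputs produce byte-identical VCF bodies.
    """
    thresholds = thresholds or CallThresholds()
    snv_model, indel_model = load_model_config(model_config)

    contigs = dict(reference_contigs(reference_path))
    if regions_bed is not None:
        regions = read_bed_regions(regions_bed)
    elif region is not None:
        contig, start, end = region
        if contig not in contigs:
            raise ValueError(f"region contig {contig!r} not in reference")
        regions = [(contig, start or 0, end if end is not None else contigs[contig])]
    else:
        regions = [(name, 0, length) for name, length in contigs.items()]

    summary = CallSummary()
    all_calls: List[VariantCall] = []
    gvcf_regions = []
    for contig, start, end in regions:
        ref = load_reference(reference_path, contig)
        cands, depth = discover_region(
            alignment_path, ref, (contig, start, end), read_cfg, reference_path
        )
        summary.n_candidates += len(cands)
        score_candidates(cands, snv_model, indel_model)
        all_calls.extend(call_region(cands, depth, thresholds, summary))
        gvcf_regions.append(((contig, start, end), depth))

    snv_path, indel_path = write_vcf(
        all_calls,
        reference_path,
        out_prefix,
        sample=sample,
        gvcf=gvcf,
        bgzf=bgzf,
        gvcf_regions=gvcf_regions if gvcf else None,
    )
    logger.info(
        "calling done: %d candidates, %d reported, %d PASS (%d SNV / %d indel)",
        summary.n_candidates,
        summary.n_reported,
        summary.n_pass,
        summary.n_pass_snv,
        summary.n_pass_indel,
    )
    return snv_path, indel_path, summary
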
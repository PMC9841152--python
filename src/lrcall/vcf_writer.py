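"""VCF 4.2 serialization: SNVs and indels to separate files, optional gVCF.

Calls are written through pysam/htslib as standards-compliant VCF 4.2,
optionally BGZF-compressed. In gVCF mode, non-variant blocks carrying
coverage information are interleaved into the SNV-stream file so that every
position of the processed region is accounted for exactly once, either by a
variant record (one position for an SNV or insertion anchor, the full
reference span for a deletion) or by one block. Blocks break wherever the
depth class changes (bands 0, 1-4, 5-9, 10-19, 20-49, >=50) and at variant
records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .discovery import DEL, INS, SNV, DepthProfile
from .genotype import HET, HOM_ALT, HOM_REF, VariantCall

DEPTH_BANDS: List[Tuple[int, Optional[int]]] = [
    (0, 0),
    (1, 4),
    (5, 9),
    (10, 19),
    (20, 49),
    (50, None),
]

FILTER_DESCRIPTIONS = {
    "low_qual": "Model score at or below the reporting cutoff",
    "low_cov": "Too few reads supporting the variant allele",
    "low_mapq": "Mean mapping quality of covering reads below threshold",
    "no_var": "Most likely genotype is homozygous reference",
}


@dataclass
class GvcfBlock:
    """A non-variant coverage block (1-based inclusive span)."""

    contig: str
    start: int
    end: int
    min_dp: int
    mean_dp: float
    depth_class: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def depth_class(d: int) -> str:
    """Banding label for a depth value."""
    for lo, hi in DEPTH_BANDS:
        if hi is None:
            if d >= lo:
                return f">={lo}"
        elif lo <= d <= hi:
            return f"{lo}" if lo == hi else f"{lo}-{hi}"
    raise ValueError(f"negative depth {d}")


def _band_index(d: int) -> int:
    for i, (lo, hi) in enumerate(DEPTH_BANDS):
        if hi is None:
            if d >= lo:
                return i
        elif lo <= d <= hi:
            return i
    raise ValueError(f"negative depth {d}")


def call_covered_span(call: VariantCall) -> Tuple[int, int]:
    """0-based half-open reference span accounted for by a call's VCF record."""
    c = call.candidate
    if c.vtype == SNV:
        return c.pos, c.pos + 1
    if c.vtype == INS:
        anchor = c.pos - 1 if c.pos > 0 else 0
        return anchor, anchor + 1
    anchor = c.pos - 1 if c.pos > 0 else 0
    return anchor, anchor + 1 + len(c.ref_allele)


def emit_gvcf_blocks(
    depth: DepthProfile,
    calls: Sequence[VariantCall],
    region: Tuple[int, int],
) -> List[GvcfBlock]:
    """Partition the non-variant part of `region` into coverage blocks.

    Every position in ``[region[0], region[1])`` not covered by a call's
    record span lands in exactly one block; blocks are maximal runs of
    uncovered positions with a constant depth class.
    """
    start, end = region
    covered = set()
    for call in calls:
        s, e = call_covered_span(call)
        covered.update(range(max(s, start), min(e, end)))

    blocks: List[GvcfBlock] = []
    run_start = None
    run_band = None
    for pos in range(start, end):
        if pos in covered:
            band = None
        else:
            band = _band_index(depth.depth_at(pos))
        if band != run_band or band is None:
            if run_start is not None and run_band is not None:
                blocks.append(_make_block(depth, run_start, pos))
            run_start = pos if band is not None else None
            run_band = band
    if run_start is not None and run_band is not None:
        blocks.append(_make_block(depth, run_start, end))
    return blocks


def _make_block(depth: DepthProfile, start: int, end: int) -> GvcfBlock:
    min_dp = depth.min_depth(start, end)
    return GvcfBlock(
        contig=depth.contig,
        start=start + 1,
        end=end,
        min_dp=min_dp,
        mean_dp=depth.mean_depth(start, end),
        depth_class=depth_class(min_dp),
    )


def _build_header(
    contigs: Sequence[Tuple[str, int]], sample: str, vtype: str, gvcf: bool
) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs:
        h.contigs.add(name, length=length)
    for tag, desc in FILTER_DESCRIPTIONS.items():
        h.filters.add(tag, None, None, desc)
    h.info.add("SCORE", 1, "Float", "Logistic regression model probability")
    h.info.add("MMQ", 1, "Float", "Mean mapping quality of reads covering the site")
    h.info.add("RS", 1, "Float", "Supporting-read ratio feature")
    h.info.add("AVNQS", 1, "Float", "Mean neighborhood base quality feature")
    if vtype == "snv":
        h.info.add("BQ", 1, "Float", "Mean base quality at site across supporting reads")
        h.info.add("RELPOS", 1, "Float", "Mean relative in-read variant position")
        h.info.add("TITV", 1, "Integer", "Transition (1) or transversion (0)")
    else:
        h.info.add("SD", 1, "Integer", "Supported by both strands (1) or one (0)")
        h.info.add("ENT", 1, "Float", "Indel sequence entropy (bits)")
        h.info.add("MVR", 1, "Float", "Mean per-read variation rate")
    if gvcf:
        h.info.add("END", 1, "Integer", "End position of non-variant block (inclusive)")
        h.info.add("MIN_DP", 1, "Integer", "Minimum depth within non-variant block")
        h.info.add("DPB", 1, "String", "Depth class of non-variant block")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("DP", 1, "Integer", "Filtered read depth at site")
    h.formats.add("AD", "R", "Integer", "Read depth per allele (ref, alt)")
    h.formats.add("GQ", 1, "Integer", "Phred-like confidence proxy from model score")
    h.add_sample(sample)
    return h


def _gt_tuple(genotype: str) -> Tuple[int, int]:
    return {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}[genotype]


def _vcf_alleles(call: VariantCall, ref: str) -> Tuple[int, str, str]:
    """(0-based POS, REF, ALT) with VCF anchoring for indels."""
    c = call.candidate
    if c.vtype == SNV:
        return c.pos, c.ref_allele, c.alt_allele
    if c.pos > 0:
        anchor = ref[c.pos - 1]
        if c.vtype == DEL:
            return c.pos - 1, anchor + c.ref_allele, anchor
        return c.pos - 1, anchor, anchor + c.alt_allele
    # variant at contig start: anchor on the base following the edit
    if c.vtype == DEL:
        anchor = ref[len(c.ref_allele)]
        return 0, c.ref_allele + anchor, anchor
    anchor = ref[0]
    return 0, anchor, c.alt_allele + anchor


def _write_call(out: pysam.VariantFile, call: VariantCall, ref: str, sample: str) -> None:
    c = call.candidate
    pos0, ref_allele, alt_allele = _vcf_alleles(call, ref)
    rec = out.new_record(
        contig=c.contig, start=pos0, alleles=(ref_allele, alt_allele)
    )
    if call.filters:
        for tag in sorted(call.filters):
            rec.filter.add(tag)
    else:
        rec.filter.add("PASS")
    f = call.features.as_dict()
    rec.info["SCORE"] = call.score
    rec.info["MMQ"] = call.site_mean_mapq
    rec.info["RS"] = f["ratio_score"]
    rec.info["AVNQS"] = f["mean_avnqs"]
    if c.vtype == SNV:
        rec.info["BQ"] = f["base_qual"]
        rec.info["RELPOS"] = f["rel_pos"]
        rec.info["TITV"] = int(f["titv"])
    else:
        rec.info["SD"] = int(f["strand_dir"])
        rec.info["ENT"] = f["seq_entropy"]
        rec.info["MVR"] = f["mean_var_rate"]
    smp = rec.samples[sample]
    smp["GT"] = _gt_tuple(call.genotype)
    smp["DP"] = c.site_depth
    smp["AD"] = (c.site_depth - c.alt_count, c.alt_count)
    smp["GQ"] = call.gq
    out.write(rec)


def _write_block(out: pysam.VariantFile, block: GvcfBlock, ref: str, sample: str) -> None:
    rec = out.new_record(
        contig=block.contig,
        start=block.start - 1,
        stop=block.end,
        alleles=(ref[block.start - 1], "<NON_REF>"),
    )
    rec.filter.add("PASS")
    rec.info["MIN_DP"] = block.min_dp
    rec.info["DPB"] = block.depth_class
    smp = rec.samples[sample]
    smp["GT"] = (0, 0)
    smp["DP"] = int(round(block.mean_dp))
    out.write(rec)


def write_vcf(
    calls: Iterable[VariantCall],
    reference_path: str,
    out_prefix: str,
    sample: str = "SAMPLE",
    gvcf: bool = False,
    bgzf: bool = False,
    gvcf_regions: Optional[Sequence[Tuple[Tuple[str, int, int], DepthProfile]]] = None,
) -> Tuple[str, str]:
    """Write sorted calls to ``<prefix>_snv.vcf[.gz]`` and ``<prefix>_indel.vcf[.gz]``.

    With ``gvcf=True``, non-variant blocks (computed per processed region
    from its depth profile in `gvcf_regions`) are interleaved into the SNV
    file; the indel file stays variant-only. Unsorted input raises at the
    first violation.
    """
    if gvcf and gvcf_regions is None:
        raise ValueError("gVCF output requires per-region depth profiles")

    ext = ".vcf.gz" if bgzf else ".vcf"
    mode = "wz" if bgzf else "w"
    snv_path = f"{out_prefix}_snv{ext}"
    indel_path = f"{out_prefix}_indel{ext}"

    contigs = []
    refs: Dict[str, str] = {}
    with pysam.FastaFile(reference_path) as fa:
        for name, length in zip(fa.references, fa.lengths):
            contigs.append((name, length))
            refs[name] = fa.fetch(name).upper()
    contig_rank = {name: i for i, (name, _) in enumerate(contigs)}

    calls = list(calls)
    last = None
    for call in calls:
        key = (contig_rank[call.candidate.contig], call.candidate.pos)
        if last is not None and key < last:
            raise ValueError(
                f"calls not sorted: {call.candidate.contig}:{call.candidate.pos + 1} "
                "follows a later position"
            )
        last = key

    snv_calls = [c for c in calls if c.candidate.vtype == SNV]
    indel_calls = [c for c in calls if c.candidate.vtype != SNV]

    snv_header = _build_header(contigs, sample, "snv", gvcf)
    with pysam.VariantFile(snv_path, mode, header=snv_header) as out:
        if gvcf:
            by_contig: Dict[str, List[VariantCall]] = {}
            for call in calls:
                by_contig.setdefault(call.candidate.contig, []).append(call)
            for (contig, rstart, rend), depth in gvcf_regions:
                region_calls = [
                    c for c in by_contig.get(contig, []) if rstart <= c.candidate.pos < rend
                ]
                items: List[Tuple[int, int, object]] = []
                for call in region_calls:
                    if call.candidate.vtype == SNV:
                        items.append((call.candidate.pos, 0, call))
                blocks = emit_gvcf_blocks(depth, region_calls, (rstart, rend))
                for b in blocks:
                    items.append((b.start - 1, 1, b))
                for _, _, item in sorted(items, key=lambda t: (t[0], t[1])):
                    if isinstance(item, GvcfBlock):
                        _write_block(out, item, refs[contig], sample)
                    else:
                        _write_call(out, item, refs[contig], sample)
        else:
            for call in snv_calls:
                _write_call(out, call, refs[call.candidate.contig], sample)

    indel_header = _build_header(contigs, sample, "indel", False)
    with pysam.VariantFile(indel_path, mode, header=indel_header) as out:
        for call in indel_calls:
            _write_call(out, call, refs[call.candidate.contig], sample)

    return snv_path, indel_path
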
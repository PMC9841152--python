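"""Synthetic diploid sequencing data with known truth.

Generates every input the caller and trainer consume: a random reference
contig at a requested GC content, a diploid set of planted SNVs and indels
with a normalized truth VCF, and a coordinate-sorted, indexed BAM of
simulated reads. Reads are drawn uniformly from the two haplotypes and
emitted pre-aligned at their ground-truth placement — CIGAR strings carry
I/D operators wherever a read crosses a planted indel — so no external
aligner is involved and every test stays hermetic. Sequencing noise is
modeled as per-base substitution errors, optional per-read small indel
errors, and injected fractions of duplicate-flagged and MAPQ-0 reads;
alignment ambiguity beyond that (soft-clip noise, quality-by-cycle decay)
is deliberately not modeled.

Planted variants are spaced at least two read lengths apart, so no read
ever crosses two variants and the single-allele-per-locus caller can in
principle recover every planted site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .discovery import DEL, INS, SNV, normalize_variant
from .model import INDEL_FEATURES, SNV_FEATURES, LogisticModel, logistic_score

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    ref_length: int = 100_000
    gc_fraction: float = 0.41  # human-like GC
    n_snv: int = 80
    n_ins: int = 15
    n_del: int = 15
    indel_size_range: Tuple[int, int] = (1, 10)
    het_fraction: float = 0.5
    coverage: float = 30.0
    read_length: int = 100
    base_error_rate: float = 0.002
    indel_error_rate: float = 0.0  # per-read probability of a 1-3 bp indel error
    duplicate_fraction: float = 0.0
    mapq0_fraction: float = 0.0
    seed: int = 0
    read_seed: Optional[int] = None  # vary reads while keeping ref and truth fixed
    contig: str = "sim1"

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "het_fraction",
            "base_error_rate",
            "indel_error_rate",
            "duplicate_fraction",
            "mapq0_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TruthVariant:
    """A planted variant in normalized (leftmost parsimonious) form."""

    pos: int  # 0-based, first affected base
    ref_allele: str
    alt_allele: str
    vtype: str
    genotype: str  # "0/1" or "1/1"
    haplotypes: Tuple[bool, bool]  # carried on hap0 / hap1

    @property
    def key(self) -> Tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


def make_reference(cfg: SimConfig) -> str:
    """Seeded random reference sequence at the requested GC fraction."""
    if cfg.ref_length < 1000:
        raise ValueError("ref_length must be >= 1000")
    rng = np.random.default_rng(cfg.seed)
    at, gc = (1.0 - cfg.gc_fraction) / 2.0, cfg.gc_fraction / 2.0
    return "".join(rng.choice(_BASES, size=cfg.ref_length, p=[at, gc, gc, at]))


def write_fasta(path: str, contig: str, seq: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(path)
    return path


def plant_variants(ref: str, cfg: SimConfig) -> List[TruthVariant]:
    """Choose well-spaced variant loci and diploid genotypes, normalized."""
    rng = np.random.default_rng(cfg.seed + 1)
    n_total = cfg.n_snv + cfg.n_ins + cfg.n_del
    margin = 2 * cfg.read_length
    spacing = 2 * cfg.read_length
    slots = list(range(margin, cfg.ref_length - margin - cfg.indel_size_range[1], spacing))
    if n_total > len(slots):
        raise ValueError(
            f"cannot place {n_total} variants with {spacing} bp spacing "
            f"in {cfg.ref_length} bp (room for {len(slots)})"
        )
    positions = sorted(rng.choice(len(slots), size=n_total, replace=False))
    positions = [slots[i] for i in positions]
    types = [SNV] * cfg.n_snv + [INS] * cfg.n_ins + [DEL] * cfg.n_del
    rng.shuffle(types)

    out: List[TruthVariant] = []
    lo, hi = cfg.indel_size_range
    for pos, vtype in zip(positions, types):
        if vtype == SNV:
            ref_a = ref[pos]
            alt_a = str(rng.choice([b for b in "ACGT" if b != ref_a]))
        elif vtype == INS:
            k = int(rng.integers(lo, hi + 1))
            ref_a = ""
            alt_a = "".join(rng.choice(_BASES, size=k))
        else:
            k = int(rng.integers(lo, hi + 1))
            ref_a = ref[pos : pos + k]
            alt_a = ""
        npos, nref, nalt = normalize_variant(pos, ref_a, alt_a, ref)
        het = rng.random() < cfg.het_fraction
        if het:
            hap0 = bool(rng.integers(0, 2))
            haps = (hap0, not hap0)
            gt = "0/1"
        else:
            haps, gt = (True, True), "1/1"
        out.append(TruthVariant(npos, nref, nalt, vtype, gt, haps))
    out.sort(key=lambda v: v.pos)
    return out


# ---------------------------------------------------------------------------
# haplotype construction and coordinate-correct read alignment


def build_haplotype(ref: str, variants: Sequence[TruthVariant]) -> Tuple[str, List[tuple]]:
    """Apply variants to the reference; return (sequence, block map).

    Blocks are ``("M", ref_start, ref_end, hap_start)``,
    ``("I", seq, hap_start, ref_pos)`` or ``("D", ref_start, ref_end)`` in
    reference order; M and I blocks carry their haplotype offsets.
    """
    parts: List[str] = []
    blocks: List[tuple] = []
    rpos = 0
    hpos = 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.pos > rpos:
            seg = ref[rpos : v.pos]
            blocks.append(("M", rpos, v.pos, hpos))
            parts.append(seg)
            hpos += len(seg)
            rpos = v.pos
        if v.vtype == SNV:
            blocks.append(("M", rpos, rpos + 1, hpos))  # mismatch inside M
            parts.append(v.alt_allele)
            hpos += 1
            rpos += 1
        elif v.vtype == INS:
            blocks.append(("I", v.alt_allele, hpos, rpos))
            parts.append(v.alt_allele)
            hpos += len(v.alt_allele)
        else:
            blocks.append(("D", rpos, rpos + len(v.ref_allele)))
            rpos += len(v.ref_allele)
    if rpos < len(ref):
        blocks.append(("M", rpos, len(ref), hpos))
        parts.append(ref[rpos:])
    hap = "".join(parts)
    # merge adjacent M blocks for a compact walk
    merged: List[tuple] = []
    for b in blocks:
        if (
            merged
            and b[0] == "M"
            and merged[-1][0] == "M"
            and merged[-1][2] == b[1]
            and merged[-1][3] + (merged[-1][2] - merged[-1][1]) == b[3]
        ):
            prev = merged.pop()
            merged.append(("M", prev[1], b[2], prev[3]))
        else:
            merged.append(b)
    return hap, merged


# CIGAR codes
_OP_M, _OP_I, _OP_D, _OP_S = 0, 1, 2, 4


def _align_read(
    blocks: List[tuple], hap: str, h0: int, h1: int
) -> Optional[Tuple[int, List[Tuple[int, int]]]]:
    """Alignment of haplotype interval [h0, h1) back to the reference.

    Returns (reference start, CIGAR) or None when the interval carries no
    reference-anchored base. Terminal insertions become soft clips, terminal
    deletions are dropped, exactly as an aligner would emit them.
    """
    ops: List[Tuple[int, int]] = []
    ref_start: Optional[int] = None
    started = False
    for b in blocks:
        if b[0] == "M":
            _, rs, re_, hs = b
            he = hs + (re_ - rs)
            lo, hi = max(h0, hs), min(h1, he)
            if lo < hi:
                if ref_start is None:
                    ref_start = rs + (lo - hs)
                ops.append((_OP_M, hi - lo))
                started = True
        elif b[0] == "I":
            _, seq, hs, _rpos = b
            he = hs + len(seq)
            lo, hi = max(h0, hs), min(h1, he)
            if lo < hi:
                ops.append((_OP_I, hi - lo))
        else:  # D: no haplotype extent; emit only between flanking M content
            if started:
                ops.append((_OP_D, b[2] - b[1]))
    if ref_start is None:
        return None
    # trim trailing D ops, convert terminal I to S
    while ops and ops[-1][0] == _OP_D:
        ops.pop()
    # drop D ops emitted after the last M (handled above) and leading ones
    while ops and ops[0][0] == _OP_D:
        ops.pop(0)
    if ops and ops[0][0] == _OP_I:
        ops[0] = (_OP_S, ops[0][1])
    if ops and ops[-1][0] == _OP_I:
        ops[-1] = (_OP_S, ops[-1][1])
    return ref_start, ops


def _inject_indel_error(
    rng: np.random.Generator, seq: str, ops: List[Tuple[int, int]]
) -> Tuple[str, List[Tuple[int, int]]]:
    """Plant a 1-3 bp insertion or deletion error inside a long M run."""
    k = int(rng.integers(1, 4))
    m_idx = [
        i for i, (op, l) in enumerate(ops) if op == _OP_M and l >= 2 * k + 10
    ]
    if not m_idx:
        return seq, ops
    i = int(rng.choice(m_idx))
    qoff = 0
    for op, l in ops[:i]:
        if op in (_OP_M, _OP_I, _OP_S):
            qoff += l
    l = ops[i][1]
    cut = int(rng.integers(5, l - 5 - k))
    if rng.random() < 0.5:  # insertion error
        ins = "".join(rng.choice(_BASES, size=k))
        new_ops = ops[:i] + [(_OP_M, cut), (_OP_I, k), (_OP_M, l - cut)] + ops[i + 1 :]
        new_seq = seq[: qoff + cut] + ins + seq[qoff + cut :]
    else:  # deletion error
        new_ops = ops[:i] + [(_OP_M, cut), (_OP_D, k), (_OP_M, l - cut - k)] + ops[i + 1 :]
        new_seq = seq[: qoff + cut] + seq[qoff + cut + k :]
    return new_seq, new_ops


def simulate_alignments(
    ref: str,
    variants: Sequence[TruthVariant],
    cfg: SimConfig,
    out_path: str,
    reference_path: Optional[str] = None,
) -> str:
    """Write a coordinate-sorted, indexed BAM of simulated reads.

    Reads are drawn uniformly from both haplotypes; per-base substitution
    errors, optional read-level indel errors, and the configured fractions
    of duplicate-flagged and MAPQ-0 reads are injected.
    """
    rng = np.random.default_rng(cfg.read_seed if cfg.read_seed is not None else cfg.seed + 2)
    haps = [
        build_haplotype(ref, [v for v in variants if v.haplotypes[h]]) for h in (0, 1)
    ]
    n_reads = int(round(cfg.coverage * cfg.ref_length / cfg.read_length))
    L = cfg.read_length

    records = []
    for i in range(n_reads):
        h = int(rng.integers(0, 2))
        hap, blocks = haps[h]
        if len(hap) <= L:
            h0 = 0
        else:
            h0 = int(rng.integers(0, len(hap) - L + 1))
        aln = _align_read(blocks, hap, h0, h0 + L)
        if aln is None:
            continue
        ref_start, ops = aln
        seq = hap[h0 : h0 + L]
        if cfg.indel_error_rate > 0 and rng.random() < cfg.indel_error_rate:
            seq, ops = _inject_indel_error(rng, seq, ops)
        seq_arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        if cfg.base_error_rate > 0:
            errs = np.nonzero(rng.random(len(seq_arr)) < cfg.base_error_rate)[0]
            for j in errs:
                cur = seq_arr[j].decode()
                seq_arr[j] = str(rng.choice([b for b in "ACGT" if b != cur])).encode()
        seq = seq_arr.tobytes().decode()
        quals = rng.integers(25, 41, size=len(seq))
        mapq = 0 if rng.random() < cfg.mapq0_fraction else 60
        flag_dup = rng.random() < cfg.duplicate_fraction
        flag_rev = bool(rng.integers(0, 2))
        records.append((ref_start, i, ops, seq, quals, mapq, flag_dup, flag_rev))

    records.sort(key=lambda r: (r[0], r[1]))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.contig, "LN": cfg.ref_length}],
    }
    with pysam.AlignmentFile(out_path, "wb", header=header) as bam:
        for ref_start, i, ops, seq, quals, mapq, flag_dup, flag_rev in records:
            a = pysam.AlignedSegment()
            a.query_name = f"read{i:07d}"
            a.reference_id = 0
            a.reference_start = ref_start
            a.mapping_quality = mapq
            a.cigartuples = ops
            a.query_sequence = seq
            a.query_qualities = quals.tolist()
            a.flag = (0x400 if flag_dup else 0) | (0x10 if flag_rev else 0)
            bam.write(a)
    pysam.index(out_path)
    return out_path


def write_truth_vcf(path: str, ref: str, variants: Sequence[TruthVariant], contig: str) -> str:
    """Truth call set in VCF 4.2 with standard indel anchoring."""
    h = pysam.VariantHeader()
    h.contigs.add(contig, length=len(ref))
    h.formats.add("GT", 1, "String", "Genotype")
    h.add_sample("TRUTH")
    with pysam.VariantFile(path, "w", header=h) as out:
        for v in sorted(variants, key=lambda v: v.pos):
            if v.vtype == SNV:
                pos0, ra, aa = v.pos, v.ref_allele, v.alt_allele
            elif v.pos > 0:
                anchor = ref[v.pos - 1]
                if v.vtype == DEL:
                    pos0, ra, aa = v.pos - 1, anchor + v.ref_allele, anchor
                else:
                    pos0, ra, aa = v.pos - 1, anchor, anchor + v.alt_allele
            else:
                nxt = ref[len(v.ref_allele)]
                if v.vtype == DEL:
                    pos0, ra, aa = 0, v.ref_allele + nxt, nxt
                else:
                    pos0, ra, aa = 0, ref[0], v.alt_allele + ref[0]
            rec = out.new_record(contig=contig, start=pos0, alleles=(ra, aa))
            rec.samples["TRUTH"]["GT"] = (0, 1) if v.genotype == "0/1" else (1, 1)
            out.write(rec)
    return path


def write_regions_bed(path: str, cfg: SimConfig) -> str:
    """Evaluation regions: the contig minus one read length at each edge."""
    with open(path, "w") as fh:
        fh.write(f"{cfg.contig}\t{cfg.read_length}\t{cfg.ref_length - cfg.read_length}\n")
    return path


def simulate_dataset(cfg: SimConfig, out_dir: str, prefix: str = "sim") -> Dict[str, object]:
    """Generate reference, truth VCF, regions BED, and an aligned BAM.

    Returns a dict with paths (``fasta``, ``bam``, ``truth_vcf``,
    ``regions_bed``), the reference sequence, and the truth variant list.
    """
    os.makedirs(out_dir, exist_ok=True)
    ref = make_reference(cfg)
    fasta = write_fasta(os.path.join(out_dir, f"{prefix}.fa"), cfg.contig, ref)
    variants = plant_variants(ref, cfg)
    bam = simulate_alignments(ref, variants, cfg, os.path.join(out_dir, f"{prefix}.bam"))
    truth = write_truth_vcf(os.path.join(out_dir, f"{prefix}_truth.vcf"), ref, variants, cfg.contig)
    bed = write_regions_bed(os.path.join(out_dir, f"{prefix}_regions.bed"), cfg)
    return {
        "fasta": fasta,
        "bam": bam,
        "truth_vcf": truth,
        "regions_bed": bed,
        "reference": ref,
        "variants": variants,
    }


# ---------------------------------------------------------------------------
# model-generated labeled feature pools (for retraining tests)

# Marginals for the model-recovery experiment. Quality features span the
# low-phred regime (2-20) so the linear predictor crosses the decision
# boundary with appreciable mass and every coefficient is identifiable;
# this is an identifiability-driven design, not a model of real Illumina
# quality profiles (at typical quals the default models saturate near 1).
DEFAULT_SNV_DISTRIBUTIONS = {
    "ratio_score": ("uniform", 0.0, 1.0),
    "base_qual": ("uniform", 2.0, 20.0),
    "mean_avnqs": ("uniform", 2.0, 20.0),
    "rel_pos": ("uniform", 0.0, 1.0),
    "titv": ("bernoulli", 0.5),
}

DEFAULT_INDEL_DISTRIBUTIONS = {
    "ratio_score": ("uniform", 0.0, 1.0),
    "strand_dir": ("bernoulli", 0.5),
    "mean_avnqs": ("uniform", 2.0, 20.0),
    "seq_entropy": ("uniform", 0.0, 2.0),
    "mean_var_rate": ("uniform", 0.0, 0.3),
}


def make_labeled_feature_pools(
    model: LogisticModel,
    n: int,
    feature_distributions: Optional[Dict[str, tuple]] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, Tuple[str, ...]]:
    """Sample feature vectors and Bernoulli labels from a logistic model.

    Features are drawn independently from the stated marginal distributions
    (``("uniform", lo, hi)`` or ``("bernoulli", p)``); each label is 1 with
    probability equal to the model score at that feature vector. Returns
    ``(X, y, feature_names)`` with X of shape (n, 5).
    """
    names = SNV_FEATURES if model.model_kind == "SNV" else INDEL_FEATURES
    dists = feature_distributions or (
        DEFAULT_SNV_DISTRIBUTIONS if model.model_kind == "SNV" else DEFAULT_INDEL_DISTRIBUTIONS
    )
    missing = set(names) - set(dists)
    if missing:
        raise ValueError(f"no distribution for features: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    cols = []
    for name in names:
        spec = dists[name]
        if spec[0] == "uniform":
            cols.append(rng.uniform(spec[1], spec[2], size=n))
        elif spec[0] == "bernoulli":
            cols.append((rng.random(n) < spec[1]).astype(float))
        else:
            raise ValueError(f"unknown distribution kind {spec[0]!r}")
    X = np.column_stack(cols)
    beta = np.array([model.coefficients[name] for name in names])
    z = model.intercept + X @ beta
    p = 1.0 / (1.0 + np.exp(-z))
    y = (rng.random(n) < p).astype(int)
    return X, y, names
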
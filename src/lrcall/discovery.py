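"""Candidate variant discovery from CIGAR evidence.

Per-read sequence variations are read directly off each alignment's CIGAR
string: SNVs are point differences inside match-operator spans, insertions
and deletions come from I and D operators. No local realignment is
performed. Each variation is normalized to its leftmost parsimonious
representation before variations with matching coordinates and alleles are
aggregated across reads into candidates.

Coordinates are 0-based half-open throughout; conversion to 1-based happens
only at VCF output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .alignment_io import (
    CIGAR_D,
    CIGAR_EQ,
    CIGAR_H,
    CIGAR_I,
    CIGAR_M,
    CIGAR_N,
    CIGAR_P,
    CIGAR_S,
    CIGAR_X,
    AlignedRead,
)

logger = logging.getLogger(__name__)

SNV = "SNV"
INS = "INS"
DEL = "DEL"

_ACGT = set("ACGT")

#: reference distance (bases) defining the quality window around a variant
NEIGHBOR_WINDOW = 5


@dataclass
class ReadSupport:
    """Per-read evidence metadata attached to one observed variation."""

    is_reverse: bool
    mapq: int
    site_qual: Optional[float]  # phred at the variant base (SNVs only)
    window_qual: float  # mean phred within NEIGHBOR_WINDOW of the site
    rel_pos: float  # query offset / (read length - 1), in [0, 1]
    aligned_length: int  # reference-consuming span of the read
    var_count: int = 0  # total variations emitted for this read


@dataclass
class ReadVariant:
    """One normalized sequence difference observed on a single read."""

    contig: str
    pos: int  # 0-based; for indels, the first affected reference base
    ref_allele: str
    alt_allele: str
    vtype: str
    support: ReadSupport

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class CandidateVariant:
    """A locus+allele aggregated across supporting reads."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    supporting: List[ReadSupport] = field(default_factory=list)
    site_depth: int = 0

    @property
    def alt_count(self) -> int:
        return len(self.supporting)

    @property
    def strands_seen(self) -> Tuple[bool, bool]:
        fwd = any(not s.is_reverse for s in self.supporting)
        rev = any(s.is_reverse for s in self.supporting)
        return (fwd, rev)

    @property
    def ref_span(self) -> int:
        """Reference bases affected (1 for SNV/INS anchor, len(ref) for DEL)."""
        return max(1, len(self.ref_allele))

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


class DepthProfile:
    """Filtered read depth and MAPQ totals per reference position.

    Covers one contig interval ``[start, end)``; every filter-passing read
    contributes one unit of depth across its reference-consuming span.
    """

    def __init__(self, contig: str, start: int, end: int):
        if end < start:
            raise ValueError("end < start")
        self.contig = contig
        self.start = start
        self.end = end
        self._depth = np.zeros(end - start, dtype=np.int32)
        self._mapq_sum = np.zeros(end - start, dtype=np.float64)

    def add_read(self, read: AlignedRead) -> None:
        s = max(read.start, self.start) - self.start
        e = min(read.reference_end, self.end) - self.start
        if e > s:
            self._depth[s:e] += 1
            self._mapq_sum[s:e] += read.mapq

    def depth_at(self, pos: int) -> int:
        if not self.start <= pos < self.end:
            return 0
        return int(self._depth[pos - self.start])

    def min_depth(self, start: int, end: int) -> int:
        s = max(start, self.start) - self.start
        e = min(end, self.end) - self.start
        if e <= s:
            return self.depth_at(start)
        return int(self._depth[s:e].min())

    def mean_depth(self, start: int, end: int) -> float:
        s = max(start, self.start) - self.start
        e = min(end, self.end) - self.start
        if e <= s:
            return float(self.depth_at(start))
        return float(self._depth[s:e].mean())

    def mean_mapq_at(self, pos: int) -> float:
        d = self.depth_at(pos)
        if d == 0:
            return 0.0
        return float(self._mapq_sum[pos - self.start]) / d

    @property
    def depth_array(self) -> np.ndarray:
        return self._depth


def _window_mean_qual(
    pairs: List[Tuple[int, int]], quals: List[int], center: int, exclude_q: Optional[int] = None
) -> float:
    """Mean phred over read bases aligned within NEIGHBOR_WINDOW of `center`.

    `pairs` are (query_offset, reference_position) aligned pairs from match
    operators. The variant base itself is included for SNVs; `exclude_q` is
    unused by default and reserved for alternative window conventions.
    """
    vals = [
        quals[q]
        for q, r in pairs
        if abs(r - center) <= NEIGHBOR_WINDOW and (exclude_q is None or q != exclude_q)
    ]
    if not vals:
        return 0.0
    return float(sum(vals)) / len(vals)


def extract_read_variants(read: AlignedRead, ref: str) -> List[ReadVariant]:
    """Walk the CIGAR of one filtered read and emit its sequence variations.

    One SNV per mismatched base inside M/=/X spans (both bases must be
    A/C/G/T; sites with N contribute depth but no candidate), one INS per
    interior I operator, one DEL per D operator. Soft clips consume query
    only and never produce variants. Terminal insertions (first or last
    CIGAR operation after clipping) are treated like clips: they cannot be
    anchored and are skipped.

    Each emitted variant carries per-read metadata (strand, site and window
    qualities, relative in-read position, aligned length); the per-read
    variation count is filled in across all variants of the read before
    returning, counting every SNV and each indel event as 1.
    """
    seq = read.sequence
    quals = read.base_quals
    rlen = len(seq)
    if rlen == 0:
        return []

    # aligned (query_offset, ref_pos) pairs from match ops, for window quals
    pairs: List[Tuple[int, int]] = []
    raw: List[Tuple[int, str, str, str, int]] = []  # (pos, ref_a, alt_a, vtype, qoff)

    core_ops = [
        (i, op, l)
        for i, (op, l) in enumerate(read.cigar)
        if op not in (CIGAR_S, CIGAR_H, CIGAR_P)
    ]

    qpos = 0
    rpos = read.start
    for idx, (op, length) in enumerate(read.cigar):
        if op in (CIGAR_M, CIGAR_EQ, CIGAR_X):
            for k in range(length):
                pairs.append((qpos + k, rpos + k))
                rb = ref[rpos + k]
                qb = seq[qpos + k]
                if rb != qb and rb in _ACGT and qb in _ACGT:
                    raw.append((rpos + k, rb, qb, SNV, qpos + k))
            qpos += length
            rpos += length
        elif op == CIGAR_I:
            interior = core_ops and idx not in (core_ops[0][0], core_ops[-1][0])
            ins = seq[qpos : qpos + length]
            if interior and set(ins) <= _ACGT:
                raw.append((rpos, "", ins, INS, qpos))
            qpos += length
        elif op == CIGAR_D:
            dele = ref[rpos : rpos + length]
            interior = core_ops and idx not in (core_ops[0][0], core_ops[-1][0])
            if interior and set(dele) <= _ACGT:
                raw.append((rpos, dele, "", DEL, qpos))
            rpos += length
        elif op == CIGAR_N:
            rpos += length
        elif op == CIGAR_S:
            qpos += length
        # H, P consume nothing we track

    if qpos != rlen:
        logger.warning(
            "read %s: CIGAR consumes %d query bases but sequence has %d; skipped",
            read.query_name,
            qpos,
            rlen,
        )
        return []

    out: List[ReadVariant] = []
    for pos, ref_a, alt_a, vtype, qoff in raw:
        site_qual = float(quals[qoff]) if vtype == SNV else None
        window = _window_mean_qual(pairs, quals, pos)
        rel = qoff / (rlen - 1) if rlen > 1 else 0.0
        support = ReadSupport(
            is_reverse=read.is_reverse,
            mapq=read.mapq,
            site_qual=site_qual,
            window_qual=window,
            rel_pos=rel,
            aligned_length=read.aligned_length,
        )
        out.append(ReadVariant(read.contig, pos, ref_a, alt_a, vtype, support))

    for v in out:
        v.support.var_count = len(out)
    return out


def normalize_variant(pos: int, ref_allele: str, alt_allele: str, ref: str) -> Tuple[int, str, str]:
    """Reduce an edit to its leftmost parsimonious representation.

    Shared trailing then leading bases are trimmed; a pure insertion or
    deletion is then shifted left one base at a time while the base
    preceding it equals the last base of the varying sequence (the standard
    left-alignment rotation). The result is a fixed point of this function.
    """
    r, a = ref_allele, alt_allele
    # trim shared suffix
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    # trim shared prefix
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    if not r and not a:
        raise ValueError("alleles are identical: not a variant")
    if r and a:
        return pos, r, a  # substitution (SNV, or MNP if longer)
    seq = r or a
    while pos > 0 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, (seq if not a else ""), (seq if not r else "")


def left_align_parsimonious(v: ReadVariant, ref: str) -> ReadVariant:
    """Return `v` in leftmost parsimonious form (idempotent; SNVs are fixed)."""
    pos, r, a = normalize_variant(v.pos, v.ref_allele, v.alt_allele, ref)
    if (pos, r, a) == (v.pos, v.ref_allele, v.alt_allele):
        return v
    return ReadVariant(v.contig, pos, r, a, v.vtype, v.support)


def aggregate_candidates(
    variants: Iterable[ReadVariant], depth: DepthProfile
) -> List[CandidateVariant]:
    """Group normalized per-read variations into candidates with depth counts.

    One candidate per unique (contig, pos, ref, alt); `site_depth` is the
    filtered depth at the variant position, using the minimum across the
    deleted span for deletions (a conservative denominator).
    """
    by_key: Dict[Tuple[str, int, str, str], CandidateVariant] = {}
    for v in variants:
        cand = by_key.get(v.key)
        if cand is None:
            cand = CandidateVariant(v.contig, v.pos, v.ref_allele, v.alt_allele, v.vtype)
            by_key[v.key] = cand
        cand.supporting.append(v.support)

    out = []
    for cand in by_key.values():
        if cand.vtype == DEL:
            d = depth.min_depth(cand.pos, cand.pos + len(cand.ref_allele))
        else:
            d = depth.depth_at(cand.pos)
        # supporting reads always count toward depth, even if left-alignment
        # shifted the locus to the edge of their aligned span
        cand.site_depth = max(d, cand.alt_count)
        out.append(cand)
    out.sort(key=lambda c: (c.contig, c.pos, c.ref_allele, c.alt_allele))
    return out
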
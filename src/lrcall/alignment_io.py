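"""Alignment and reference input with preliminary read filtering.

Reads are streamed from a coordinate-sorted, indexed SAM/BAM/CRAM file and
passed through the caller's preliminary filter: unmapped reads, duplicate
reads, and reads whose mapping quality falls below a minimum threshold
(default 1, so MAPQ 0 is dropped) are excluded from all further evaluation.
Secondary, supplementary, and QC-fail records are likewise dropped since
they would double-count evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import pysam

_VALID_REF_BASES = set("ACGTN")

# CIGAR operator codes as used by pysam/htslib
CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_N, CIGAR_S, CIGAR_H, CIGAR_P, CIGAR_EQ, CIGAR_X = range(9)

_QUERY_CONSUMING = {CIGAR_M, CIGAR_I, CIGAR_S, CIGAR_EQ, CIGAR_X}
_REF_CONSUMING = {CIGAR_M, CIGAR_D, CIGAR_N, CIGAR_EQ, CIGAR_X}


@dataclass
class AlignedRead:
    """One mapped read: the evidence unit for candidate discovery."""

    query_name: str
    contig: str
    start: int  # 0-based leftmost reference coordinate
    mapq: int
    cigar: List[Tuple[int, int]]  # (operator code, length)
    sequence: str
    base_quals: List[int]
    is_unmapped: bool = False
    is_duplicate: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if len(self.base_quals) != len(self.sequence):
            raise ValueError(
                f"read {self.query_name}: {len(self.base_quals)} base qualities "
                f"for {len(self.sequence)} bases"
            )
        qlen = sum(l for op, l in self.cigar if op in _QUERY_CONSUMING)
        if self.cigar and qlen != len(self.sequence):
            raise ValueError(
                f"read {self.query_name}: CIGAR consumes {qlen} query bases, "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def reference_end(self) -> int:
        """One past the last reference position covered by this alignment."""
        return self.start + sum(l for op, l in self.cigar if op in _REF_CONSUMING)

    @property
    def aligned_length(self) -> int:
        """Reference-consuming span of the alignment (bases)."""
        return self.reference_end - self.start

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedRead":
        quals = rec.query_qualities
        return cls(
            query_name=rec.query_name or "",
            contig=rec.reference_name or "",
            start=rec.reference_start,
            mapq=rec.mapping_quality,
            cigar=list(rec.cigartuples or []),
            sequence=rec.query_sequence or "",
            base_quals=list(quals) if quals is not None else [0] * len(rec.query_sequence or ""),
            is_unmapped=rec.is_unmapped,
            is_duplicate=rec.is_duplicate,
            is_reverse=rec.is_reverse,
        )


@dataclass
class ReadFilterConfig:
    """Preliminary read filter settings (defaults match the caller's)."""

    min_mapq: int = 1
    drop_duplicates: bool = True
    drop_unmapped: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


def read_passes_filter(rec: pysam.AlignedSegment, cfg: ReadFilterConfig) -> bool:
    """Pure predicate: does this record survive preliminary filtering?

    Inclusion depends only on the record's flags and MAPQ plus the config.
    """
    if cfg.drop_unmapped and rec.is_unmapped:
        return False
    if cfg.drop_duplicates and rec.is_duplicate:
        return False
    if rec.mapping_quality < cfg.min_mapq:
        return False
    if rec.is_secondary or rec.is_supplementary or rec.is_qcfail:
        return False
    return True


def stream_reads(
    alignment_path: str,
    region: Optional[Tuple[str, Optional[int], Optional[int]]] = None,
    cfg: Optional[ReadFilterConfig] = None,
    reference_path: Optional[str] = None,
) -> Iterator[AlignedRead]:
    """Stream filter-passing reads in coordinate order.

    Parameters
    ----------
    alignment_path:
        Coordinate-sorted, indexed SAM/BAM/CRAM file.
    region:
        Optional ``(contig, start, end)`` (0-based half-open; start/end may be
        None for a whole contig). Reads overlapping the boundary are included
        if any aligned base falls inside.
    cfg:
        Filter settings; defaults drop unmapped, duplicate, and MAPQ-0 reads.
    reference_path:
        Reference FASTA, required for CRAM decoding.
    """
    cfg = cfg or ReadFilterConfig()
    kwargs = {}
    if reference_path is not None:
        kwargs["reference_filename"] = reference_path
    try:
        af = pysam.AlignmentFile(alignment_path, **kwargs)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {alignment_path}: {exc}") from exc
    with af:
        if region is not None:
            contig = region[0]
            if contig not in af.references:
                raise ValueError(
                    f"region contig {contig!r} not present in alignment header"
                )
            it = af.fetch(contig, region[1], region[2])
        else:
            it = af.fetch()
        for rec in it:
            if read_passes_filter(rec, cfg):
                yield AlignedRead.from_pysam(rec)


def load_reference(fasta_path: str, contig: str) -> str:
    """Load one contig of an indexed FASTA, uppercased.

    Soft-masked (lowercase) bases are uppercased; any character outside
    A/C/G/T/N is rejected.
    """
    with pysam.FastaFile(fasta_path) as fa:
        if contig not in fa.references:
            raise KeyError(f"contig {contig!r} not found in {fasta_path}")
        seq = fa.fetch(contig).upper()
    bad = set(seq) - _VALID_REF_BASES
    if bad:
        raise ValueError(
            f"reference contig {contig} contains invalid characters: {sorted(bad)}"
        )
    return seq


def reference_contigs(fasta_path: str) -> List[Tuple[str, int]]:
    """(name, length) for every contig in an indexed FASTA, in file order."""
    with pysam.FastaFile(fasta_path) as fa:
        return list(zip(fa.references, fa.lengths))
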
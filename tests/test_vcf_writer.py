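import gzip

import pysam
import pytest

from lrcall.discovery import DEL, INS, SNV, CandidateVariant, DepthProfile, ReadSupport
from lrcall.features import IndelFeatures, SnvFeatures
from lrcall.genotype import HET, VariantCall
from lrcall.vcf_writer import (
    GvcfBlock,
    depth_class,
    emit_gvcf_blocks,
    write_vcf,
)


def _ref_fasta(tmp_path, seq, contig="c1"):
    fa = tmp_path / "ref.fa"
    fa.write_text(f">{contig}\n{seq}\n")
    pysam.faidx(str(fa))
    return str(fa)


def _call(contig, pos, ref_a, alt_a, vtype, depth=20, alt=10):
    sup = [ReadSupport(False, 60, 30.0, 30.0, 0.5, 100, 1) for _ in range(alt)]
    c = CandidateVariant(contig, pos, ref_a, alt_a, vtype, supporting=sup)
    c.site_depth = depth
    if vtype == SNV:
        f = SnvFeatures(alt / depth, 30.0, 30.0, 0.5, 1)
    else:
        f = IndelFeatures(alt / depth, 1, 30.0, 1.0, 0.01)
    return VariantCall(c, f, 0.95, HET, None, site_mean_mapq=60.0)


class TestAnchoring:
    def test_deletion_anchored_on_preceding_base(self, tmp_path):
        #      0123456789
        seq = "GATTACACGT"
        fa = _ref_fasta(tmp_path, seq)
        call = _call("c1", 4, "AC", "", DEL)  # delete seq[4:6] = "AC"
        snv_path, indel_path = write_vcf([call], fa, str(tmp_path / "out"))
        rec = next(iter(pysam.VariantFile(indel_path)))
        assert (rec.pos, rec.ref, rec.alts[0]) == (4, "TAC", "T")

    def test_insertion_anchored_on_preceding_base(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        call = _call("c1", 4, "", "GG", INS)  # insert before seq[4], anchor seq[3]="T"
        _, indel_path = write_vcf([call], fa, str(tmp_path / "out"))
        rec = next(iter(pysam.VariantFile(indel_path)))
        assert (rec.pos, rec.ref, rec.alts[0]) == (4, "T", "TGG")

    def test_contig_start_variant_anchors_on_following_base(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        call = _call("c1", 0, "GA", "", DEL)
        _, indel_path = write_vcf([call], fa, str(tmp_path / "out"))
        rec = next(iter(pysam.VariantFile(indel_path)))
        assert (rec.pos, rec.ref, rec.alts[0]) == (1, "GAT", "T")

    def test_snv_written_at_one_based_position(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        call = _call("c1", 3, "T", "G", SNV)
        snv_path, _ = write_vcf([call], fa, str(tmp_path / "out"))
        rec = next(iter(pysam.VariantFile(snv_path)))
        assert (rec.pos, rec.ref, rec.alts[0]) == (4, "T", "G")
        assert "PASS" in rec.filter


class TestWriter:
    def test_empty_stream_produces_parsable_header_only_files(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        snv_path, indel_path = write_vcf([], fa, str(tmp_path / "out"))
        for path in (snv_path, indel_path):
            with pysam.VariantFile(path) as vf:
                assert list(vf) == []

    def test_unsorted_input_is_fatal(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        calls = [_call("c1", 5, "A", "G", SNV), _call("c1", 2, "T", "G", SNV)]
        with pytest.raises(ValueError, match="not sorted"):
            write_vcf(calls, fa, str(tmp_path / "out"))

    def test_format_fields_round_trip(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        snv_path, _ = write_vcf([_call("c1", 3, "T", "G", SNV)], fa, str(tmp_path / "o"))
        rec = next(iter(pysam.VariantFile(snv_path)))
        s = rec.samples["SAMPLE"]
        assert s["GT"] == (0, 1)
        assert s["DP"] == 20
        assert tuple(s["AD"]) == (10, 10)
        assert rec.info["SCORE"] == pytest.approx(0.95, abs=1e-6)

    def test_bgzf_output_round_trips_to_plain_bytes(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT")
        calls = [_call("c1", 3, "T", "G", SNV)]
        snv_gz, _ = write_vcf(calls, fa, str(tmp_path / "z"), bgzf=True)
        snv_plain, _ = write_vcf(calls, fa, str(tmp_path / "p"), bgzf=False)
        with gzip.open(snv_gz, "rb") as fh:
            assert fh.read() == open(snv_plain, "rb").read()


class TestGvcfBlocks:
    def _depth(self, values):
        d = DepthProfile("c1", 0, len(values))
        for i, v in enumerate(values):
            d._depth[i] = v
        return d

    def test_uniform_depth_no_calls_single_block(self):
        d = self._depth([30] * 100)
        blocks = emit_gvcf_blocks(d, [], (0, 100))
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start, b.end, b.min_dp, b.depth_class) == (1, 100, 30, "20-49")

    def test_variant_splits_region_into_abutting_blocks(self):
        d = self._depth([30] * 100)
        call = _call("c1", 50, "A", "G", SNV)
        blocks = emit_gvcf_blocks(d, [call], (0, 100))
        assert [(b.start, b.end) for b in blocks] == [(1, 50), (52, 100)]
        assert sum(b.length for b in blocks) + 1 == 100

    def test_depth_class_change_forces_boundary(self):
        d = self._depth([30] * 50 + [0] * 50)
        blocks = emit_gvcf_blocks(d, [], (0, 100))
        assert [(b.start, b.end, b.min_dp) for b in blocks] == [(1, 50, 30), (51, 100, 0)]

    def test_partition_is_exact_for_arbitrary_profiles(self):
        import numpy as np

        rng = np.random.default_rng(1)
        d = self._depth(rng.integers(0, 60, size=500).tolist())
        calls = [_call("c1", p, "A", "G", SNV) for p in (100, 200, 300)]
        blocks = emit_gvcf_blocks(d, calls, (0, 500))
        positions = set()
        for b in blocks:
            span = set(range(b.start - 1, b.end))
            assert not span & positions
            positions |= span
        assert positions | {100, 200, 300} == set(range(500))

    def test_depth_class_labels(self):
        assert depth_class(0) == "0"
        assert depth_class(4) == "1-4"
        assert depth_class(19) == "10-19"
        assert depth_class(50) == ">=50"


class TestGvcfFile:
    def test_gvcf_records_carry_end_and_min_dp(self, tmp_path):
        fa = _ref_fasta(tmp_path, "GATTACACGT" * 10)
        d = DepthProfile("c1", 0, 100)
        d._depth[:] = 25
        call = _call("c1", 50, "A", "G", SNV)
        snv_path, _ = write_vcf(
            [call], fa, str(tmp_path / "g"), gvcf=True,
            gvcf_regions=[(("c1", 0, 100), d)],
        )
        recs = list(pysam.VariantFile(snv_path))
        blocks = [r for r in recs if r.alts[0] == "<NON_REF>"]
        assert len(blocks) == 2
        assert blocks[0].stop == 50 and blocks[0].info["MIN_DP"] == 25
        variant = [r for r in recs if r.alts[0] != "<NON_REF>"]
        assert len(variant) == 1 and variant[0].pos == 51
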
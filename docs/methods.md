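# Methods

This note documents the models, conventions, and design choices behind
lrcall, in the spirit of a methods supplement: what the caller computes,
what its synthetic data does and does not emulate, and where the design was
genuinely open.

## Candidate discovery

Variations are read directly off each filtered alignment's CIGAR string
against the reference: one SNV per mismatched base inside M/=/X spans, one
insertion per interior I operator, one deletion per interior D operator.
There is no local realignment or haplotype assembly; what the aligner
reported is the evidence. Consequences of this convention:

- `=`/`X` operators are treated as match spans with the mismatch test
  re-applied, so the caller is indifferent to whether the aligner emits M
  or =/X.
- Terminal insertions (an I operator first or last among non-clip
  operations) cannot be anchored on both sides and are treated like soft
  clips: they consume query bases but produce no candidate. The read
  simulator emits the same convention, as real aligners do.
- Sites where the read or reference base is N contribute to depth but not
  to candidates.
- Adjacent mismatches stay independent SNVs; there is no MNP merging,
  consistent with reporting at most one SNV allele per locus.
- Coordinates are 0-based half-open internally; 1-based conversion and
  indel anchoring happen only at VCF serialization.

Each variation is normalized to its leftmost parsimonious representation:
shared trailing then leading allele bases are trimmed, then a pure indel is
rotated left one base at a time while the preceding reference base equals
the last base of the varying sequence. The function is idempotent and is
verified against a brute-force oracle that enumerates every parsimonious
single-replacement representation of the edited sequence and takes the
leftmost (tests and the acceptance script run this on ~1,000 random edits
per run).

Aggregation keys candidates by (contig, pos, ref, alt). Site depth is the
filtered-read depth at the variant position; deletions use the minimum
depth across the deleted span as a conservative denominator. Supporting
reads always count toward depth even if left-alignment shifted the locus to
the edge of their aligned span, preserving alt_count ≤ depth.

## Features

SNV model features: supporting-read fraction (`ratio_score`, raw fraction
in [0,1]); mean phred base quality at the site across supporting reads
(`base_qual`); mean phred within a reference distance of 5 from the site,
site included, clipped at read ends (`mean_avnqs`, an 11-position window);
mean relative in-read position, query offset over read length − 1
(`rel_pos`); and a transition indicator (`titv`, 1 for A↔G and C↔T).

Indel model features: the same supporting-read fraction; a both-strands
indicator (`strand_dir`); `mean_avnqs` over the up-to-10 flanking aligned
positions (a deleted base has no query quality, so indels use flanking
windows only; inserted bases are likewise not part of the window); Shannon
entropy in bits of the mononucleotide composition of the inserted or
deleted sequence (`seq_entropy`, range [0,2]); and the mean per-read
variation rate (`mean_var_rate`): each supporting read's total count of
emitted variations (SNVs and indel events each counting 1) divided by its
reference-aligned length, averaged over supporting reads. Normalizing by
aligned length keeps the feature on a per-base scale commensurate with its
default coefficient.

`ratio_score` is deliberately the raw supporting fraction, with no
standardization of any feature: the default coefficients are applied to raw
scales. A practical consequence, visible in every run: at typical base
qualities (~30) the quality terms alone push the linear predictor far
above zero, so nearly every candidate — including error singletons —
scores above the 0.25 reporting cutoff. Precision is enforced downstream:
the binomial genotyper assigns hom-ref to low-VAF candidates (`no_var`
filter) and the minimum-support filter (`low_cov`) catches the rest. The
score cutoff is a reporting threshold, not the precision mechanism.

## Scoring and genotyping

Scores are p = σ(intercept + Σ coef·feature) with the published default
parameters; both intercepts and coefficients can be overridden via a flat
`model.parameter = value` config file, which is also the retraining output
format. The sigmoid is computed in its numerically stable branch form.

Per locus and variant class, the candidate with the greatest supporting
read count is reported; SNV ties break on the higher score, remaining ties
on allele lexicographic order, so selection is deterministic under input
permutation.

Indel genotypes come from VAF cutoffs: ≥ 0.8 hom-alt, ≥ 0.2 het, else
hom-ref. The cutoffs are conventional values, exposed in `CallThresholds`.
SNV genotypes maximize a binomial likelihood: alt reads ~ Binomial(depth,
q) with q = ε, 0.5, 1−ε for hom-ref/het/hom-alt and ε = 0.01 per-base
error (configurable). The log-pmf is computed from lgamma directly; tests
and the acceptance script verify the argmax against scipy's binomial for
every (alt, depth ≤ 100) pair, ties resolving toward the fewer-alt
genotype. Everything is diploid, including sex chromosomes.

Since the model does not produce a calibrated genotype quality, the
reported GQ is a proxy: round(−10·log10(1 − score)) capped at 100, with
the raw score in INFO/SCORE.

## VCF and gVCF output

SNVs and indels go to separate VCF 4.2 files (pysam/htslib emission,
optional BGZF). Indels are anchored on the preceding reference base; a
variant at position 0 anchors on the following base. In gVCF mode the SNV
file carries `<NON_REF>` non-variant blocks with END, MIN_DP, and a depth
class label; blocks break at variant records and wherever the depth class
changes, with bands 0, 1–4, 5–9, 10–19, 20–49, ≥50 (the banding scheme is
this package's construction). The partition is exact by design: every
position of the processed region is covered exactly once by a block, an
SNV record, or an indel record's reference span — the indel file stays
variant-only, but indel spans are excluded from blocks so the identity
holds across the two files. Tests assert the identity position by
position.

## Retraining

Candidate site tables are compiled with the calling pipeline minus all
cutoffs, so training features are exactly calling features. Labels follow
the replicate-concordance rules; truth matching uses the same normalized
representation on both sides. Truth-set sites seen in only one replicate
are excluded entirely (neither clean positives nor clean negatives).
Train/test sets are disjoint on site keys, each with half positives and
negatives drawn half from the both-replicates pool and half from the
single-replicate pool; the default set size is 10,000 per set. Fitting
uses scikit-learn's LogisticRegression with C = 10⁶ (lbfgs, tol 1e−10):
effectively unregularized on realistic data while keeping perfectly
separable toy sets finite, and pinned so behavior does not drift with
library defaults. SNV and indel models are fit independently from
type-filtered pools.

## Synthetic data

The generator produces a seeded random reference at a requested GC
fraction (default 0.41, human-like), plants well-spaced diploid variants
(default 80 SNVs, 15 insertions, 15 deletions of 1–10 bp in 100 kb,
het fraction 0.5), and emits reads pre-aligned at their ground-truth
placement on each haplotype — CIGARs carry I/D operators where reads cross
planted indels, with terminal indels converted to clips as an aligner
would. Default read conditions: 30× coverage, 100 bp reads, base qualities
uniform on 25–40, 0.2% substitution error rate. Optional knobs inject
duplicate-flagged reads, MAPQ-0 reads, and per-read 1–3 bp indel errors
(`indel_error_rate`, default 0); the indel-error knob exists chiefly so a
replicate pair yields indel-negative training sites. Variants are spaced
at least two read lengths apart so no read crosses two variants.

What the simulator does *not* model — and hence what passing tests do not
show about real data: alignment ambiguity and mapping errors (reads are
placed at ground truth; MAPQ-0 injection is the only mapping noise),
quality-by-cycle decay, context-dependent and indel error hotspots,
structural variants, and clustered/overlapping variation. Truth-closure
results on this generator certify the pipeline's bookkeeping (extraction,
normalization, genotyping, reporting), not real-genome accuracy.

The feature-pool generator (`make_labeled_feature_pools`) samples feature
vectors from stated marginals and draws labels Bernoulli(model score). Its
default marginals are an identifiability-driven design for the
model-recovery experiment: quality features uniform on phred 2–20 place
substantial probability mass on both sides of the decision boundary, so
all five coefficients and the intercept are recoverable within tight
relative error at n = 50,000. At realistic quality values the default
model saturates near p = 1 and coefficient recovery degrades; the
marginals are therefore a power design, not an emulation of Illumina
quality profiles.

## Problem sizes and numerical choices

Tests and the acceptance script run on 20–100 kb single-contig
simulations at 30×, chosen so the whole verification cycle completes in
minutes; the pipeline itself is streaming per region and has no intrinsic
size limit, though this reference implementation keeps one region's reads
in memory and is single-threaded. Degenerate inputs are handled
explicitly: empty regions produce header-only VCFs; reads of length 1
define rel_pos = 0; a variant shifted to the contig start anchors at
position 0; zero-depth block spans report MIN_DP 0. The report cutoff
comparison is strict (score must exceed 0.25), and filter evaluation is
independent of reporting, matching the separation between whether a
variant is called and whether a called variant is filtered.

## Known limitations

Single-sample, diploid, biallelic records only (no 1/2 genotypes, no
joint calling, no phasing). No local realignment means dense or complex
variation can be misrepresented. Site-level truth concordance in
`evaluate` is representation-based, not haplotype-aware. The default
coefficients' raw-scale saturation (above) makes the score a weak ranking
signal at high base quality; retraining on data with informative quality
variation is the intended remedy.
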
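# lrcall

A single-sample germline variant caller for SNVs and small indels in
short-read sequencing data, built around logistic-regression candidate
scoring. It targets the situation where variant calls are needed quickly
and at scale on commodity hardware: no local realignment, no haplotype
assembly — candidates are read directly off CIGAR strings, normalized,
scored by a fixed-form model, genotyped, and written to VCF or gVCF. The
package also includes the retraining machinery to refit the scoring models
from a pair of technical replicates plus a truth set, and a fully seeded
synthetic-data generator so every part of the pipeline can be exercised
without downloading any reference data.

## Method

Calling runs in three stages:

1. **Read filtering.** Reads marked unmapped or duplicate, or with mapping
   quality below a threshold (default 1, so exactly MAPQ 0 is dropped), are
   excluded. Secondary, supplementary, and QC-fail records are also dropped.
2. **Candidate discovery.** Per-read sequence variations come straight from
   the alignment: SNVs are point differences inside CIGAR match-operator
   spans, insertions and deletions come from I and D operators. Every
   variation is reduced to its leftmost parsimonious representation, and
   variations with identical normalized coordinates and alleles are
   aggregated across reads into candidates with depth bookkeeping.
3. **Scoring, genotyping, reporting.** Each candidate's feature vector
   x (supporting-read fraction, base and neighborhood qualities, in-read
   position, transition indicator for SNVs; strand concordance, sequence
   entropy, and per-read variation rate for indels) is mapped to a
   probability

       p = σ(β₀ + βᵀx),   σ(z) = 1 / (1 + e⁻ᶻ)

   under a fixed-form logistic model per variant class (default β as
   published; user-overridable and retrainable). Candidates with p above a
   cutoff (default 0.25) are reported, at most one SNV and one indel allele
   per locus (greatest read support wins, SNV ties broken by score). Indels
   are genotyped by variant-allele-fraction cutoffs (het ≥ 0.2,
   hom ≥ 0.8); SNVs take the maximum-likelihood diploid genotype under a
   binomial allele model with per-base error rate ε = 0.01. Reported calls
   may carry filters (`low_cov`, `low_mapq`, `no_var`, `low_qual`); an
   empty filter set means PASS. SNVs and indels go to separate VCF 4.2
   files, optionally BGZF-compressed, and gVCF mode adds non-variant
   coverage blocks so every position of the processed region is accounted
   for exactly once.

Retraining follows the replicate-concordance recipe: compile every
candidate site with its feature values in two replicate alignments of the
same specimen; label in-region sites present in both replicates and in the
truth set as positives, in-region sites absent from the truth as negatives
(split into both-replicate and single-replicate pools); sample disjoint
train/test sets at a 1:1 positive:negative ratio (negatives half from each
pool); fit per-class logistic regressions on the raw features; and emit a
config file that drops straight back into calling.

## Worked example

Simulate a 20 kb diploid sample (10 SNVs, 2 insertions, 2 deletions, 30×
coverage, 0.2% base-error rate), then call it:

```
$ lrcall simulate --out-dir demo --ref-length 20000 --n-snv 10 --n-ins 2 \
      --n-del 2 --base-error-rate 0.002 --seed 7
$ lrcall call --bam demo/sim.bam --ref demo/sim.fa --out-prefix demo/calls --gvcf
{
  "snv_vcf": "demo/calls_snv.vcf",
  "indel_vcf": "demo/calls_indel.vcf",
  "candidates": 1211,
  "reported": 1181,
  "pass": 14,
  "pass_snv": 10,
  "pass_indel": 4,
  "titv_pass_snv": 0.6667
}
```

All 14 planted variants come back as PASS calls. The large
candidate/reported counts are expected: at typical base qualities the
default model assigns a high score to almost any candidate, including
sequencing-error singletons, so those are written as *filtered* records
(`low_cov`, `no_var`) rather than suppressed by the score cutoff —
precision lives in the filters, not in the 0.25 reporting threshold. The
Ti/Tv of 0.67 reflects the uniform substitution model of the simulator,
not the ≈2 expected of real human genomes. A PASS indel record looks like:

```
sim1  12000  .  CTAATT  C  .  PASS  SCORE=0.981798;...;SD=1;ENT=0.970951  GT:DP:AD:GQ  1/1:26:0,26:17
```

a homozygous 5 bp deletion supported by all 26 covering reads. Retraining
from two simulated replicates:

```
$ lrcall train --rep1 rep1.bam --rep2 rep2.bam --truth-vcf truth.vcf \
      --regions-bed regions.bed --ref ref.fa --out-model model.cfg --n-per-set 10000
$ lrcall call --bam sample.bam --ref ref.fa --model model.cfg --out-prefix out
```

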
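"""Retraining the candidate-scoring models from replicate call sets.

The procedure mirrors the published one: compile every candidate variant
site (no score cutoff) with its model feature values from each of two
technical-replicate alignments of the same specimen; label sites against a
truth set and high-confidence regions — positives are sites present in both
replicates, overlapping the truth variants, inside the regions; negatives
are in-region sites absent from the truth, split into those present in both
replicates and those present in only one; assemble disjoint train and test
sets of ``n_per_set`` examples each at a 1:1 positive:negative ratio, the
negatives drawn half from each negative pool; and fit an (effectively
unregularized) logistic regression per variant class on the raw features.
The fitted parameters are written in the scoring config dialect so a
retrained model drops straight back into calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score

import pysam

from .alignment_io import ReadFilterConfig, load_reference, reference_contigs
from .calling import discover_region, read_bed_regions
from .discovery import SNV, normalize_variant
from .features import features_for
from .model import (
    INDEL_FEATURES,
    SNV_FEATURES,
    LogisticModel,
    save_model_config,
)

SiteKey = Tuple[str, int, str, str]


@dataclass
class SiteRecord:
    """One candidate site with its model feature values."""

    key: SiteKey
    vtype: str
    features: Dict[str, float]


@dataclass
class TrainingSet:
    """Feature matrix with binary labels for one model fit."""

    X: np.ndarray
    y: np.ndarray
    feature_names: Tuple[str, ...]
    keys: List[SiteKey]
    seed: int

    @property
    def n_total(self) -> int:
        return len(self.y)

    @property
    def positive_fraction(self) -> float:
        return float(self.y.mean())


def compile_site_table(
    alignment_path: str,
    reference_path: str,
    regions: Optional[Sequence[Tuple[str, int, int]]] = None,
    read_cfg: Optional[ReadFilterConfig] = None,
) -> List[SiteRecord]:
    """All aggregated candidate sites with feature vectors, no cutoffs applied."""
    if regions is None:
        regions = [(name, 0, length) for name, length in reference_contigs(reference_path)]
    out: List[SiteRecord] = []
    for contig, start, end in regions:
        ref = load_reference(reference_path, contig)
        cands, _depth = discover_region(
            alignment_path, ref, (contig, start, end), read_cfg, reference_path
        )
        for c in cands:
            kind = SNV if c.vtype == SNV else "INDEL"
            out.append(SiteRecord(c.key, kind, features_for(c).as_dict()))
    return out


def load_truth_keys(truth_vcf: str, reference_path: str) -> Set[SiteKey]:
    """Site keys of a truth VCF, normalized exactly as calling normalizes."""
    keys: Set[SiteKey] = set()
    refs: Dict[str, str] = {}
    with pysam.VariantFile(truth_vcf) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            for alt in rec.alts:
                if alt.startswith("<"):
                    continue
                ref_seq = refs.setdefault(rec.contig, load_reference(reference_path, rec.contig))
                pos, r, a = normalize_variant(rec.start, rec.ref, alt, ref_seq)
                keys.add((rec.contig, pos, r, a))
    return keys


def _region_trees(regions: Sequence[Tuple[str, int, int]]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for contig, start, end in regions:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


def label_examples(
    rep1: Sequence[SiteRecord],
    rep2: Sequence[SiteRecord],
    truth_vcf: str,
    regions_bed: str,
    reference_path: str,
) -> Dict[str, List[SiteRecord]]:
    """Partition in-region sites into positive / negative_both / negative_single pools.

    Feature values for both-replicate sites come from the first replicate;
    single-replicate sites carry the features of whichever replicate saw
    them. Sites outside the regions are excluded.
    """
    regions = read_bed_regions(regions_bed)
    if not regions:
        raise ValueError(f"regions BED {regions_bed} is empty")
    truth = load_truth_keys(truth_vcf, reference_path)
    if not truth:
        raise ValueError(f"truth VCF {truth_vcf} contains no variants")
    trees = _region_trees(regions)

    def in_regions(key: SiteKey) -> bool:
        tree = trees.get(key[0])
        return bool(tree and tree.overlaps_point(key[1]))

    sites1 = {s.key: s for s in rep1}
    sites2 = {s.key: s for s in rep2}
    pools: Dict[str, List[SiteRecord]] = {
        "positive": [],
        "negative_both": [],
        "negative_single": [],
    }
    for key in sorted(set(sites1) | set(sites2)):
        if not in_regions(key):
            continue
        site = sites1.get(key) or sites2[key]
        both = key in sites1 and key in sites2
        if key in truth:
            if both:
                pools["positive"].append(site)
            # truth sites seen in one replicate only are neither clean
            # positives nor clean negatives: excluded
        elif both:
            pools["negative_both"].append(site)
        else:
            pools["negative_single"].append(site)
    return pools


def sample_train_test(
    pools: Dict[str, List[SiteRecord]],
    feature_names: Tuple[str, ...],
    n_per_set: int = 10_000,
    seed: int = 0,
) -> Tuple[TrainingSet, TrainingSet]:
    """Disjoint train/test sets: half positive, negatives split across pools.

    Each set holds ``n_per_set`` examples — ``n/2`` positives and ``n/2``
    negatives, the latter drawn half from the both-replicates pool and half
    from the single-replicate pool. Sampling is seeded and without
    replacement across the two sets.
    """
    n_pos = n_per_set // 2
    n_nb = n_per_set // 4
    n_ns = n_per_set - n_pos - n_nb
    need = {"positive": 2 * n_pos, "negative_both": 2 * n_nb, "negative_single": 2 * n_ns}
    for pool, n_needed in need.items():
        if len(pools.get(pool, [])) < n_needed:
            raise ValueError(
                f"pool {pool!r} has {len(pools.get(pool, []))} sites; "
                f"{n_needed} required for two disjoint sets of {n_per_set}"
            )
    rng = np.random.default_rng(seed)
    halves: Dict[str, Tuple[List[SiteRecord], List[SiteRecord]]] = {}
    for pool, n_needed in need.items():
        idx = rng.choice(len(pools[pool]), size=n_needed, replace=False)
        chosen = [pools[pool][i] for i in idx]
        halves[pool] = (chosen[: n_needed // 2], chosen[n_needed // 2 :])

    def build(part: int) -> TrainingSet:
        sites = halves["positive"][part] + halves["negative_both"][part] + halves["negative_single"][part]
        labels = [1] * len(halves["positive"][part]) + [0] * (
            len(halves["negative_both"][part]) + len(halves["negative_single"][part])
        )
        order = rng.permutation(len(sites))
        X = np.array(
            [[sites[i].features[name] for name in feature_names] for i in order]
        )
        y = np.array([labels[i] for i in order])
        return TrainingSet(X, y, feature_names, [sites[i].key for i in order], seed)

    train, test = build(0), build(1)
    if set(train.keys) & set(test.keys):
        raise AssertionError("train/test overlap on site keys")
    return train, test


def fit_model(
    train: TrainingSet,
    test: Optional[TrainingSet],
    model_kind: str,
    C: float = 1e6,
) -> Tuple[LogisticModel, Dict[str, float]]:
    """Fit a logistic model on raw features; report held-out metrics.

    A very weak ridge penalty (C=1e6) keeps perfectly separable inputs
    finite while leaving realistic fits effectively unregularized.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set contains a single label; cannot fit")
    expected = SNV_FEATURES if model_kind == "SNV" else INDEL_FEATURES
    if train.feature_names != expected:
        raise ValueError(
            f"{model_kind} model expects features {expected}, got {train.feature_names}"
        )
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(train.X, train.y)
    model = LogisticModel(
        model_kind,
        float(clf.intercept_[0]),
        {name: float(c) for name, c in zip(train.feature_names, clf.coef_[0])},
    )
    metrics: Dict[str, float] = {}
    if test is not None:
        prob = clf.predict_proba(test.X)[:, 1]
        metrics["accuracy"] = float(accuracy_score(test.y, prob >= 0.5))
        metrics["auc"] = float(roc_auc_score(test.y, prob))
    return model, metrics


def run_train(
    rep1_bam: str,
    rep2_bam: str,
    truth_vcf: str,
    regions_bed: str,
    reference_path: str,
    out_model: str,
    n_per_set: int = 10_000,
    seed: int = 0,
    read_cfg: Optional[ReadFilterConfig] = None,
) -> Dict[str, Dict[str, float]]:
    """Full retraining: compile, label, sample, fit both models, write config."""
    regions = read_bed_regions(regions_bed)
    rep1 = compile_site_table(rep1_bam, reference_path, regions, read_cfg)
    rep2 = compile_site_table(rep2_bam, reference_path, regions, read_cfg)
    pools = label_examples(rep1, rep2, truth_vcf, regions_bed, reference_path)

    models = {}
    report: Dict[str, Dict[str, float]] = {}
    for kind, names in (("SNV", SNV_FEATURES), ("INDEL", INDEL_FEATURES)):
        want = SNV if kind == "SNV" else "INDEL"
        typed = {pool: [s for s in sites if s.vtype == want] for pool, sites in pools.items()}
        train, test = sample_train_test(typed, names, n_per_set=n_per_set, seed=seed)
        model, metrics = fit_model(train, test, kind)
        models[kind] = model
        report[kind] = metrics
    save_model_config(out_model, models["SNV"], models["INDEL"])
    return report
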
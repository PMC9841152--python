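import numpy as np
import pytest

from lrcall.calling import read_bed_regions
from lrcall.model import SNV_FEATURES, LogisticModel, load_model_config
from lrcall.retrain import (
    SiteRecord,
    TrainingSet,
    compile_site_table,
    fit_model,
    label_examples,
    run_train,
    sample_train_test,
)
from lrcall.simulate import make_labeled_feature_pools


def _site(key, vtype="SNV", ratio=0.5):
    feats = {"ratio_score": ratio, "base_qual": 30.0, "mean_avnqs": 30.0,
             "rel_pos": 0.5, "titv": 1.0}
    return SiteRecord(key, vtype, feats)


def _pools(n_pos, n_nb, n_ns):
    rng = np.random.default_rng(0)
    def mk(tag, n):
        return [_site(("c", 1000 * i, "A", tag), ratio=float(rng.random())) for i in range(n)]
    return {
        "positive": mk("G", n_pos),
        "negative_both": mk("T", n_nb),
        "negative_single": mk("C", n_ns),
    }


class TestSampling:
    def test_set_composition_and_disjointness(self):
        pools = _pools(60, 30, 30)
        train, test = sample_train_test(pools, SNV_FEATURES, n_per_set=40, seed=1)
        for ts in (train, test):
            assert ts.n_total == 40
            assert ts.positive_fraction == 0.5
        assert not set(train.keys) & set(test.keys)

    def test_seeded_reproducibility(self):
        pools = _pools(60, 30, 30)
        a = sample_train_test(pools, SNV_FEATURES, n_per_set=40, seed=7)
        b = sample_train_test(pools, SNV_FEATURES, n_per_set=40, seed=7)
        assert np.array_equal(a[0].X, b[0].X) and np.array_equal(a[0].y, b[0].y)

    def test_shortfall_reports_required_vs_available(self):
        pools = _pools(10, 30, 30)
        with pytest.raises(ValueError, match="positive.*10.*40"):
            sample_train_test(pools, SNV_FEATURES, n_per_set=40, seed=0)

    def test_negatives_split_between_pools(self):
        pools = _pools(60, 30, 30)
        train, _ = sample_train_test(pools, SNV_FEATURES, n_per_set=40, seed=1)
        tags = [k[3] for k, label in zip(train.keys, train.y) if label == 0]
        assert sum(t == "T" for t in tags) == 10
        assert sum(t == "C" for t in tags) == 10


class TestLabeling:
    def test_pools_follow_replicate_and_truth_rules(self, replicate_pair):
        d1, d2 = replicate_pair
        regs = read_bed_regions(d1["regions_bed"])
        r1 = compile_site_table(d1["bam"], d1["fasta"], regs)
        r2 = compile_site_table(d2["bam"], d2["fasta"], regs)
        pools = label_examples(r1, r2, d1["truth_vcf"], d1["regions_bed"], d1["fasta"])

        truth_keys = {
            ("sim1", v.pos, v.ref_allele, v.alt_allele) for v in d1["variants"]
        }
        keys1, keys2 = {s.key for s in r1}, {s.key for s in r2}
        for s in pools["positive"]:
            assert s.key in truth_keys and s.key in keys1 and s.key in keys2
        for s in pools["negative_both"]:
            assert s.key not in truth_keys and s.key in keys1 and s.key in keys2
        for s in pools["negative_single"]:
            assert s.key not in truth_keys
            assert (s.key in keys1) != (s.key in keys2)

    def test_pools_are_disjoint(self, replicate_pair):
        d1, d2 = replicate_pair
        regs = read_bed_regions(d1["regions_bed"])
        r1 = compile_site_table(d1["bam"], d1["fasta"], regs)
        r2 = compile_site_table(d2["bam"], d2["fasta"], regs)
        pools = label_examples(r1, r2, d1["truth_vcf"], d1["regions_bed"], d1["fasta"])
        sets = [{s.key for s in pool} for pool in pools.values()]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_compile_is_deterministic(self, clean_dataset):
        t1 = compile_site_table(clean_dataset["bam"], clean_dataset["fasta"])
        t2 = compile_site_table(clean_dataset["bam"], clean_dataset["fasta"])
        assert [(s.key, s.features) for s in t1] == [(s.key, s.features) for s in t2]

    def test_planted_sites_all_compiled(self, clean_dataset):
        table = {s.key for s in compile_site_table(clean_dataset["bam"], clean_dataset["fasta"])}
        for v in clean_dataset["variants"]:
            assert ("sim1", v.pos, v.ref_allele, v.alt_allele) in table


class TestFitting:
    def test_recovers_simulated_coefficients(self):
        m = LogisticModel.snv_default()
        X, y, names = make_labeled_feature_pools(m, 50_000, seed=0)
        fitted, _ = fit_model(TrainingSet(X, y, names, [], 0), None, "SNV")
        for name, coef in m.coefficients.items():
            est = fitted.coefficients[name]
            assert np.sign(est) == np.sign(coef)
            assert abs(est - coef) / abs(coef) < 0.25, name
        assert abs(fitted.intercept - m.intercept) / abs(m.intercept) < 0.25

    def test_no_signal_gives_chance_accuracy(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(20_000, 5))
        y = rng.integers(0, 2, size=20_000)
        train = TrainingSet(X[:10_000], y[:10_000], SNV_FEATURES, [], 0)
        test = TrainingSet(X[10_000:], y[10_000:], SNV_FEATURES, [], 0)
        _, metrics = fit_model(train, test, "SNV")
        assert abs(metrics["accuracy"] - 0.5) < 0.03

    def test_separable_data_stays_finite(self):
        X = np.vstack([np.zeros((50, 5)), np.ones((50, 5))])
        y = np.array([0] * 50 + [1] * 50)
        fitted, _ = fit_model(TrainingSet(X, y, SNV_FEATURES, [], 0), None, "SNV")
        assert all(np.isfinite(v) for v in fitted.coefficients.values())

    def test_single_label_fatal(self):
        X = np.zeros((10, 5))
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError, match="single label"):
            fit_model(TrainingSet(X, y, SNV_FEATURES, [], 0), None, "SNV")


class TestEndToEnd:
    def test_retrained_config_loads_and_calls(self, replicate_pair, tmp_path):
        d1, d2 = replicate_pair
        out_model = str(tmp_path / "model.cfg")
        report = run_train(
            d1["bam"], d2["bam"], d1["truth_vcf"], d1["regions_bed"], d1["fasta"],
            out_model, n_per_set=16, seed=0,
        )
        assert set(report) == {"SNV", "INDEL"}
        assert report["SNV"]["auc"] > 0.9  # planted variants separate easily
        snv, indel = load_model_config(out_model)
        assert snv.model_kind == "SNV" and indel.model_kind == "INDEL"

        from lrcall.calling import run_call

        _, _, summary = run_call(
            d1["bam"], d1["fasta"], str(tmp_path / "out"), model_config=out_model
        )
        assert summary.n_pass > 0

    def test_seeded_run_twice_identical_config(self, replicate_pair, tmp_path):
        d1, d2 = replicate_pair
        p1, p2 = str(tmp_path / "m1.cfg"), str(tmp_path / "m2.cfg")
        for p in (p1, p2):
            run_train(d1["bam"], d2["bam"], d1["truth_vcf"], d1["regions_bed"],
                      d1["fasta"], p, n_per_set=16, seed=3)
        assert open(p1).read() == open(p2).read()
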
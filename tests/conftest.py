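import pytest

from lrcall.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Noiseless 20 kb diploid simulation at 30x with 23 planted variants."""
    cfg = SimConfig(
        ref_length=20_000,
        n_snv=15,
        n_ins=4,
        n_del=4,
        base_error_rate=0.0,
        duplicate_fraction=0.0,
        mapq0_fraction=0.0,
        seed=3,
    )
    out = simulate_dataset(cfg, str(tmp_path_factory.mktemp("clean")))
    out["cfg"] = cfg
    return out


@pytest.fixture(scope="session")
def replicate_pair(tmp_path_factory):
    """Two noisy technical replicates sharing one reference and truth set."""
    base = dict(
        ref_length=60_000,
        n_snv=60,
        n_ins=15,
        n_del=15,
        base_error_rate=0.02,
        indel_error_rate=0.1,
        seed=11,
    )
    d1 = simulate_dataset(
        SimConfig(**base, read_seed=101), str(tmp_path_factory.mktemp("rep1"))
    )
    d2 = simulate_dataset(
        SimConfig(**base, read_seed=202), str(tmp_path_factory.mktemp("rep2"))
    )
    return d1, d2
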
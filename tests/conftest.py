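import pytest

from isocollapse.model import ExonChain, GenomicInterval
from isocollapse.simulate import SimConfig, build_truth, simulate_samples


def chain(*exons, chrom="chr1", strand="+"):
    """Shorthand for building exon chains in tests."""
    return ExonChain([GenomicInterval(chrom, s, e, strand) for s, e in exons])


@pytest.fixture(scope="session")
def truth():
    return build_truth(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_sim(truth):
    cfg = SimConfig(seed=1, n_samples=50)
    return cfg, simulate_samples(truth, cfg)


@pytest.fixture(scope="session")
def clean_sim(truth):
    """No jitter, no dropout: every sample reproduces the truth structurally."""
    cfg = SimConfig(seed=3, n_samples=12, utr_jitter_bp=0, dropout=0.0, count_depth=2000)
    return cfg, simulate_samples(truth, cfg)
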
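import numpy as np
import pytest

from locusdrift.sim import SimConfig, SimGene, default_config, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast scenario for unit tests: 6-gene locus, 900-nt genes."""
    base = dict(
        locus=tuple(SimGene(f"G{i+1:02d}", length_nt=900) for i in range(6)),
        flank_genes=2,
        flank_length_nt=900,
        inversion_interval=(1, 4),
        paralog_of="G03",
        coverage=6.0,
        read_len=100,
        err_rate=0.002,
    )
    base.update(overrides)
    return default_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_sim():
    """One forced disruption on the galliform stem branch, small genes."""
    cfg = small_config(seed=11)
    return simulate(cfg)
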
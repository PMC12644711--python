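import pytest

import amplijoin as aj


@pytest.fixture(scope="session")
def junction():
    """Standard synthetic two-DSB junction with planted repeats (flank 60)."""
    return aj.random_junction(seed=11, flank=60, repeats=aj.DEFAULT_REPEATS)


@pytest.fixture(scope="session")
def clean_sim(junction):
    """Error-free simulated library under the default category mix."""
    cfg = aj.SimConfig(n_reads=3000, seed=5, substitution_error_rate=0.0)
    reads, truth = aj.simulate_reads(junction, cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def clean_calls(junction, clean_sim):
    _, reads, _ = clean_sim
    return aj.classify_all(reads, junction)
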
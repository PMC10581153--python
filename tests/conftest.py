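import numpy as np
import pytest

from paleofv import simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def templates():
    return simulate.default_templates(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-genome cohort: 2 shared + 1 private insertion per genome."""
    split = 2.8e6
    events = [
        simulate.InsertionEvent(12e6, "fv_a"),
        simulate.InsertionEvent(8e6, "fv_a"),
        simulate.InsertionEvent(1.0e6, "fv_b", "genomeA"),
        simulate.InsertionEvent(1.2e6, "fv_b", "genomeB"),
    ]
    cfg = simulate.SimConfig(genome_length=120_000, split_time_years=split,
                             insertion_events=events, seed=11,
                             min_locus_spacing=18_000)
    return simulate.simulate_cohort(cfg)
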
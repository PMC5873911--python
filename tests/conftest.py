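import numpy as np
import pytest
from hypothesis import settings

import tumorgi as tgi

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    # 3 Mb genome: fast enough for unit tests, large enough for statistics
    return tgi.SimConfig(
        seed=11,
        chrom_lengths={"X": 800_000, "2L": 900_000, "2R": 700_000, "3R": 600_000},
        y_length=100_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return tgi.simulate_genome(small_config)


@pytest.fixture(scope="session")
def default_genome():
    return tgi.simulate_genome(tgi.SimConfig(seed=7))
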
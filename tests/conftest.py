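import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # ng86_oracle

from ltrsurvey.detect import detect
from ltrsurvey.simulate import SimulationConfig, simulate_genome

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=30,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def small_sim():
    """A 600 kb genome with 8 planted elements and 4 solos."""
    cfg = SimulationConfig(genome_length=600_000, n_full_elements=8,
                           n_solo=4, seed=5)
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def small_detection(small_sim):
    """Detector output on the session genome."""
    _, genome, _ = small_sim
    return detect(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
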
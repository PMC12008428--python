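import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from octomics.features import ExtractionConfig, extract_table
from octomics.synthetic import generate_cohort, high_separation_config


@pytest.fixture(scope="session")
def small_cohort():
    """24-eye high-separation synthetic cohort (6 eyes per phenotype)."""
    return generate_cohort(high_separation_config(n_eyes=24, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_table(small_cohort, ExtractionConfig.fast())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_roi(rng, max_side=12, ng_levels=6, density=0.8):
    """Random small discretizable patch + mask for oracle suites."""
    h, w = rng.integers(5, max_side + 1, 2)
    raw = rng.integers(0, ng_levels * 10, (h, w)).astype(float)
    mask = rng.random((h, w)) < density
    if mask.sum() < 16:
        mask[:4, :4] = True
    return raw, mask
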
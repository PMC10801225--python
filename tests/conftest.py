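"""Shared fixtures: a small synthetic cohort and a trained small pipeline.

Everything is generated from fixed seeds at session start; no data files
are shipped.  The small cohort (60/80/40 subjects) keeps every training
run under a couple of seconds while still producing a connected
population graph and a usable classifier.
"""

import numpy as np
import pytest

from popgraphx.pipeline import run_pipeline
from popgraphx.synthetic_cohort import default_spec, generate_cohort

SMALL_N = {"NC": 60, "MCI": 80, "AD": 40}
SMALL_SEED = 7


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_spec(), seed=SMALL_SEED, n_override=SMALL_N)


@pytest.fixture(scope="session")
def small_pipeline():
    return run_pipeline(seed=SMALL_SEED, n_override=SMALL_N)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
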
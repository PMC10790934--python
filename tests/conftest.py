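import numpy as np
import pytest

import raseeg as rg
from raseeg.pipeline import cohort_band_powers


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort at desk scale: 4 participants x 1 task x 1200 frames."""
    cfg = rg.SimulationConfig(
        n_participants=4, tasks_per_participant=1, frames_per_task=1200,
        baseline_duration=30.0, seed=20260901)
    return rg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Normalized band-power table for the null cohort (ASR skipped for
    speed; the ASR unit tests cover it separately)."""
    return cohort_band_powers(small_cohort, asr_cutoff=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
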
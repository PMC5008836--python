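import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

from loudtone import GeneratorConfig, SyntheticCohort

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale generator config (fewer subjects, default conditions)."""
    return GeneratorConfig(n_subjects=4)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """A 3-subject cohort with every source of variability off."""
    cfg = GeneratorConfig(n_subjects=3).noise_free()
    return SyntheticCohort(cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_cell_table(rng, n_subjects=6, scale=1.0):
    """A random complete 2x2 within-subject table."""
    rows = []
    for s in range(n_subjects):
        off = rng.normal(0, 2)
        for b in ("pure_tone", "white_noise"):
            for p in ("sitting", "supine"):
                rows.append({"subject_id": f"s{s:02d}", "bandwidth": b,
                             "posture": p,
                             "value": off + rng.normal(0, scale)})
    return pd.DataFrame(rows)
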
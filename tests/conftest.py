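import pandas as pd
import pytest

from methstab.config import SimConfig
from methstab.icc import compute_scenario_icc
from methstab.scenarios import SCENARIOS
from methstab.simulate import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort shared across tests: 16 subjects, 60 probes."""
    return generate_cohort(SimConfig(n_subjects_per_group=8, n_probes=60, seed=11))


@pytest.fixture(scope="session")
def small_icc_tables(small_cohort):
    """Adjusted ICC tables for two scenarios of the small cohort."""
    c = small_cohort
    tables = [
        compute_scenario_icc(c.beta, c.sheet, SCENARIOS[name], adjust=True)
        for name in ("NoStressT1-2", "StressT1-2")
    ]
    return pd.concat(tables, ignore_index=True)
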
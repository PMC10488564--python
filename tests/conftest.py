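import dataclasses

import numpy as np
import pytest

from iodect import PhantomConfig, TumorGroup, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A fast phantom config on a reduced grid for pipeline-level tests."""
    return PhantomConfig(
        grid_shape=(32, 32, 20),
        spacing=(1.5, 1.5, 2.0),
        tumor_radius_range=(7.0, 11.0),
        seed=42,
        cases_per_class={
            TumorGroup.LOW_RISK_THYMOMA: 12,
            TumorGroup.HIGH_RISK_THYMOMA: 10,
            TumorGroup.THYMIC_CARCINOMA: 8,
        },
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def calibration_cohort():
    """200 cases/class at default settings: the study-condition calibration run."""
    cfg = dataclasses.replace(
        PhantomConfig(seed=2024), cases_per_class={g: 200 for g in TumorGroup}
    )
    _, table = generate_cohort(cfg)
    return table


def table_to_arrays(table):
    """Reconstruct per-case (score, outcome) arrays from 2x2 counts."""
    scores = np.array([1] * (table.a + table.b) + [0] * (table.c + table.d))
    outcome = np.array(
        [1] * table.a + [0] * table.b + [1] * table.c + [0] * table.d
    )
    return scores, outcome
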
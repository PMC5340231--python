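import numpy as np
import pandas as pd
import pytest

from nbx import (
    CellLineSimConfig,
    CohortSimConfig,
    QPCRSimConfig,
    simulate_cellline_experiment,
    simulate_patient_cohort,
    simulate_qpcr_plate,
)


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient, 60-gene cohort with 8 planted prognostic genes."""
    return simulate_patient_cohort(
        CohortSimConfig(n_patients=300, n_genes=60, n_prognostic=8, seed=11)
    )


@pytest.fixture(scope="session")
def small_cellline():
    """6-line hypoxia experiment with 10 planted responsive genes."""
    return simulate_cellline_experiment(
        CellLineSimConfig(
            n_lines=6, n_genes=40, n_hypoxia_responsive=10, seed=12
        )
    )


@pytest.fixture(scope="session")
def noiseless_plate():
    return simulate_qpcr_plate(
        QPCRSimConfig(
            genes=("HK2", "PGK1", "ENO1"),
            true_log2_fold=(3.0, 2.0, -1.0),
            ct_noise_sd=0.0,
            seed=13,
        )
    )


@pytest.fixture
def toy_survival():
    """Six patients with a mix of events and censoring."""
    return pd.DataFrame(
        {
            "os_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "os_event": [1, 1, 0, 1, 0, 1],
        }
    )
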
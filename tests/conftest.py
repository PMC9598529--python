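import numpy as np
import pandas as pd
import pytest

from composcore import (
    CohortDataset,
    GeneratorConfig,
    default_battery,
    generate_cohort,
)


@pytest.fixture
def battery():
    return default_battery()


@pytest.fixture
def crossover_cohort():
    """9 subjects x 2 conditions from the calibrated generator (18 records)."""
    return generate_cohort(GeneratorConfig(n_subjects=9, seed=42))


@pytest.fixture
def crossover_csv(tmp_path, crossover_cohort):
    path = tmp_path / "cohort.csv"
    crossover_cohort.table.to_csv(path, index=False)
    return path


def make_cohort(values: np.ndarray, battery=None) -> CohortDataset:
    """Wrap an (n_subjects*2) x n_measures value matrix as a cohort,
    alternating MK/MCK rows per subject."""
    battery = battery if battery is not None else default_battery()
    n = values.shape[0]
    assert n % 2 == 0
    rows = []
    for i in range(n):
        rows.append(
            {
                "subject": f"S{i // 2 + 1:03d}",
                "condition": "MK" if i % 2 == 0 else "MCK",
                **{m.name: values[i, k] for k, m in enumerate(battery)},
            }
        )
    return CohortDataset(
        table=pd.DataFrame(rows), battery=battery, condition_levels=("MK", "MCK")
    )
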
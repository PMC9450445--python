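import numpy as np
import pytest

from bavscreen.cohort_model import GenotypeMatrix, fixtures


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def table3_cohort(fx):
    """Candidate-table variants with dosages reconstructed so each variant's
    discovery carrier count equals its printed Cases value."""
    records = [row.variant for row in fx.table3]
    n = fx.n_discovery
    dosage = np.zeros((n, len(records)), dtype=np.int8)
    for j, row in enumerate(fx.table3):
        dosage[: row.case_count, j] = 1
    matrix = GenotypeMatrix(
        [f"BAV{i + 1:02d}" for i in range(n)],
        [v.key for v in records],
        dosage,
        [v.gene for v in records],
    )
    return records, matrix


@pytest.fixture(scope="session")
def fixture_cohort():
    from bavscreen.simcohort import table_fixture_cohort

    return table_fixture_cohort()
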
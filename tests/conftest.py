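import numpy as np
import pandas as pd
import pytest

from neoresponse.simulate import CohortConfig, generate_cohort

#: 19 evaluable % viable-tumor values: 3 complete regressions, 2 in (0,10),
#: 4 in [10,50) and 10 at >= 50 — the count structure of a small phase-II
#: resection cohort.
TABLE2_VIABLE = [0, 0, 0, 5, 8, 12, 20, 30, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100]


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    return generate_cohort(CohortConfig(seed=42))


def clonotype_table(freqs, prefix="CASSA"):
    """Build a normalized clonotype table from a frequency vector."""
    freqs = np.asarray(freqs, dtype=float)
    counts = np.rint(freqs * 1e7).astype(np.int64)
    return pd.DataFrame(
        {
            "cdr3aa": [f"{prefix}{i:04d}F" for i in range(len(freqs))],
            "v_segment": "TRBV20-1",
            "j_segment": "TRBJ2-5",
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )
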
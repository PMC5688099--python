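import numpy as np
import pandas as pd
import pytest

from raceblend.synthetic import default_scenario


@pytest.fixture(scope="session")
def default_data():
    """One generated realization of the default three-cohort scenario."""
    return default_scenario().generate(seed=1)


@pytest.fixture()
def patients_small():
    """A tiny hand-built two-group clinical table (deterministic)."""
    rng = np.random.default_rng(7)
    n = 40
    rows = []
    for i in range(n):
        asian = i < n // 2
        rows.append(
            {
                "sample_id": f"S{i:02d}",
                "cohort": "Chinese" if asian else "Caucasian",
                "age": float(50 + rng.integers(0, 20)),
                "gender": "male" if rng.random() < 0.8 else "female",
                "stage": str(rng.choice(["I", "II", "III", "IV"])),
                "smoking": str(rng.choice(["ever", "never", "unknown"])),
                "alcohol": str(rng.choice(["yes", "no", "unknown"])),
                "os_months": float(rng.uniform(1, 60)),
                "os_event": int(rng.random() < 0.5),
                "group": "Asian" if asian else "Caucasian",
            }
        )
    return pd.DataFrame(rows)
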
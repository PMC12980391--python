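import numpy as np
import pandas as pd
import pytest

from acutephys.core import FeatureTable
from acutephys.simulate import SimScenario, default_moments, simulate_design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_meta():
    """Three-arm metadata: 2 participants per group at pre/post10."""
    rows = []
    for g in ("EE", "RE", "CON"):
        for i in range(2):
            part = f"{g}{i}"
            for tp in ("pre", "post10"):
                rows.append((f"{part}_{tp}", part, g, tp, "F" if i == 0 else "M"))
    return pd.DataFrame(
        rows, columns=["sample_id", "participant_id", "group", "timepoint", "sex"]
    )


@pytest.fixture(scope="session")
def blood_design():
    """A realized blood-sized design (EE + CON, profiles, 5 timepoints)."""
    scenario = SimScenario(n_per_subgroup=8)
    meta = simulate_design(scenario, np.random.default_rng(7))
    return scenario, meta


def make_table(values: np.ndarray, ome="metabolite_intensity", samples=None, features=None):
    f, s = values.shape
    return FeatureTable(
        pd.DataFrame(
            values,
            index=features or [f"f{i}" for i in range(f)],
            columns=samples or [f"s{j}" for j in range(s)],
        ),
        ome,
    )
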
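import numpy as np
import pandas as pd
import pytest

from sorpkit import simulate


def make_grid(series_by_channel: dict, patient_id: str = "P0") -> pd.DataFrame:
    """Single-patient grid from {channel: {hour: value}} dicts."""
    n_h = max(max(d) for d in series_by_channel.values()) + 1
    idx = pd.MultiIndex.from_product([[patient_id], range(n_h)],
                                     names=["patient_id", "hour"])
    frame = pd.DataFrame(index=idx, columns=list(series_by_channel), dtype=float)
    for ch, d in series_by_channel.items():
        for h, v in d.items():
            frame.loc[(patient_id, h), ch] = v
    return frame


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient synthetic cohort shared across tests (hours domain)."""
    return simulate.generate_cohort(simulate.CohortSpec(n_patients=120), seed=11)


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    from sorpkit import phenotype
    return phenotype.label_cohort(small_cohort.in_hours())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
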
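import numpy as np
import pandas as pd
import pytest

from pfcnet import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_config() -> syn.SimCohortConfig:
    return syn.SimCohortConfig(seed=1, noise_cv=0.0, subject_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config) -> pd.DataFrame:
    """Default profiles/couplings with all randomness switched off."""
    return syn.generate_dialysate(noiseless_config)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return syn.generate_dialysate(syn.SimCohortConfig(seed=7))


@pytest.fixture()
def toy_dialysate() -> pd.DataFrame:
    """Hand-built 16-sample table for one subject and one neurotransmitter."""
    times = -60.0 + 20.0 * np.arange(16)
    ks = np.repeat([4, 30, 60, 120], 4)
    conc = np.array(
        [2.0, 2.0, 2.0, 2.0,  # baseline -> basal 2.0
         4.0, 6.0, 3.0, 2.0,
         5.0, 8.0, 4.0, 2.0,
         6.0, 10.0, 7.0, 3.0]
    )
    return pd.DataFrame(
        {
            "subject": "control_01",
            "group": "control",
            "sample_index": np.arange(1, 17),
            "time_min": times,
            "k_mM": ks,
            "neurotransmitter": "DA",
            "conc_nM": conc,
        }
    )
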
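import numpy as np
import pandas as pd
import pytest

import microtempo as mt


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic community reused across read-only tests."""
    cfg = mt.SynthConfig(n_asvs=40, seed=7, reps_min=3, reps_max=3)
    return mt.generate_dataset(cfg)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        {"s1": [6, 3, 1], "s2": [1, 3, 6], "s3": [2, 2, 2], "s4": [5, 0, 5]},
        index=["A1", "A2", "A3"],
    )


@pytest.fixture()
def toy_metadata(toy_counts):
    return pd.DataFrame(
        {
            "habitat": "rhizosphere",
            "domain": "bacteria_archaea",
            "season": ["winter", "winter", "summer", "summer"],
            "year": [2018, 2018, 2018, 2018],
            "date": pd.to_datetime(
                ["2018-02-19", "2018-02-19", "2018-08-22", "2018-08-22"]
            ),
            "genotype": ["G01", "G02", "G01", "G02"],
            "species": "P_trichocarpa",
            "block": [1, 2, 1, 2],
        },
        index=toy_counts.columns,
    )
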
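import io

import numpy as np
import pandas as pd
import pytest

from rarethin.survey import SurveyDataset
from rarethin.synthetic import build_scenario, single_sighting_fixture


@pytest.fixture
def tiny_dataset() -> SurveyDataset:
    """Two segments, one single-group sighting."""
    seg = pd.DataFrame(
        {
            "segment_id": ["S1", "S2"],
            "transect_id": ["T1", "T1"],
            "day_index": [0, 0],
            "length_km": [10.0, 10.0],
            "protocol": ["line", "line"],
            "half_width_km": [0.2, 0.2],
            "sst": [15.0, 17.0],
        }
    )
    sig = pd.DataFrame(
        {
            "sighting_id": ["G1"],
            "segment_id": ["S1"],
            "taxon": ["dolphin"],
            "group_size": [3],
        }
    )
    return SurveyDataset(seg, sig, schema=("sst",))


@pytest.fixture(scope="session")
def dolphin_fixture() -> SurveyDataset:
    """3,320 segments with 277 single-group sightings on distinct segments."""
    return single_sighting_fixture(3320, 277, taxon="dolphins", seed=0)


@pytest.fixture(scope="session")
def small_scenario():
    """Small narrow-habitat scenario shared by model-level tests."""
    return build_scenario(
        "narrow",
        seed=11,
        n_segments=900,
        target_sightings=320,
        resolution=0.3,
        days=(0, 6, 180, 186),
    )


NARROW_VARS = ("depth", "sst_mean", "sst_grad", "ssh_mean")
BROAD_VARS = ("sst_mean", "sst_var", "ssh_mean", "ssh_sd")
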
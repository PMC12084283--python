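import warnings

import numpy as np
import pandas as pd
import pytest

from mastpheno.process import ProcessParams
from mastpheno.synthetic import (
    ClimateConfig,
    StudyDesign,
    default_archetypes,
    generate_climate,
    generate_study,
)

warnings.filterwarnings("ignore", message="cv_metric: zero-mean series")


@pytest.fixture(scope="session")
def climate():
    """Default-window weekly forcing (2000-2023), fixed seed."""
    return generate_climate(seed=1)


@pytest.fixture(scope="session")
def small_study():
    """One resource-matcher species, one site, 4 trees, no deaths."""
    design = StudyDesign(
        species_sites={"rmspec": ["Sk"]}, extra_pair=None, n_per_site=4, death_prob=0.0
    )
    arch = default_archetypes()["resource_matcher"]
    obs, roster, cl, truth = generate_study(
        design, {"rmspec": "resource_matcher"}, {"resource_matcher": arch}, seed=11
    )
    return obs, roster, cl, truth, arch


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (18+ species, 290 trees)."""
    return generate_study(seed=2)


@pytest.fixture
def obs_rows():
    """Tiny hand-written observation table (3 rows, valid)."""
    return pd.DataFrame(
        {
            "tree_id": ["t1", "t1", "t2"],
            "species": ["acanig"] * 3,
            "site": ["Nk"] * 3,
            "date": ["2016-01-15", "2016-02-15", "2016-01-15"],
            "phenophase": ["flower", "flower", "fruit"],
            "score": [0, 3, 2],
        }
    )
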
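"""Shared fixtures: small seeded synthetic atlases and queries.

The small scenario (4 types x 6 metacells x 400 genes at 20k UMIs) keeps
unit tests fast; acceptance tests build their own full-scale scenarios.
"""

import numpy as np
import pytest

from atlasproj import SyntheticScenario, generate_atlas, generate_query


SMALL = dict(
    n_types=4,
    metacells_per_type=6,
    n_genes=400,
    n_feature_genes=120,
    markers_per_type=40,
    umis_per_metacell=20_000,
    min_feature_mean_umis=10.0,
    n_query_metacells=12,
    seed=7,
)


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(**SMALL)


@pytest.fixture(scope="session")
def small_atlas(small_scenario):
    return generate_atlas(small_scenario)


@pytest.fixture(scope="session")
def small_query(small_scenario, small_atlas):
    return generate_query(small_scenario, small_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
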
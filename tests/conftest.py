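import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from plonet import InteractionNetwork, NetworkCovariates, PlantTraitTable

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("plonet").setLevel(logging.ERROR)


def make_net(weights, network_id="net") -> InteractionNetwork:
    w = np.asarray(weights, dtype=float)
    return InteractionNetwork(
        network_id=network_id,
        plant_ids=tuple(f"p{i}" for i in range(w.shape[0])),
        pollinator_ids=tuple(f"a{j}" for j in range(w.shape[1])),
        weights=w,
    )


def random_net(rng, n_plants, n_pollinators, high=5) -> InteractionNetwork:
    """Random integer network with no empty rows/columns."""
    while True:
        w = rng.integers(0, high, size=(n_plants, n_pollinators)).astype(float)
        if (w.sum(axis=1) > 0).all() and (w.sum(axis=0) > 0).all():
            return make_net(w)


@pytest.fixture
def identity3():
    return make_net(np.eye(3))


@pytest.fixture
def trait_table():
    return PlantTraitTable(pd.DataFrame({
        "species": ["p0", "p1", "p2", "p3", "p4", "p5", "p6"],
        "ploidy": ["polyploid", "polyploid", "diploid", "diploid",
                   "unknown", "unknown", "unknown"],
        "mating": ["self_compatible", "unknown", "self_incompatible",
                   "unknown", "unknown", "unknown", "unknown"],
        "restrictiveness": ["high", "low", "moderate", "unrestrictive",
                            "unknown", "unknown", "unknown"],
    }))


@pytest.fixture
def covariates():
    return NetworkCovariates(pd.DataFrame({
        "network_id": ["net", "other"],
        "latitude": [10.0, -35.0],
        "longitude": [20.0, 150.0],
        "bio4": [500.0, 700.0],
        "bio10": [18.0, 22.0],
        "bio15": [60.0, 30.0],
        "bio18": [200.0, 0.0],
    }))
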
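import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated study shared across tests."""
    from clonal_circuits.config import ExpressionConfig, SimConfig
    from clonal_circuits.synthetic_data import simulate_study

    cfg = SimConfig(
        n_clones=4,
        background_per_site=200,
        n_pairs_per_type=40,
        expression=ExpressionConfig(n_genes=200, n_clusters=4, n_ref_cells_per_cluster=60),
        seed=7,
    )
    cells, pairs, bundle, atlas = simulate_study(cfg)
    return {"config": cfg, "cells": cells, "pairs": pairs, "bundle": bundle, "atlas": atlas}


def make_pairs(
    n,
    p,
    relation="related",
    pre_layer="L4",
    post_layer="L5",
    tangential=50.0,
    vertical=150.0,
    rostrocaudal=3,
    rng=None,
    connected=None,
):
    """Hand-built pair table with constant covariates for targeted tests."""
    rng = rng or np.random.default_rng(0)
    if connected is None:
        connected = rng.random(n) < p
    return pd.DataFrame(
        {
            "pre_layer": pre_layer,
            "post_layer": post_layer,
            "relation": relation,
            "connected": connected,
            "bidirectional_tested": False,
            "tangential_um": float(tangential),
            "vertical_um": float(vertical),
            "euclidean_um": float(np.hypot(tangential, vertical)),
            "rostrocaudal": rostrocaudal,
            "clone_id": 0,
        }
    )
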
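"""Shared fixtures: small atlas phantoms, community specs, and a tiny
end-to-end cohort on disk (session-scoped, reused across pipeline tests)."""

from pathlib import Path

import numpy as np
import pytest

from rodentfc import synthetic as syn


@pytest.fixture(scope="session")
def small_atlas():
    """20-region bilateral phantom on a 12x12x6 grid."""
    return syn.make_atlas_phantom(20, (12, 12, 6))


@pytest.fixture(scope="session")
def atlas30():
    """30-region phantom used for matrix-level cohort simulations."""
    return syn.make_atlas_phantom(30, (18, 12, 6))


@pytest.fixture(scope="session")
def three_block_spec(atlas30):
    _, table = atlas30
    ids = list(table.region_id)
    return syn.CommunitySpec(
        blocks=[ids[:10], ids[10:20], ids[20:]],
        within_block_r=0.4,
        between_block_r=0.15,
        homotopic_r=0.4,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A scaled-down on-disk study: 3 subjects/strain, 2 sessions,
    12 regions, 150-volume series.  Returns (data_dir, config dict)."""
    data = tmp_path_factory.mktemp("cohort")
    out = tmp_path_factory.mktemp("results")
    cfg = {
        "seed": 11,
        "paths": {"data_dir": str(data), "out_dir": str(out)},
        "simulate": {
            "n_per_strain": 3,
            "sessions": [3, 6],
            "n_regions": 12,
            "grid_shape": [12, 12, 6],
            "n_volumes": 150,
        },
        "preprocess": {"window_volumes": 120},
        "graph": {"k": 3, "k_range": [2, 4], "n_random": 10},
        "nbs": {"k": 3, "n_perm": 100},
        "community": {"k": 3},
        "memri": {"median_kernel": 3, "n_perm": 15, "min_cluster_voxels": 5},
    }
    config = syn.CohortConfig(
        n_per_strain=3, sessions=(3, 6), n_regions=12,
        grid_shape=(12, 12, 6), n_volumes=150,
    )
    syn.simulate_cohort(config, seed=11, out_dir=data)
    return Path(data), cfg
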
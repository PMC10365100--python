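import dataclasses

import numpy as np
import pytest

from imgx.meta_map import VoxelGrid, build_activation_map, select_studies
from imgx.synthetic import SimulationConfig, generate_expression_atlases, generate_study_database


@pytest.fixture
def small_grid() -> VoxelGrid:
    """20^3 voxel grid, 4 mm, centered near the origin — for exhaustive oracles."""
    return VoxelGrid(shape=(20, 20, 20), spacing=4.0, origin=(-38.0, -38.0, -38.0))


@pytest.fixture(scope="session")
def world():
    """One shared synthetic world: database, term map, atlases (seed 7)."""
    cfg = SimulationConfig(seed=7, n_sites_per_donor=300)
    db = generate_study_database(cfg)
    amap = build_activation_map(
        select_studies(db, cfg.term), cfg.grid, 10.0, term=cfg.term
    )
    atlases = generate_expression_atlases(cfg, amap)
    return cfg, db, amap, atlases


def make_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
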
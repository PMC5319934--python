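"""Shared fixtures: one synthetic world built once per session.

The world is small (5 targets x 12 actives, 30 background molecules,
3 held-out query analogs per target) but exercises every pipeline stage:
activity filtering, group building, scaling calibration, null fitting and
prediction.
"""

from __future__ import annotations

import pytest

from ppb import (
    FixtureSpec,
    build_target_groups,
    calibrate_database,
    calibrate_scaling,
    filter_activities,
    generate_fixture,
    load_activity_table,
    standardize,
)

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world():
    return generate_fixture(FixtureSpec(seed=WORLD_SEED))


@pytest.fixture(scope="session")
def activity_path(world, tmp_path_factory):
    path = tmp_path_factory.mktemp("world") / "activities.tsv"
    world.write_activity_tsv(str(path))
    return str(path)


@pytest.fixture(scope="session")
def records(activity_path):
    return load_activity_table(activity_path)


@pytest.fixture(scope="session")
def db(records):
    return build_target_groups(filter_activities(records))


@pytest.fixture(scope="session")
def background(world):
    return [standardize(s, mol_id=f"BG{i}") for i, s in enumerate(world.background_smiles)]


@pytest.fixture(scope="session")
def scaling(background):
    return calibrate_scaling(background, n_pairs=20_000, seed=7)


@pytest.fixture(scope="session")
def calibration(db, background, scaling):
    return calibrate_database(db, background, scaling, n_max=2_000, seed=11)
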
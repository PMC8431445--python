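"""Shared fixtures: small simulated scenes reused across the suite."""

import numpy as np
import pytest

import melcpipe as mp
from melcpipe.synthetic import default_panel


@pytest.fixture(scope="session")
def small_scene() -> mp.SceneTruth:
    """~60 cells of 4 types on a 300 px field, mild artifacts."""
    params = mp.SyntheticParams(seed=11, image_size=300)
    return mp.make_scene(60, mp.default_cell_types(), [0.25] * 4, params)


@pytest.fixture(scope="session")
def small_run(small_scene) -> mp.MelcRun:
    panel = default_panel(small_scene, nc_pairs={"GD2": "NC1"})
    return mp.render_run(small_scene, panel)


@pytest.fixture(scope="session")
def corrected_run(small_run) -> mp.MelcRun:
    corrected, _ = mp.correct_run(small_run, smoothing_scale=40, min_images=6)
    return corrected


@pytest.fixture(scope="session")
def cell_table(corrected_run) -> mp.CellTable:
    pi = corrected_run.cycle_for("PI")
    nuclei = mp.segment_nuclei(pi.tag_image)
    cells = mp.segment_cells(pi.phase_image)
    return mp.reconcile_masks(cells, nuclei)


@pytest.fixture(scope="session")
def feature_table(corrected_run, cell_table):
    return mp.build_feature_table(corrected_run, cell_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
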
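"""Feature extraction: closed-form shapes, oracle equivalence, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import melcpipe as mp
from melcpipe.features import (
    MORPHOLOGY_COLUMNS,
    boundary_edge_count,
    convex_hull_area,
    feature_columns_for,
    intensity_stats,
)
from melcpipe.segmentation import CellTable


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for y, x in coords:
        m[y, x] = True
    return m


class TestMorphology:
    def test_filled_square(self):
        nuc = np.zeros((8, 8), dtype=bool)
        nuc[2:6, 2:6] = True
        f = mp.compute_morphology(nuc, nuc)
        assert f.nucleus_size == 16
        assert f.nucleus_perimeter == 16
        assert f.nucleus_roundness == pytest.approx(math.pi / 4)
        assert f.nucleus_solidity == pytest.approx(1.0)

    def test_single_pixel(self):
        m = _mask((5, 5), [(2, 2)])
        f = mp.compute_morphology(m, m)
        assert (f.nucleus_size, f.nucleus_perimeter) == (1, 4)
        assert f.nucleus_roundness == pytest.approx(math.pi / 4)
        assert f.nucleus_solidity == pytest.approx(1.0)

    def test_plus_shaped_cross_solidity(self):
        # 5-pixel cross: hull of the unit squares is a 3x3 square minus 4
        # corner triangles of area 1/2 -> area 7
        m = _mask((5, 5), [(1, 2), (2, 1), (2, 2), (2, 3), (3, 2)])
        assert convex_hull_area(m) == pytest.approx(7.0)
        f = mp.compute_morphology(m, m)
        assert f.nucleus_solidity == pytest.approx(5 / 7)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mp.compute_morphology(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))


class TestIntensity:
    def test_one_to_ten(self):
        me, to, m20 = intensity_stats(np.arange(1.0, 11.0))
        assert (me, to, m20) == (5.5, 55.0, 9.5)

    def test_constant_compartment(self):
        me, to, m20 = intensity_stats(np.full(7, 3.0))
        assert (me, to, m20) == (3.0, 21.0, 3.0)

    def test_total_intensity_additive_over_compartments(self, rng):
        channel = rng.uniform(0, 100, (10, 10))
        cell = np.zeros((10, 10), dtype=bool)
        cell[2:6, 2:5] = True  # 12 px
        nuc = np.zeros((10, 10), dtype=bool)
        nuc[3:5, 2:4] = True  # 4 px
        feats = mp.compute_intensity(channel, cell, nuc)
        assert feats["TO_cell"] == pytest.approx(feats["TO_nucleus"] + feats["TO_cytomem"])
        # and TO = ME * n for each compartment
        assert feats["TO_cell"] == pytest.approx(feats["ME_cell"] * 12)
        assert feats["TO_nucleus"] == pytest.approx(feats["ME_nucleus"] * 4)

    def test_nucleus_filling_cell_flags_empty_cytomem(self):
        channel = np.ones((6, 6))
        m = _mask((6, 6), [(2, 2), (2, 3)])
        feats = mp.compute_intensity(channel, m, m)
        assert feats["ME_cytomem"] == feats["TO_cytomem"] == feats["M20_cytomem"] == 0.0


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0.001, 1e4), min_size=1, max_size=60))
def test_m20_never_below_mean(values):
    me, _, m20 = intensity_stats(np.array(values))
    assert m20 >= me - 1e-9 * max(values)


class TestFeatureTable:
    @pytest.mark.parametrize("n_markers,expected", [(1, 15), (20, 186)])
    def test_column_count(self, n_markers, expected):
        cols = feature_columns_for([f"M{i}" for i in range(n_markers)])
        assert len(cols) == expected

    def test_zero_cells_gives_header_only(self):
        empty = CellTable(
            records=pd.DataFrame(
                columns=["cell_id", "cell_label", "nucleus_label", "centroid_x", "centroid_y", "border_touching"]
            ),
            cell_mask=np.zeros((8, 8), dtype=np.int64),
            nucleus_mask=np.zeros((8, 8), dtype=np.int64),
        )
        table = mp.build_feature_table({"A": np.zeros((8, 8))}, empty)
        assert len(table) == 0
        assert list(table.columns[-15:]) == feature_columns_for(["A"])

    def test_missing_marker_rejected(self, corrected_run, cell_table):
        with pytest.raises(KeyError):
            mp.build_feature_table(corrected_run, cell_table, markers=["NOPE"])

    def test_intensity_invariant_to_mask_relabeling(self, rng):
        channel = rng.uniform(0, 50, (12, 12))
        cell = np.zeros((12, 12), dtype=np.int64)
        cell[2:7, 2:7] = 1
        nuc = np.zeros((12, 12), dtype=np.int64)
        nuc[3:6, 3:6] = 1
        t1 = mp.reconcile_masks(cell, nuc)
        t2 = mp.reconcile_masks(cell * 7, nuc * 3)  # same geometry, new labels
        f1 = mp.build_feature_table({"A": channel}, t1)
        f2 = mp.build_feature_table({"A": channel}, t2)
        cols = feature_columns_for(["A"])
        np.testing.assert_allclose(f1[cols].to_numpy(), f2[cols].to_numpy())


def naive_features(channel, cell_mask, nucleus_mask):
    """Independent per-pixel loop oracle for all morphology and intensity features."""
    h, w = cell_mask.shape
    cell_px = [(y, x) for y in range(h) for x in range(w) if cell_mask[y, x]]
    nuc_px = [(y, x) for y in range(h) for x in range(w) if nucleus_mask[y, x]]

    def perim(pixels):
        pset = set(pixels)
        edges = 0
        for y, x in pixels:
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (y + dy, x + dx) not in pset:
                    edges += 1
        return edges

    from shapely.geometry import MultiPoint

    def hull_area(pixels):
        corners = [(y + dy, x + dx) for y, x in pixels for dy in (0, 1) for dx in (0, 1)]
        return MultiPoint(corners).convex_hull.area

    def stats(pixels):
        vals = sorted(channel[y, x] for y, x in pixels)
        n = len(vals)
        if n == 0:
            return 0.0, 0.0, 0.0
        k = max(1, math.ceil(0.2 * n))
        return sum(vals) / n, sum(vals), sum(vals[-k:]) / k

    cyto_px = [p for p in cell_px if p not in set(nuc_px)]
    out = {
        "cell_size": len(cell_px),
        "cell_perimeter": perim(cell_px),
        "nucleus_size": len(nuc_px),
        "nucleus_perimeter": perim(nuc_px),
        "nucleus_roundness": 4 * math.pi * len(nuc_px) / perim(nuc_px) ** 2,
        "nucleus_solidity": len(nuc_px) / hull_area(nuc_px),
    }
    for comp, px in (("nucleus", nuc_px), ("cell", cell_px), ("cytomem", cyto_px)):
        me, to, m20 = stats(px)
        out[f"ME_{comp}"], out[f"TO_{comp}"], out[f"M20_{comp}"] = me, to, m20
    return out


def random_cell_and_nucleus(rng, size=14):
    """A random connected blob with a nucleus inside it."""
    from scipy import ndimage

    while True:
        seed_mask = rng.random((size, size)) < 0.35
        lab, n = ndimage.label(seed_mask)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        big = int(np.argmax(sizes)) + 1
        cell = lab == big
        if cell.sum() < 6:
            continue
        eroded = ndimage.binary_erosion(cell)
        nucleus = eroded if eroded.any() else cell
        # keep one connected nucleus component
        nl, nn = ndimage.label(nucleus)
        nucleus = nl == 1
        if nucleus.any():
            return cell, nucleus


@pytest.mark.parametrize("trial", range(25))
def test_oracle_equivalence_on_random_masks(trial):
    """Every feature equals the naive per-pixel oracle exactly on random shapes."""
    rng = np.random.default_rng(1000 + trial)
    cell, nucleus = random_cell_and_nucleus(rng)
    channel = rng.uniform(0, 255, cell.shape)
    expected = naive_features(channel, cell, nucleus)

    morph = mp.compute_morphology(cell, nucleus)
    for key in MORPHOLOGY_COLUMNS:
        assert getattr(morph, key) == pytest.approx(expected[key], abs=1e-9), key
    intens = mp.compute_intensity(channel, cell, nucleus)
    for key, val in intens.items():
        assert val == pytest.approx(expected[key], abs=1e-9), key
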
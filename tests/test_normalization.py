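"""NC-ratio and background-level normalization contracts."""

import numpy as np
import pandas as pd
import pytest

from melcpipe.features import feature_columns_for
from melcpipe.normalization import (
    NormalizationConfig,
    apply_background_normalization,
    estimate_background_levels,
    nc_ratio_normalize,
)


def _table(marker_values: dict[str, np.ndarray], sample="s1", fov="f1") -> pd.DataFrame:
    """Feature table whose nine intensity features per marker all equal the
    given per-cell value (a convenient degenerate case for exact checks)."""
    n = len(next(iter(marker_values.values())))
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "sample_id": sample,
            "fov_id": fov,
            "cyto_empty": False,
        }
    )
    for col in feature_columns_for([]):
        df[col] = 1.0
    for marker, vals in marker_values.items():
        for col in feature_columns_for([marker])[6:]:
            df[col] = np.asarray(vals, dtype=float)
    return df


class TestNcRatio:
    def test_simple_ratio(self):
        t = _table({"A": np.array([8.0]), "NC": np.array([2.0])})
        out = nc_ratio_normalize(t, NormalizationConfig(nc_pairs={"A": "NC"}))
        assert out["A_ME_cell"].iloc[0] == pytest.approx(4.0, rel=1e-5)
        assert "NC_ME_cell" not in out.columns

    def test_unit_nc_is_identity(self):
        t = _table({"A": np.array([5.0, 7.0]), "NC": np.array([1.0, 1.0])})
        out = nc_ratio_normalize(t, NormalizationConfig(nc_pairs={"A": "NC"}))
        np.testing.assert_allclose(out["A_TO_cell"], [5.0, 7.0], rtol=1e-5)

    def test_zero_nc_guard_flags_cell(self):
        t = _table({"A": np.array([8.0, 8.0]), "NC": np.array([0.0, 2.0])})
        out = nc_ratio_normalize(t, NormalizationConfig(nc_pairs={"A": "NC"}, eps=1e-6))
        assert np.isfinite(out["A_ME_cell"]).all()
        assert list(out["nc_zero"]) == [True, False]

    def test_morphology_and_unpaired_markers_untouched(self):
        t = _table({"A": np.array([8.0]), "B": np.array([3.0]), "NC": np.array([2.0])})
        out = nc_ratio_normalize(t, NormalizationConfig(nc_pairs={"A": "NC"}))
        assert out["B_ME_cell"].iloc[0] == 3.0
        assert out["cell_size"].iloc[0] == 1.0

    def test_missing_nc_column_rejected(self):
        t = _table({"A": np.array([8.0])})
        with pytest.raises(KeyError):
            nc_ratio_normalize(t, NormalizationConfig(nc_pairs={"A": "NC"}))


def _two_population_table(rng, n=500, neg_mu=10.0, pos_mu=100.0, sample="s1", fov="f1", gain=1.0):
    """Half the cells are counterpart-positive (marker at background), half
    genuinely marker-positive (counterpart at background)."""
    half = n // 2
    marker = np.concatenate([rng.normal(neg_mu, 1, half), rng.normal(pos_mu, 5, n - half)])
    counter = np.concatenate([rng.normal(pos_mu, 5, half), rng.normal(neg_mu, 1, n - half)])
    t = _table({"A": gain * np.clip(marker, 0.1, None), "B": gain * np.clip(counter, 0.1, None)},
               sample=sample, fov=fov)
    t["truth_positive"] = np.arange(n) >= half
    return t


class TestBackgroundLevels:
    def test_level_separates_planted_populations(self, rng):
        # q_background = 0.99: by construction the level sits at the chosen
        # quantile of the background population, so classification accuracy
        # can only reach 1 - (1 - q)/2 on balanced populations
        t = _two_population_table(rng)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"}, q_background=0.99)
        levels = estimate_background_levels(t, cfg)
        b = levels.lookup("s1", "f1", "A")
        assert 10 < b < 100
        pred = t["A_M20_cytomem"] > b
        accuracy = np.mean(pred == t["truth_positive"])
        assert accuracy >= 0.99

    def test_all_counterpart_negative_warns_and_skips(self, rng, caplog):
        t = _two_population_table(rng, n=30)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"}, min_reference_cells=29)
        with caplog.at_level("WARNING"):
            levels = estimate_background_levels(t, cfg)
        assert levels.lookup("s1", "f1", "A") is None
        assert "insufficient" in caplog.text

    def test_zero_marker_in_reference_floored_and_flagged(self, rng):
        t = _two_population_table(rng, n=100)
        for col in [c for c in t.columns if c.startswith("A_")]:
            t[col] = 0.0
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"}, min_reference_cells=5)
        levels = estimate_background_levels(t, cfg)
        row = levels.levels.iloc[0]
        assert row.level == pytest.approx(cfg.eps)
        assert bool(row.flagged)


class TestApplyBackground:
    def test_value_at_level_maps_to_one(self, rng):
        t = _two_population_table(rng)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"})
        levels = estimate_background_levels(t, cfg)
        b = levels.lookup("s1", "f1", "A")
        t.loc[0, [c for c in t.columns if c.startswith("A_")]] = b
        out = apply_background_normalization(t, levels)
        assert out["A_ME_cell"].iloc[0] == pytest.approx(1.0)

    def test_planted_batch_gain_removed(self, rng):
        """Two images identical up to a x3 staining gain agree after normalization."""
        t1 = _two_population_table(np.random.default_rng(1), fov="f1", gain=1.0)
        t2 = _two_population_table(np.random.default_rng(2), fov="f2", gain=3.0)
        t = pd.concat([t1, t2], ignore_index=True)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"})
        out = apply_background_normalization(t, estimate_background_levels(t, cfg))
        med1 = out[(out.fov_id == "f1") & out.truth_positive]["A_ME_cell"].median()
        med2 = out[(out.fov_id == "f2") & out.truth_positive]["A_ME_cell"].median()
        assert abs(med1 - med2) / med1 < 0.10
        # and the between-batch spread strictly shrinks vs the raw features
        raw1 = t[(t.fov_id == "f1") & t.truth_positive]["A_ME_cell"].median()
        raw2 = t[(t.fov_id == "f2") & t.truth_positive]["A_ME_cell"].median()
        cv = lambda a, b: abs(a - b) / np.mean([a, b])
        assert cv(med1, med2) < cv(raw1, raw2)

    def test_scale_equivariance_exact(self, rng):
        t = _two_population_table(rng)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"})
        out1 = apply_background_normalization(t, estimate_background_levels(t, cfg))
        scaled = t.copy()
        cols = [c for c in t.columns if c.startswith(("A_", "B_"))]
        scaled[cols] = scaled[cols] * 17.0
        out2 = apply_background_normalization(scaled, estimate_background_levels(scaled, cfg))
        np.testing.assert_allclose(
            out1["A_ME_cell"].to_numpy(), out2["A_ME_cell"].to_numpy(), rtol=1e-9
        )

    def test_within_image_ordering_preserved(self, rng):
        t = _two_population_table(rng)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"})
        out = apply_background_normalization(t, estimate_background_levels(t, cfg))
        before = np.argsort(t["A_ME_cell"].to_numpy())
        after = np.argsort(out["A_ME_cell"].to_numpy())
        np.testing.assert_array_equal(before, after)

    def test_marker_without_level_passes_through(self, rng, caplog):
        t = _two_population_table(rng)
        cfg = NormalizationConfig(exclusive_pairs={"A": "B"})
        levels = estimate_background_levels(t, cfg)
        levels.levels = levels.levels[levels.levels.marker != "A"]
        with caplog.at_level("WARNING"):
            out = apply_background_normalization(t, levels)
        np.testing.assert_array_equal(out["A_ME_cell"], t["A_ME_cell"])
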
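"""Stability metrics, consensus clustering, F-tests and PCA contributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from melcpipe.cluster_eval import (
    ConsensusResult,
    ConsensusSpec,
    StabilityMetrics,
    compute_mcs,
    feature_significance,
    pca_contributions,
    run_consensus,
    stability_metrics,
    variant_columns,
)
from melcpipe.features import feature_columns_for


def _intensity_table(x: np.ndarray) -> pd.DataFrame:
    """Wrap a matrix as marker ME_cell columns so variants pick it up."""
    return pd.DataFrame(x, columns=[f"M{i}_ME_cell" for i in range(x.shape[1])])


class TestMcs:
    @pytest.mark.parametrize(
        "pac,con,mss,expected",
        [(0.0, 1.0, 1.0, 1.0), (1.0, 0.0, 0.0, 0.0), (0.4, 0.8, 0.5, 1.9 / 3)],
    )
    def test_closed_form(self, pac, con, mss, expected):
        assert compute_mcs(StabilityMetrics(pac, con, mss)) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(-1, 1),
    )
    def test_bounds(self, pac, con, mss):
        mcs = compute_mcs(StabilityMetrics(pac, con, mss))
        assert -1 / 3 - 1e-12 <= mcs <= 1 + 1e-12

    def test_strictly_decreasing_in_pac(self):
        lo = compute_mcs(StabilityMetrics(0.2, 0.5, 0.5))
        hi = compute_mcs(StabilityMetrics(0.8, 0.5, 0.5))
        assert hi < lo


def _result_from_consensus(c: np.ndarray, partition, repeats) -> ConsensusResult:
    return ConsensusResult(
        consensus_matrix=c,
        repeat_partitions=[np.asarray(p) for p in repeats],
        consensus_partition=np.asarray(partition),
    )


class TestStabilityMetrics:
    def test_binary_consensus_has_zero_pac(self):
        c = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        res = _result_from_consensus(c, [1, 1, 2], [[1, 1, 2]])
        m = stability_metrics(res, ConsensusSpec(n_clusters=2))
        assert m.pac == 0.0

    def test_all_half_consensus_has_unit_pac(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        res = _result_from_consensus(c, [1, 1, 2, 2], [[1, 1, 2, 2]])
        m = stability_metrics(res, ConsensusSpec(n_clusters=2))
        assert m.pac == 1.0

    def test_concordant_repeats_give_unit_con(self):
        c = np.eye(4)
        c[:2, :2] = 1.0
        c[2:, 2:] = 1.0
        res = _result_from_consensus(c, [1, 1, 2, 2], [[1, 1, 2, 2]] * 5)
        m = stability_metrics(res, ConsensusSpec(n_clusters=2))
        assert m.con == 1.0
        assert m.mss > 0.9

    def test_single_cluster_partition_mss_zero(self):
        c = np.ones((3, 3))
        res = _result_from_consensus(c, [1, 1, 1], [[1, 1, 1]])
        with pytest.warns(UserWarning, match="single-cluster"):
            m = stability_metrics(res, ConsensusSpec(n_clusters=2))
        assert m.mss == 0.0


class TestRunConsensus:
    def test_two_blobs_are_stable(self, rng):
        x = np.vstack([rng.normal(0, 1, (100, 10)), rng.normal(8, 1, (100, 10))])
        spec = ConsensusSpec(n_repeats=8, n_clusters=2, seed=5)
        res = run_consensus(_intensity_table(x), spec)
        m = stability_metrics(res, spec)
        off = res.consensus_matrix[np.triu_indices(200, k=1)]
        assert m.pac <= 0.05
        assert np.mean((off < 0.05) | (off > 0.95)) > 0.9

    def test_single_repeat_gives_binary_consensus(self, rng):
        x = rng.normal(0, 1, (60, 8))
        spec = ConsensusSpec(n_repeats=1, n_clusters=3, seed=2, perplexity=15)
        res = run_consensus(_intensity_table(x), spec)
        vals = np.unique(res.consensus_matrix)
        assert set(vals.tolist()) <= {0.0, 1.0}
        assert stability_metrics(res, spec).pac == 0.0

    def test_consensus_matrix_symmetric_unit_diagonal(self, rng):
        x = rng.normal(0, 1, (50, 6))
        spec = ConsensusSpec(n_repeats=3, n_clusters=3, seed=3, perplexity=10)
        res = run_consensus(_intensity_table(x), spec)
        np.testing.assert_allclose(res.consensus_matrix, res.consensus_matrix.T)
        np.testing.assert_allclose(np.diag(res.consensus_matrix), 1.0)
        assert res.consensus_matrix.min() >= 0 and res.consensus_matrix.max() <= 1

    def test_too_few_cells_rejected(self, rng):
        x = rng.normal(0, 1, (5, 4))
        with pytest.raises(ValueError):
            run_consensus(_intensity_table(x), ConsensusSpec(n_clusters=10))


class TestVariants:
    def test_variant_column_selection(self):
        df = pd.DataFrame(columns=["cell_id"] + feature_columns_for(["A", "B"]))
        assert len(variant_columns(df, "I")) == 6 + 18
        assert len(variant_columns(df, "II")) == 6 + 6
        assert len(variant_columns(df, "III")) == 6 + 6
        assert len(variant_columns(df, "IV")) == 6 + 6
        assert len(variant_columns(df, "V")) == 6  # M20 only, no morphology

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            variant_columns(pd.DataFrame(), "VI")


class TestFeatureSignificance:
    def test_constant_feature_not_significant(self):
        t = pd.DataFrame({"f": np.ones(20)})
        out = feature_significance(t, np.repeat([1, 2], 10), feature_cols=["f"])
        assert not out.significant.iloc[0]
        assert out.max_scaled_diff.iloc[0] == 0.0

    def test_hand_computed_anova(self):
        # {1,2,3} vs {11,12,13}: SSB = 150 (df 1), MSW = 1 (df 4) -> F = 150
        t = pd.DataFrame({"f": [1.0, 2, 3, 11, 12, 13]})
        out = feature_significance(t, np.repeat([1, 2], 3), feature_cols=["f"])
        assert out.F.iloc[0] == pytest.approx(150.0)

    def test_planted_shift_detected_after_bh(self, rng):
        n, k = 100, 5
        labels = np.repeat(np.arange(k), n)
        t = pd.DataFrame({
            "shifted": rng.normal(0, 1, n * k) + 5.0 * (labels == 2),
            "null1": rng.normal(0, 1, n * k),
            "null2": rng.normal(0, 1, n * k),
        })
        out = feature_significance(t, labels, feature_cols=["shifted", "null1", "null2"])
        assert bool(out.set_index("feature").significant["shifted"])
        assert out.set_index("feature").max_scaled_diff["shifted"] > 0

    def test_degenerate_within_cluster_variance_flagged(self):
        t = pd.DataFrame({"f": [1.0, 1, 2, 2]})
        out = feature_significance(t, np.array([1, 1, 2, 2]), feature_cols=["f"])
        assert np.isinf(out.F.iloc[0])


class TestPca:
    def test_single_informative_feature_dominates_pc1(self, rng):
        t = pd.DataFrame({
            "live": rng.normal(0, 1, 100),
            "const1": np.ones(100),
            "const2": np.zeros(100),
            "live2": rng.normal(0, 1, 100) * 1e-9 + 5,
        })
        with pytest.warns(UserWarning, match="constant"):
            loadings, evr, contrib = pca_contributions(t, feature_cols=list(t.columns))
        assert contrib.loc["live", "PC1"] == pytest.approx(
            contrib["PC1"].max(), rel=1e-6
        )

    def test_autoscaled_total_variance_equals_feature_count(self, rng):
        from melcpipe.cluster_eval import _zscore

        x = rng.normal(0, 1, (200, 6)) * rng.uniform(1, 50, 6)
        z = _zscore(x)
        assert z.var(axis=0, ddof=0).sum() == pytest.approx(6.0)
        t = pd.DataFrame(x, columns=[f"f{i}" for i in range(6)])
        _, evr, _ = pca_contributions(t, feature_cols=list(t.columns))
        assert evr.sum() == pytest.approx(1.0)

    def test_isotropic_variance_split_evenly(self, rng):
        x = rng.normal(0, 1, (2000, 5))
        t = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
        _, evr, contrib = pca_contributions(t, feature_cols=list(t.columns))
        np.testing.assert_allclose(evr, 0.2, atol=0.03)
        np.testing.assert_allclose(contrib.sum(axis=0), 1.0, rtol=1e-9)
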
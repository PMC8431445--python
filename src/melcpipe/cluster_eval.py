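"""Consensus-clustering stability scoring and feature validation.

A feature subset is scored by how stably it clusters: the clustering
(t-SNE embedding of z-scored data followed by a Gaussian-mixture fit) is
repeated R times on random subsamples of the feature space, co-clustering
frequencies form a consensus matrix, and three metrics summarize it:

* PAC — proportion of ambiguous clustering: fraction of cell pairs whose
  consensus frequency falls strictly inside an ambiguous band (default
  (0.1, 0.9)); lower is more stable;
* CON — concordance: mean pair-agreement (Rand index) between each repeat's
  partition and the consensus partition;
* MSS — mean silhouette width of the consensus partition under the distance
  1 - consensus;

combined into the mean clustering score ``MCS = ((1 - PAC) + CON + MSS) / 3``.

Feature-subset variants follow the study design: (I) all three intensity
statistics in all three compartments plus morphology, (II) M20 +
morphology, (III) ME + morphology, (IV) TO + morphology, (V) M20 without
morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import rand_score, silhouette_score
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from melcpipe.features import MORPHOLOGY_COLUMNS, intensity_columns

FEATURE_VARIANTS = ("I", "II", "III", "IV", "V")


def variant_columns(table: pd.DataFrame, variant: str) -> list[str]:
    """Feature columns of one of the five study feature-subset variants."""
    stats_of = {"I": ("ME", "TO", "M20"), "II": ("M20",), "III": ("ME",), "IV": ("TO",), "V": ("M20",)}
    if variant not in stats_of:
        raise ValueError(f"unknown feature variant {variant!r}; expected one of {FEATURE_VARIANTS}")
    cols = [
        c
        for c in intensity_columns(table)
        if c.rsplit("_", 2)[1] in stats_of[variant]
    ]
    if variant != "V":
        cols = [c for c in MORPHOLOGY_COLUMNS if c in table.columns] + cols
    return cols


@dataclass
class ConsensusSpec:
    feature_variant: str = "I"
    n_repeats: int = 100
    subsample_rate: float = 0.8
    n_clusters: int = 10
    perplexity: float = 30.0
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_rate <= 1:
            raise ValueError("subsample_rate must be in (0, 1]")
        if not self.pac_lower < self.pac_upper:
            raise ValueError("pac_lower must be < pac_upper")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")


@dataclass
class ConsensusResult:
    consensus_matrix: np.ndarray
    repeat_partitions: list[np.ndarray]
    consensus_partition: np.ndarray


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _embed(x: np.ndarray, perplexity: float, seed: int) -> np.ndarray:
    n = x.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of cells ({n})")
    if np.allclose(x, x[0]):
        # fully degenerate input (all cells identical): the embedding is a
        # single point; short-circuit rather than feed zero spread to t-SNE
        return np.zeros((n, 2))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tsne.fit_transform(x)


def run_consensus(table: pd.DataFrame, spec: ConsensusSpec) -> ConsensusResult:
    """Repeated subsample–embed–cluster, aggregated into a consensus matrix.

    Per repeat: sample ``ceil(rate * F)`` feature columns without
    replacement, z-score them, embed to 2D (t-SNE at the spec's perplexity)
    and fit a G-component Gaussian mixture on the embedding.  The consensus
    matrix holds co-clustering frequencies over repeats; the consensus
    partition is an average-linkage cut of ``1 - consensus`` into G groups.
    A repeat whose mixture fit degenerates is re-seeded once, then skipped.
    """
    cols = variant_columns(table, spec.feature_variant)
    x_all = table[cols].to_numpy(dtype=np.float64)
    n = x_all.shape[0]
    if n <= spec.n_clusters:
        raise ValueError("need more cells than clusters")
    n_feat = len(cols)
    k_feat = max(1, int(np.ceil(spec.subsample_rate * n_feat)))
    rng = np.random.default_rng(spec.seed)

    co = np.zeros((n, n))
    partitions: list[np.ndarray] = []
    for rep in range(spec.n_repeats):
        chosen = rng.choice(n_feat, size=k_feat, replace=False)
        x = _zscore(x_all[:, chosen])
        emb = _embed(x, spec.perplexity, seed=int(rng.integers(2**31)))
        labels = None
        for attempt in range(2):
            gm = GaussianMixture(
                n_components=spec.n_clusters,
                random_state=int(rng.integers(2**31)),
                reg_covar=1e-6,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    labels = gm.fit_predict(emb)
                break
            except Exception:  # degenerate fit: re-seed once, then skip
                labels = None
        if labels is None:
            warnings.warn(f"skipping degenerate mixture fit in repeat {rep}")
            continue
        partitions.append(labels)
        co += (labels[:, None] == labels[None, :]).astype(np.float64)

    if not partitions:
        raise RuntimeError("all consensus repeats failed")
    consensus = co / len(partitions)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    partition = fcluster(z, t=spec.n_clusters, criterion="maxclust")
    return ConsensusResult(
        consensus_matrix=consensus,
        repeat_partitions=partitions,
        consensus_partition=np.asarray(partition),
    )


@dataclass
class StabilityMetrics:
    pac: float
    con: float
    mss: float

    @property
    def mcs(self) -> float:
        return compute_mcs(self)


def stability_metrics(result: ConsensusResult, spec: ConsensusSpec) -> StabilityMetrics:
    """PAC / CON / MSS of a consensus-clustering result."""
    c = result.consensus_matrix
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    pac = float(np.mean((vals > spec.pac_lower) & (vals < spec.pac_upper)))
    con = float(
        np.mean([rand_score(p, result.consensus_partition) for p in result.repeat_partitions])
    )
    if len(np.unique(result.consensus_partition)) < 2:
        warnings.warn("single-cluster consensus partition; MSS defined as 0")
        mss = 0.0
    else:
        dist = 1.0 - c
        np.fill_diagonal(dist, 0.0)
        mss = float(
            silhouette_score(dist, result.consensus_partition, metric="precomputed")
        )
    return StabilityMetrics(pac=pac, con=con, mss=mss)


def compute_mcs(metrics: StabilityMetrics) -> float:
    """Mean clustering score: ((1 - PAC) + CON + MSS) / 3."""
    return ((1.0 - metrics.pac) + metrics.con + metrics.mss) / 3.0


def feature_significance(
    table: pd.DataFrame,
    labels: np.ndarray,
    feature_cols: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across clusters with BH correction.

    Returns one row per feature: F statistic, BH-adjusted p-value, a
    significance flag at ``alpha``, and the max difference of z-scored
    cluster means (0 for non-significant or degenerate features).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 clusters")
    if any(np.sum(labels == g) < 2 for g in groups):
        raise ValueError("every cluster needs at least 2 cells")
    if feature_cols is None:
        feature_cols = variant_columns(table, "I")

    rows = []
    for col in feature_cols:
        x = table[col].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            rows.append({"feature": col, "F": 0.0, "p": 1.0, "max_scaled_diff": 0.0})
            continue
        samples = [x[labels == g] for g in groups]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) > 1:
            # zero within-cluster variance but distinct means
            rows.append({"feature": col, "F": np.inf, "p": 0.0, "max_scaled_diff": np.nan})
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = f_oneway(*samples)
            rows.append({"feature": col, "F": float(f_stat), "p": float(p), "max_scaled_diff": np.nan})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha

    # max - min of z-scored cluster means, for significant features
    for i, col in enumerate(feature_cols):
        if not out.loc[i, "significant"]:
            out.loc[i, "max_scaled_diff"] = 0.0
            continue
        x = table[col].to_numpy(dtype=np.float64)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / (sd if sd > 0 else 1.0)
        means = [z[labels == g].mean() for g in groups]
        out.loc[i, "max_scaled_diff"] = float(max(means) - min(means))
    return out[["feature", "F", "p", "p_adj", "significant", "max_scaled_diff"]]


def pca_contributions(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of autoscaled features with per-feature contributions.

    Constant columns are dropped with a warning before scaling.  Returns
    (loadings, variance-explained ratios, contributions), contributions being
    squared loadings normalized to sum to 1 within each component.
    """
    if feature_cols is None:
        feature_cols = variant_columns(table, "I")
    x = table[feature_cols].to_numpy(dtype=np.float64)
    if x.shape[1] < 2 or x.shape[0] <= 2:
        raise ValueError("PCA needs >= 2 features and > 2 cells")
    keep = [i for i in range(x.shape[1]) if np.ptp(x[:, i]) > 0]
    if len(keep) < len(feature_cols):
        dropped = [feature_cols[i] for i in range(x.shape[1]) if i not in keep]
        warnings.warn(f"dropping constant features before PCA: {dropped}")
    cols = [feature_cols[i] for i in keep]
    z = _zscore(x[:, keep])
    pca = PCA()
    pca.fit(z)
    comp_names = [f"PC{i + 1}" for i in range(pca.components_.shape[0])]
    loadings = pd.DataFrame(pca.components_.T, index=cols, columns=comp_names)
    contrib = loadings**2
    contrib = contrib / contrib.sum(axis=0)
    return loadings, pca.explained_variance_ratio_, contrib
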
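"""Correlation structure of ratio features and sample clustering.

Feature-feature correlations are reported with two-sided p-values and a
significance mask at p < 0.05; negatively correlated feature blocks are
detected by clustering the correlation matrix (distance 1 - r, complete
linkage) and scoring cluster pairs by their mean significant
between-cluster correlation.  Samples are clustered with correlation
distance (1 - Pearson r between feature profiles) and complete linkage,
and cluster cuts are compared against phenotype labels to report
misclassified samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    """Symmetric correlation / p matrices with a p < 0.05 mask."""

    feature_ids: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    significant_mask: pd.DataFrame
    method: str
    n_samples: int


@dataclass
class NegativeBlock:
    """One negatively correlated off-diagonal block between two feature
    clusters."""

    features_a: list[str]
    features_b: list[str]
    mean_r: float
    n_significant: int


@dataclass
class ClusterResult:
    """Complete-linkage sample dendrogram with phenotype labels."""

    linkage: np.ndarray
    sample_ids: list[str]
    labels: pd.Series
    leaf_order: list[str] = field(default_factory=list)

    def cut(self, k: int) -> pd.Series:
        if k > len(self.sample_ids):
            raise ValidationError(f"cannot cut {len(self.sample_ids)} samples into {k} clusters")
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.sample_ids, name="cluster")


def _feature_frame(table) -> pd.DataFrame:
    return getattr(table, "scaled_values", table)


def correlation_matrix(features, method: str = "pearson") -> CorrelationReport:
    """Pairwise feature correlations with two-sided p from the t transform.

    Spearman correlations rank-transform first and use the same t
    reference (adequate at the sample sizes in play).  Zero-variance
    features are dropped with a warning.
    """
    frame = _feature_frame(features)
    n = frame.shape[0]
    if n < 3:
        raise ValidationError("correlation needs at least 3 samples")
    sd = frame.std(axis=0, ddof=1)
    drop = sd.index[(sd == 0) | sd.isna()]
    if len(drop):
        logger.warning("dropping %d zero-variance feature(s)", len(drop))
        frame = frame.drop(columns=drop)
    if method == "spearman":
        frame = frame.rank(axis=0)
    elif method != "pearson":
        raise ValidationError("method must be 'pearson' or 'spearman'")
    x = frame.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = np.clip((x.T @ x) / (n - 1), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(p)] = 0.0  # |r| = 1 exactly
    np.fill_diagonal(p, 0.0)
    ids = list(frame.columns)
    r_df = pd.DataFrame(r, index=ids, columns=ids)
    p_df = pd.DataFrame(p, index=ids, columns=ids)
    return CorrelationReport(ids, r_df, p_df, p_df < 0.05, method, n)


def _feature_linkage(r: pd.DataFrame) -> np.ndarray:
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(dist, checks=False), method="complete")


def order_features(report: CorrelationReport) -> list[str]:
    """Dendrogram leaf order of features under 1 - r / complete linkage."""
    z = _feature_linkage(report.r)
    return [report.feature_ids[i] for i in hierarchy.leaves_list(z)]


def detect_negative_blocks(
    report: CorrelationReport,
    min_block_size: int = 3,
    mean_r_threshold: float = -0.3,
    cut_distance: float = 1.0,
) -> list[NegativeBlock]:
    """Find anti-correlated feature blocks.

    Features are clustered on 1 - r (complete linkage) and the tree is
    cut at ``cut_distance`` (default 1.0, i.e. clusters are internally
    positively correlated).  Every pair of clusters each of size >=
    ``min_block_size`` whose mean significant between-cluster r is <=
    ``mean_r_threshold`` is reported, ranked by |mean r| descending.
    """
    if mean_r_threshold >= 0:
        raise ValidationError("mean_r_threshold must be negative")
    ids = report.feature_ids
    if len(ids) < 2 * min_block_size:
        return []
    z = _feature_linkage(report.r)
    assign = hierarchy.fcluster(z, t=cut_distance, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for feat, c in zip(ids, assign):
        clusters.setdefault(int(c), []).append(feat)
    blocks: list[NegativeBlock] = []
    keys = sorted(clusters)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            fa, fb = clusters[ka], clusters[kb]
            if min(len(fa), len(fb)) < min_block_size:
                continue
            sub_r = report.r.loc[fa, fb].to_numpy()
            sub_sig = report.significant_mask.loc[fa, fb].to_numpy()
            if not sub_sig.any():
                continue
            mean_r = float(sub_r[sub_sig].mean())
            if mean_r <= mean_r_threshold:
                blocks.append(
                    NegativeBlock(sorted(fa), sorted(fb), mean_r, int(sub_sig.sum()))
                )
    blocks.sort(key=lambda b: (-abs(b.mean_r), b.features_a, b.features_b))
    return blocks


def hcluster_samples(features, labels: pd.Series) -> ClusterResult:
    """Complete-linkage clustering of samples on correlation distance.

    Distance between two samples is 1 - Pearson r between their feature
    profiles (in [0, 2]).  Constant profiles have undefined correlation
    and are dropped with a warning.
    """
    frame = _feature_frame(features)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValidationError("need >= 2 samples and >= 2 features")
    sd = frame.std(axis=1, ddof=1)
    drop = sd.index[(sd == 0) | sd.isna()]
    if len(drop):
        logger.warning("dropping %d constant sample profile(s): %s", len(drop), list(drop))
        frame = frame.drop(index=drop)
    x = frame.to_numpy(dtype=float)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    r = np.clip((x @ x.T) / (x.shape[1] - 1), -1.0, 1.0)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    sample_ids = list(frame.index)
    leaf_order = [sample_ids[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(z, sample_ids, labels.loc[sample_ids], leaf_order)


def misclassified_samples(cluster: ClusterResult, k: int) -> list[str]:
    """Samples whose phenotype differs from their cluster's majority.

    Each cluster at the k-cut is assigned its majority phenotype; ties
    are broken toward "not misclassified" (a sample whose label is among
    the cluster's modal labels is kept).
    """
    assign = cluster.cut(k)
    out: list[str] = []
    for c in sorted(assign.unique()):
        members = assign.index[assign == c]
        counts = cluster.labels.loc[members].value_counts()
        modal = set(counts.index[counts == counts.max()])
        out.extend(s for s in members if cluster.labels.loc[s] not in modal)
    return sorted(out)


def plot_correlation_heatmap(report: CorrelationReport, path) -> None:
    """Significance-masked correlation heatmap in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = order_features(report)
    r = report.r.loc[order, order].where(report.significant_mask.loc[order, order])
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="r (shown where p < 0.05)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
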
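"""Correlation-distance hierarchical clustering of expression samples.

Mirrors the standard microarray heatmap workflow: drop near-constant genes
(variance filter), z-score each retained gene row, compute pairwise sample
distances as 1 − Pearson r, and cluster. Agglomerative complete linkage is
the primary mode; a DIANA-style divisive mode is available. A small summary
statistic quantifies how cleanly the top split separates treated from
control samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .data import InputError

__all__ = [
    "ScaledMatrix",
    "filter_and_scale",
    "correlation_distance",
    "hierarchical_cluster",
    "ClusterResult",
    "treatment_separation_score",
]


@dataclass
class ScaledMatrix:
    """Variance-filtered, row-standardized expression values.

    Each retained row has mean 0 and (sample, ddof=1) SD 1; ``mask`` marks
    which input genes survived the variance filter.
    """

    values: pd.DataFrame
    mask: pd.Series
    var_threshold: float


def filter_and_scale(values: pd.DataFrame, var_threshold: float = 0.1) -> ScaledMatrix:
    """Drop rows with variance ≤ threshold, then z-score the rest.

    Variance and SD use the sample (ddof=1) convention, so the row (1, 2, 3)
    scales to (−1, 0, 1). Raises :class:`InputError` when nothing survives.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise InputError("need at least 2 genes and 2 samples")
    var = values.var(axis=1, ddof=1)
    mask = var > var_threshold
    if not mask.any():
        raise InputError(
            f"no genes pass the variance filter (threshold {var_threshold})"
        )
    kept = values.loc[mask]
    scaled = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=1),
                                                     axis=0)
    return ScaledMatrix(scaled, mask, var_threshold)


def correlation_distance(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distance 1 − Pearson r over genes; range [0, 2]."""
    sd = values.std(axis=0, ddof=0)
    dead = sd.index[sd == 0]
    if len(dead):
        raise InputError(
            f"zero-variance sample column(s), distance undefined: {list(dead[:5])}"
        )
    corr = np.corrcoef(values.T.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=values.columns, columns=values.columns)


@dataclass
class ClusterResult:
    """A sample clustering: distances, tree and leaf order.

    For the agglomerative mode ``linkage_matrix`` is a scipy linkage array;
    for the divisive mode ``divisions`` records (cluster, left, right,
    diameter) splits from the root downward.
    """

    distance: pd.DataFrame
    leaf_order: list[str]
    method: str
    linkage_matrix: np.ndarray | None = None
    divisions: list[tuple[tuple[str, ...], tuple[str, ...], float]] | None = None

    def root_bipartition(self) -> tuple[set[str], set[str]]:
        """The two sample groups at the top split of the tree."""
        labels = list(self.distance.index)
        if self.linkage_matrix is not None:
            assign = fcluster(self.linkage_matrix, 2, criterion="maxclust")
            a = {lab for lab, g in zip(labels, assign) if g == assign[0]}
            return a, set(labels) - a
        left, right, _ = self.divisions[0]
        return set(left), set(right)

    def merge_heights(self) -> np.ndarray:
        if self.linkage_matrix is None:
            raise ValueError("divisive trees have no merge heights")
        return self.linkage_matrix[:, 2]

    def to_tsv(self, path) -> None:
        if self.linkage_matrix is None:
            raise ValueError("TSV export implemented for agglomerative trees")
        df = pd.DataFrame(self.linkage_matrix,
                          columns=["left", "right", "height", "size"])
        df.index.name = "merge"
        df.to_csv(path, sep="\t")


def _diana(dist: np.ndarray, labels: list[str]):
    """Minimal DIANA-style divisive clustering: repeatedly split the cluster
    with the largest diameter by seeding a splinter group with the object of
    maximal average dissimilarity and moving objects whose average
    dissimilarity to the splinter group is smaller than to the remainder."""
    divisions = []
    clusters: list[list[int]] = [list(range(len(labels)))]
    order: list[list[int]] = []

    def diameter(c):
        if len(c) < 2:
            return 0.0
        sub = dist[np.ix_(c, c)]
        return float(sub.max())

    while any(len(c) > 1 for c in clusters):
        target = max((c for c in clusters if len(c) > 1), key=diameter)
        clusters.remove(target)
        sub = dist[np.ix_(target, target)]
        avg = sub.sum(axis=1) / (len(target) - 1)
        splinter = [int(np.argmax(avg))]
        rest = [i for i in range(len(target)) if i not in splinter]
        moved = True
        while moved and len(rest) > 1:
            moved = False
            gains = []
            for i in rest:
                d_spl = sub[i, splinter].mean()
                others = [j for j in rest if j != i]
                d_rest = sub[i, others].mean() if others else 0.0
                gains.append(d_rest - d_spl)
            best = int(np.argmax(gains))
            if gains[best] > 0:
                splinter.append(rest.pop(best))
                moved = True
        left = tuple(labels[target[i]] for i in sorted(splinter))
        right = tuple(labels[target[i]] for i in sorted(rest))
        divisions.append((left, right, diameter(target)))
        clusters.append(sorted(target[i] for i in splinter))
        clusters.append(sorted(target[i] for i in rest))
    leaf_order = [labels[c[0]] for c in sorted(clusters)]
    return divisions, leaf_order


def hierarchical_cluster(scaled: ScaledMatrix, method: str = "complete") -> ClusterResult:
    """Cluster samples on 1 − Pearson r distances.

    ``method`` is any scipy agglomerative linkage name (``complete`` is the
    default and the tested path) or ``"divisive"`` for the DIANA-style mode.
    Leaf order comes from scipy's deterministic dendrogram ordering; ties in
    merge distance are broken by cluster index (insertion order).
    """
    dist = correlation_distance(scaled.values)
    if dist.shape[0] < 2:
        raise InputError("need at least 2 samples to cluster")
    labels = list(dist.index)
    if method == "divisive":
        divisions, leaf_order = _diana(dist.to_numpy(), labels)
        return ClusterResult(dist, leaf_order, method, divisions=divisions)
    lm = linkage(squareform(dist.to_numpy(), checks=False), method=method)
    leaf_order = [labels[i] for i in leaves_list(lm)]
    return ClusterResult(dist, leaf_order, method, linkage_matrix=lm)


def treatment_separation_score(result: ClusterResult,
                               treatments: pd.Series) -> float:
    """Fraction of (exposed, control) sample pairs split by the root
    bipartition of the tree; 1 means the top split perfectly separates
    treatment groups, ~0.5 is chance. NaN when only one treatment level is
    present."""
    groups = treatments.loc[result.distance.index]
    levels = groups.unique()
    if len(levels) < 2:
        return float("nan")
    if len(levels) != 2:
        raise InputError("treatment separation needs exactly 2 levels")
    a, b = result.root_bipartition()
    t0 = set(groups.index[groups == levels[0]])
    t1 = set(groups.index[groups == levels[1]])
    split = len(a & t0) * len(b & t1) + len(a & t1) * len(b & t0)
    return split / (len(t0) * len(t1))


def plot_heatmap(scaled: ScaledMatrix, result: ClusterResult, path,
                 sample_annotations: pd.DataFrame | None = None) -> None:
    """Export a clustered heatmap (genes × reordered samples) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = scaled.values[result.leaf_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu",
                   interpolation="nearest")
    ax.set_xticks(range(len(result.leaf_order)))
    ax.set_xticklabels(result.leaf_order, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("samples (cluster order)")
    ax.set_ylabel(f"{ordered.shape[0]} genes (row-scaled)")
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
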
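"""Hierarchical clustering of averaged correlation matrices.

Genes are agglomeratively clustered (complete linkage by default) on the rows
of the averaged gene-gene correlation matrix and the dendrogram is cut into a
requested number of clusters, mirroring the hclust/cutree workflow common in
microarray co-expression studies.  The default row distance is Euclidean
(what a clustering routine computes when handed the matrix directly); ``1 - r``
is available as an alternative metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .correlate import CorrelationMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Gene -> cluster id (1..k) mapping with the parameters that produced it."""

    labels: pd.Series
    k: int
    linkage: str
    distance: str

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def _dense_values(matrix: CorrelationMatrix) -> np.ndarray:
    vals = matrix.values.to_numpy(dtype=float).copy()
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.warning("imputing %d missing correlation cells to 0", n_missing)
        vals = np.nan_to_num(vals, nan=0.0)
        np.fill_diagonal(vals, 1.0)
    return vals


def cluster_genes(
    matrix: CorrelationMatrix,
    k: int,
    linkage: str = "complete",
    distance: str = "euclidean",
) -> ClusterAssignment:
    """Cut a complete-linkage dendrogram of the correlation matrix into k clusters.

    ``distance`` is either ``"euclidean"`` (between matrix rows) or
    ``"one-minus-r"`` (1 - correlation as a dissimilarity).
    """
    genes = list(matrix.genes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the number of genes ({len(genes)})")
    vals = _dense_values(matrix)
    if distance == "euclidean":
        condensed = pdist(vals, metric="euclidean")
    elif distance == "one-minus-r":
        dis = 1.0 - vals
        np.fill_diagonal(dis, 0.0)
        condensed = squareform(dis, checks=False)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    tree = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=genes, name="cluster"),
        k=k, linkage=linkage, distance=distance,
    )


def cluster_summary(
    matrix: CorrelationMatrix, assignment: ClusterAssignment
) -> tuple[pd.Series, pd.DataFrame]:
    """Within-cluster mean r and cross-cluster negative-correlation fractions.

    Returns ``(within, negative_fraction)`` where ``within[c]`` is the mean
    off-diagonal correlation inside cluster ``c`` (NaN for singletons) and
    ``negative_fraction.loc[a, b]`` is the fraction of cluster-``b`` genes
    whose mean correlation with cluster-``a`` genes is negative.
    """
    genes = list(matrix.genes)
    if not set(genes) <= set(assignment.labels.index):
        raise ValueError("assignment does not cover all matrix genes")
    vals = matrix.values
    ids = sorted(assignment.labels.unique())
    members = {c: [g for g in genes if assignment.labels[g] == c] for c in ids}

    within = {}
    for c in ids:
        m = members[c]
        if len(m) < 2:
            within[c] = np.nan  # singleton: no off-diagonal pairs
            continue
        block = vals.loc[m, m].to_numpy()
        off = block[~np.eye(len(m), dtype=bool)]
        within[c] = float(off.mean())

    neg = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for a in ids:
        for b in ids:
            block = vals.loc[members[a], members[b]]
            if a == b:
                # exclude self-correlations from each gene's mean
                arr = block.to_numpy(dtype=float).copy()
                np.fill_diagonal(arr, np.nan)
                gene_means = np.nanmean(arr, axis=0) if len(members[a]) > 1 else np.array([np.nan])
            else:
                gene_means = block.mean(axis=0).to_numpy()
            neg.loc[a, b] = float(np.mean(gene_means < 0))
    return pd.Series(within, name="within_mean_r"), neg


def write_assignment(assignment: ClusterAssignment, path) -> None:
    assignment.labels.rename_axis("gene").to_csv(path, sep="\t")
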
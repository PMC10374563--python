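"""Hierarchical clustering of SVGs by Jaccard distance over hotspot sets.

Because genes with the same spatial aggregation pattern can differ wildly
in expression magnitude, clustering operates on the binary hotspot vectors:
the distance between two genes is one minus the Jaccard coefficient of
their hotspot-spot sets. Agglomerative clustering (average linkage by
default) on that distance matrix groups SVGs into spatial-pattern clusters,
and each cluster is summarized by its hotspot-frequency map: per spot, the
fraction of member genes calling that spot a hotspot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .hotspots import HotspotMatrix

logger = logging.getLogger("svgrank")

DEFAULT_LINKAGE = "average"
DEFAULT_NEIGHBOR_SIMILARITY = 0.2
_LINKAGES = {"average", "complete", "single"}


@dataclass
class SVGClusterAssignment:
    """Gene -> cluster labels (contiguous 1..n_clusters) plus the dendrogram."""

    gene_ids: list[str]
    labels: np.ndarray
    linkage: str
    n_clusters: int
    merge_heights: np.ndarray
    linkage_matrix: np.ndarray

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.labels) if c == cluster]


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| for binary vectors of equal length.

    Two all-zero vectors have no defined Jaccard coefficient; their
    distance is reported as 1 with a warning.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    union = int((a | b).sum())
    if union == 0:
        warnings.warn(
            "Jaccard distance of two all-zero vectors is undefined; using 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - int((a & b).sum()) / union


def pairwise_jaccard(X: np.ndarray) -> np.ndarray:
    """Condensed Jaccard distance vector over the rows of a binary matrix."""
    Xb = np.asarray(X).astype(bool)
    inter = (Xb.astype(np.int64) @ Xb.T.astype(np.int64)).astype(np.float64)
    sizes = Xb.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - inter / union
    dist[union == 0] = 1.0
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_svgs(
    hm: HotspotMatrix,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    linkage: str = DEFAULT_LINKAGE,
) -> SVGClusterAssignment:
    """Agglomerative clustering of genes on Jaccard distance.

    Exactly one of ``n_clusters`` and ``distance_threshold`` selects the
    dendrogram cut. Genes whose hotspot vector is all zeros must be
    excluded upstream (their Jaccard distance is undefined).
    """
    if (n_clusters is None) == (distance_threshold is None):
        raise ValueError("specify exactly one of n_clusters / distance_threshold")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    X = hm.X
    n_genes = X.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes to cluster")
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(
            "genes with no hotspots cannot be clustered: "
            + ", ".join(hm.gene_ids[i] for i in zero[:5])
        )
    if n_clusters is not None and n_clusters > n_genes:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n_genes} genes")
    Z = sch.linkage(pairwise_jaccard(X), method=linkage)
    if n_clusters is not None:
        raw = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = sch.fcluster(Z, t=distance_threshold, criterion="distance")
    # relabel to contiguous 1..k in order of first appearance (deterministic)
    remap: dict[int, int] = {}
    labels = np.empty(n_genes, dtype=np.int64)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    k = len(remap)
    logger.info("cluster_svgs: %d genes -> %d clusters (%s linkage)",
                n_genes, k, linkage)
    return SVGClusterAssignment(
        list(hm.gene_ids), labels, linkage, k, Z[:, 2].copy(), Z
    )


def exclude_zero_hotspot_genes(hm: HotspotMatrix) -> HotspotMatrix:
    """Drop genes with no hotspots (warning); Jaccard needs nonzero vectors."""
    keep = hm.X.sum(axis=1) > 0
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(
            f"excluding {n_drop} gene(s) with no hotspots from clustering",
            stacklevel=2,
        )
    idx = np.flatnonzero(keep)
    return HotspotMatrix(
        hm.X[idx],
        [hm.gene_ids[i] for i in idx],
        hm.spot_ids,
        hm.fdr_threshold,
        hm.p_raw[idx] if hm.p_raw is not None else None,
        hm.p_adj[idx] if hm.p_adj is not None else None,
    )


def cluster_frequency(
    hm: HotspotMatrix, assignment: SVGClusterAssignment
) -> pd.DataFrame:
    """Per-cluster, per-spot mean of member genes' hotspot indicators.

    Returns a DataFrame with clusters as rows (index = cluster label) and
    spots as columns; every value lies in [0, 1].
    """
    gene_pos = {g: i for i, g in enumerate(hm.gene_ids)}
    missing = [g for g in assignment.gene_ids if g not in gene_pos]
    if missing:
        raise ValueError(f"assignment covers genes absent from matrix: {missing[:5]}")
    rows = {}
    for c in range(1, assignment.n_clusters + 1):
        idx = [gene_pos[g] for g in assignment.members(c)]
        rows[c] = hm.X[idx].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=hm.spot_ids)


def neighbor_clusters(
    freq: pd.DataFrame, similarity_threshold: float = DEFAULT_NEIGHBOR_SIMILARITY
) -> set[tuple[int, int]]:
    """Cluster pairs whose frequency maps have cosine similarity >= threshold.

    This operationalizes "overlapped/neighbor clusters" for restricting the
    combinatorial search: two clusters are neighbors when their hotspot
    footprints substantially overlap.
    """
    F = freq.to_numpy(dtype=np.float64)
    norms = np.linalg.norm(F, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (F @ F.T) / np.outer(safe, safe)
    labels = list(freq.index)
    pairs = set()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if norms[i] > 0 and norms[j] > 0 and sim[i, j] >= similarity_threshold:
                pairs.add((int(labels[i]), int(labels[j])))
    return pairs


def write_assignment(assignment: SVGClusterAssignment, path) -> None:
    pd.DataFrame(
        {"gene_id": assignment.gene_ids, "cluster": assignment.labels}
    ).to_csv(path, sep="\t", index=False)


def write_frequency(freq: pd.DataFrame, path) -> None:
    """Long TSV: cluster, spot, frequency."""
    long = freq.reset_index(names="cluster").melt(
        id_vars="cluster", var_name="spot", value_name="frequency"
    )
    long.to_csv(path, sep="\t", index=False)
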
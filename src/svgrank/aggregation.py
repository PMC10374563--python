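"""The aggregation index: a per-gene score of hotspot spatial clumping.

For a gene with hotspot indicator h over spots, the local aggregation
density at a hotspot spot i is the p-value-weighted fraction of its K
nearest neighbors that are themselves hotspots:

    D_i = sum_{j in KNN(i)} w_j h_j,
    w_j = log(p_j) / sum_{l in KNN(i)} log(p_l)

where p_j is the neighbor's raw local-Moran p-value. With every p in (0,1)
both numerator and denominator are negative, so the weights are nonnegative
and sum to one; a neighbor with p = 1 contributes zero weight, so smaller
(more significant) neighbor p-values count more. The aggregation index is
the mean density over the gene's n_g hotspots:

    AI_g = sum_i D_i / n_g,      AI_g := 0 when n_g = 0.

AI lies in [0, 1]; a solid hotspot block whose every hotspot has an
all-hotspot neighborhood scores 1, scattered isolated hotspots score 0.
Genes are ranked by descending AI, ties broken by descending hotspot count
then ascending gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hotspots import HotspotMatrix
from .preprocess import SpotLattice

logger = logging.getLogger("svgrank")

DEFAULT_TOP_K = 500
P_WEIGHT_FLOOR = 1e-300  # keeps log(p) finite


@dataclass
class AggregationTable:
    """Per-gene aggregation index, hotspot count and rank (1 = highest AI)."""

    table: pd.DataFrame  # columns: gene_id, AI, n_hotspots, rank

    def top(self, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
        return self.table.nsmallest(min(k, len(self.table)), "rank")

    def gene_rank(self, gene_id: str) -> int:
        sub = self.table.loc[self.table["gene_id"] == gene_id, "rank"]
        if sub.empty:
            raise KeyError(gene_id)
        return int(sub.iloc[0])


def local_density(
    hot_row: np.ndarray, pvals: np.ndarray, lattice: SpotLattice
) -> tuple[np.ndarray, np.ndarray]:
    """Local aggregation density D_i at each of the gene's hotspot spots.

    Returns ``(hotspot_indices, D)``. If every neighbor of a hotspot has
    p = 1 exactly, the weights degenerate (log 1 = 0 everywhere) and
    uniform weights 1/K are used instead.
    """
    hot_row = np.asarray(hot_row)
    pvals = np.asarray(pvals, dtype=np.float64)
    if hot_row.size != lattice.n_spots or pvals.size != lattice.n_spots:
        raise ValueError("hot_row/pvals length does not match lattice")
    if np.isnan(pvals).any():
        raise ValueError("p-values contain NaN")
    hotspots = np.flatnonzero(hot_row)
    if hotspots.size == 0:
        return hotspots, np.empty(0)
    logs = np.log(np.clip(pvals, P_WEIGHT_FLOOR, 1.0))
    nb = lattice.neighbor_idx[hotspots]            # (n_hot, K)
    lw = logs[nb]
    denom = lw.sum(axis=1)
    h_nb = hot_row[nb].astype(np.float64)
    K = lattice.K
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = (lw * h_nb).sum(axis=1) / denom
    uniform = h_nb.mean(axis=1)
    D = np.where(denom != 0.0, weighted, uniform)
    return hotspots, D


def aggregation_index(
    hot_row: np.ndarray, pvals: np.ndarray, lattice: SpotLattice
) -> tuple[float, int]:
    """Mean local density over the gene's hotspots; (0, 0) with no hotspots."""
    hotspots, D = local_density(hot_row, pvals, lattice)
    if hotspots.size == 0:
        return 0.0, 0
    return float(D.mean()), int(hotspots.size)


def rank_genes(
    hm: HotspotMatrix, lattice: SpotLattice, pvals: np.ndarray | None = None
) -> AggregationTable:
    """Aggregation index and rank for every gene in a hotspot matrix.

    ``pvals`` defaults to the raw local-Moran p-values stored in ``hm``
    (the test's own p-values, not the BH-adjusted ones, enter the weights).
    """
    if pvals is None:
        if hm.p_raw is None:
            raise ValueError("hotspot matrix carries no p-values; pass pvals")
        pvals = hm.p_raw
    rows = []
    for g, gid in enumerate(hm.gene_ids):
        ai, n_hot = aggregation_index(hm.X[g], pvals[g], lattice)
        rows.append((gid, ai, n_hot))
    df = pd.DataFrame(rows, columns=["gene_id", "AI", "n_hotspots"])
    df = df.sort_values(
        ["AI", "n_hotspots", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    logger.info(
        "rank_genes: %d genes, %d with >=1 hotspot, top AI = %.3f",
        len(df), int((df["n_hotspots"] > 0).sum()),
        df["AI"].iloc[0] if len(df) else float("nan"),
    )
    return AggregationTable(df)


def write_aggregation(at: AggregationTable, path, top_k: int | None = None) -> None:
    df = at.table if top_k is None else at.top(top_k)
    df.to_csv(path, sep="\t", index=False)


def read_aggregation(path) -> AggregationTable:
    return AggregationTable(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))
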
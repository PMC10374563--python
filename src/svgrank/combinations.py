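"""Pairwise co-localization / exclusion scoring of SVGs and joint hotspot maps.

With X the binary genes x spots hotspot matrix restricted to the selected
genes, the co-localization and exclusion count matrices are

    C = X . X^T            C_ij = # spots hot for both i and j
    E = (1 - X) . X^T      E_ij = # spots hot for j but not i

so C is symmetric with C_ii the hotspot count of gene i, E is generally
asymmetric with zero diagonal, and C_ij + E_ij = C_jj for every pair (every
j-hotspot is either shared with i or not). Pairs are ranked by raw C
(co-localization) or by the symmetrized min(E_ij, E_ji) (exclusion —
mutual exclusion requires both directions); a normalized overlap
coefficient C_ij / min(C_ii, C_jj) is reported as an extra column. The
search space is optionally restricted to pairs within the same SVG cluster
or within neighboring (overlapping-footprint) clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations as iter_pairs

import numpy as np
import pandas as pd

from .hotspots import HotspotMatrix
from .svg_clustering import SVGClusterAssignment

logger = logging.getLogger("svgrank")

SCOPES = ("same_cluster", "neighbor_clusters", "all")
MODES = ("colocalization", "exclusion")


@dataclass
class CombinationScores:
    """Pairwise co-localization (C) and exclusion (E) counts over m genes."""

    gene_ids: list[str]
    C: np.ndarray
    E: np.ndarray
    n_spots: int

    def pair(self, a: str, b: str) -> tuple[int, int, int]:
        """(C_ab, E_ab, E_ba) for a named gene pair."""
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return int(self.C[i, j]), int(self.E[i, j]), int(self.E[j, i])


def score_combinations(hm: HotspotMatrix) -> CombinationScores:
    """Exact integer C = X.X^T and E = (1-X).X^T over the matrix's genes."""
    X = np.asarray(hm.X)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("hotspot matrix must be binary")
    Xi = X.astype(np.int64)
    C = Xi @ Xi.T
    E = (1 - Xi) @ Xi.T
    return CombinationScores(list(hm.gene_ids), C, E, X.shape[1])


def rank_pairs(
    scores: CombinationScores,
    assignment: SVGClusterAssignment | None = None,
    mode: str = "colocalization",
    scope: str = "all",
    neighbor_pairs: set[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Ordered gene-pair table under a cluster scope.

    scope="same_cluster" keeps pairs whose genes share a cluster;
    "neighbor_clusters" additionally keeps pairs whose clusters are in
    ``neighbor_pairs`` (as produced by
    :func:`svgrank.svg_clustering.neighbor_clusters`); "all" keeps every
    pair. Ranking is by descending C_ij (colocalization) or descending
    min(E_ij, E_ji) (exclusion); ties break lexicographically on the gene
    pair. Columns: gene_a, gene_b, C, E_ab, E_ba, normalized_overlap,
    scope, rank.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if scope != "all" and assignment is None:
        raise ValueError(f"scope={scope!r} requires a cluster assignment")
    if scope == "neighbor_clusters" and neighbor_pairs is None:
        raise ValueError("scope='neighbor_clusters' requires neighbor_pairs")
    label_of = {}
    if assignment is not None:
        label_of = dict(zip(assignment.gene_ids, assignment.labels))
        missing = [g for g in scores.gene_ids if g not in label_of]
        if missing:
            raise ValueError(f"assignment does not cover genes: {missing[:5]}")
    rows = []
    m = len(scores.gene_ids)
    for i, j in iter_pairs(range(m), 2):
        ga, gb = scores.gene_ids[i], scores.gene_ids[j]
        if scope != "all":
            ca, cb = label_of[ga], label_of[gb]
            same = ca == cb
            neighbor = (
                same
                or (min(ca, cb), max(ca, cb)) in (neighbor_pairs or set())
            )
            if scope == "same_cluster" and not same:
                continue
            if scope == "neighbor_clusters" and not neighbor:
                continue
        c = int(scores.C[i, j])
        e_ab, e_ba = int(scores.E[i, j]), int(scores.E[j, i])
        denom = min(scores.C[i, i], scores.C[j, j])
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "C": c,
                "E_ab": e_ab,
                "E_ba": e_ba,
                "E_min": min(e_ab, e_ba),
                "normalized_overlap": c / denom if denom > 0 else 0.0,
                "scope": scope,
            }
        )
    if not rows:
        warnings.warn(f"no gene pairs in scope {scope!r}", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "C", "E_ab", "E_ba", "E_min",
                     "normalized_overlap", "scope", "rank"]
        )
    df = pd.DataFrame(rows)
    key = "C" if mode == "colocalization" else "E_min"
    df = df.sort_values(
        [key, "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def joint_hotspot_map(
    hm: HotspotMatrix, gene_ids: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Categorical per-spot labels for a 2- or 3-gene hotspot combination.

    Each spot is labeled by the subset of the chosen genes calling it a
    hotspot ("A+B" style, "none" when no gene does). Returns
    ``(labels, counts)``: labels indexed by spot id, counts per category.
    Category sizes reproduce the C/E entries by construction:
    for a pair (A, B), #("A+B") = C_AB and #("B" alone) = E_AB.
    """
    if not 2 <= len(gene_ids) <= 3:
        raise ValueError(
            "joint hotspot maps cover 2 or 3 genes; for more genes use "
            "pairwise scoring"
        )
    rows = np.stack([hm.row(g) for g in gene_ids])
    labels = []
    for s in range(rows.shape[1]):
        active = [g for g, v in zip(gene_ids, rows[:, s]) if v]
        labels.append("+".join(active) if active else "none")
    labels = pd.Series(labels, index=hm.spot_ids, name="category")
    counts = labels.value_counts()
    return labels, counts


def write_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_joint_map(labels: pd.Series, path) -> None:
    labels.rename_axis("spot").reset_index().to_csv(path, sep="\t", index=False)
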
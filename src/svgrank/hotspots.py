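"""Per-gene hotspot detection via local Moran's I.

A hotspot is a spot with significantly high expression amid high-expressing
neighbors. For gene values v over n spots with centered values
z = v - mean(v) and m2 = sum(z^2)/n, the local Moran statistic at spot i is

    I_i = (z_i / m2) * sum_j w_ij z_j

with w row-standardized over the spot's K nearest neighbors (weight 1/K
each). Significance is assessed one-sidedly (aggregation only) either by
conditional permutation — hold z_i fixed, redraw its K neighbor values from
the remaining spots — or by a normal approximation with the exact
conditional mean and variance of the permutation distribution:

    E[lag_i]   = -z_i / (n-1)
    Var[lag_i] = s2_i * (n-1-K) / (K*(n-2)),   s2_i = Var of the other z's

so E[I_i] = z_i*E[lag_i]/m2 and sd[I_i] = |z_i|*sd[lag_i]/m2. Per-gene
p-values are Benjamini-Hochberg adjusted across spots and thresholded at an
FDR level (default 0.05); the high-high quadrant condition (z_i > 0 and
positive spatial lag) restricts calls to genuine high-amid-high spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix, SpotLattice

logger = logging.getLogger("svgrank")

DEFAULT_FDR = 0.05
DEFAULT_N_PERMUTATIONS = 999
ANALYTIC_P_FLOOR = 1e-300


@dataclass
class LocalMoranResult:
    """Local Moran's I for one gene over all spots."""

    gene_id: str
    I: np.ndarray
    z: np.ndarray
    lag: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_permutations: int = 0  # 0 = analytic normal approximation
    constant: bool = False   # all values identical: I := 0, p := 1


@dataclass
class HotspotMatrix:
    """Binary genes x spots hotspot indicator plus per-gene p-values."""

    X: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    fdr_threshold: float = DEFAULT_FDR
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("hotspot matrix entries must be 0/1")
        self.X = self.X.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_spots(self) -> int:
        return self.X.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.X[self.gene_ids.index(gene_id)]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _conditional_moments(z: np.ndarray, m2: float, K: int):
    """Exact mean/variance of I_i under conditional permutation of the
    non-focal values (sampling K of the remaining n-1 without replacement)."""
    n = z.size
    mu_others = -z / (n - 1)
    s2_raw = (n * m2 - z**2) / (n - 1)      # E[z^2] over the others
    var_others = np.maximum(s2_raw - mu_others**2, 0.0)
    var_lag = var_others * (n - 1 - K) / (K * (n - 2))
    e_i = z * mu_others / m2
    sd_i = np.abs(z) / m2 * np.sqrt(np.maximum(var_lag, 0.0))
    return e_i, sd_i


def local_morans_i(
    values: np.ndarray,
    lattice: SpotLattice,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    analytic: bool = False,
    gene_id: str = "",
) -> LocalMoranResult:
    """Local Moran's I with one-sided p-values for a single gene.

    Permutation mode (default) draws, for each spot in index order, a fresh
    ``rng.permutation(n-1)[:K]`` index sample per permutation from a single
    ``numpy.random.default_rng(seed)`` stream, recomputes the statistic, and
    reports the pseudo p-value ``(#{I_perm >= I_obs} + 1)/(n_permutations+1)``.
    Analytic mode replaces the permutation tail by a normal tail with the
    exact conditional moments; it is the fast choice for many genes.

    Constant input yields I = 0 and p = 1 everywhere (flagged, no error).
    """
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    n = values.size
    if n != lattice.n_spots:
        raise ValueError("values length does not match lattice")
    K = lattice.K
    z = values - values.mean()
    m2 = float((z**2).sum() / n)
    if m2 == 0.0 or np.all(values == values[0]):
        ones = np.ones(n)
        return LocalMoranResult(
            gene_id, np.zeros(n), z, np.zeros(n), ones, ones,
            0 if analytic else n_permutations, constant=True,
        )
    lag = z[lattice.neighbor_idx].mean(axis=1)
    I = z * lag / m2

    if analytic:
        e_i, sd_i = _conditional_moments(z, m2, K)
        with np.errstate(divide="ignore", invalid="ignore"):
            zscore = np.where(sd_i > 0, (I - e_i) / np.where(sd_i > 0, sd_i, 1.0), 0.0)
        p_raw = np.where(sd_i > 0, norm.sf(zscore), 1.0)
        p_raw = np.clip(p_raw, ANALYTIC_P_FLOOR, 1.0)
        n_perm_used = 0
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        p_raw = np.empty(n)
        all_idx = np.arange(n)
        for i in range(n):
            others = z[np.delete(all_idx, i)]
            count = 0
            for _ in range(n_permutations):
                pick = rng.permutation(n - 1)[:K]
                lag_perm = others[pick].mean()
                if z[i] * lag_perm / m2 >= I[i]:
                    count += 1
            p_raw[i] = (count + 1) / (n_permutations + 1)
        n_perm_used = n_permutations

    p_adj = bh_adjust(p_raw)
    return LocalMoranResult(gene_id, I, z, lag, p_raw, p_adj, n_perm_used)


def local_morans_i_matrix(
    nm: NormalizedMatrix, lattice: SpotLattice
) -> list[LocalMoranResult]:
    """Analytic local Moran's I for every gene at once (vectorized)."""
    V = nm.dense()
    n_genes, n = V.shape
    K = lattice.K
    Z = V - V.mean(axis=1, keepdims=True)
    m2 = (Z**2).sum(axis=1) / n
    W = lattice.weights()
    lag = np.asarray(Z @ W.T.todense())
    results: list[LocalMoranResult] = []
    ones = np.ones(n)
    for g in range(n_genes):
        gid = nm.gene_ids[g]
        if m2[g] == 0.0:
            results.append(
                LocalMoranResult(
                    gid, np.zeros(n), Z[g], np.zeros(n), ones.copy(),
                    ones.copy(), 0, constant=True,
                )
            )
            continue
        I = Z[g] * lag[g] / m2[g]
        e_i, sd_i = _conditional_moments(Z[g], m2[g], K)
        with np.errstate(divide="ignore", invalid="ignore"):
            zscore = np.where(sd_i > 0, (I - e_i) / np.where(sd_i > 0, sd_i, 1.0), 0.0)
        p_raw = np.where(sd_i > 0, norm.sf(zscore), 1.0)
        p_raw = np.clip(p_raw, ANALYTIC_P_FLOOR, 1.0)
        results.append(
            LocalMoranResult(gid, I, Z[g], lag[g], p_raw, bh_adjust(p_raw), 0)
        )
    return results


def call_hotspots(
    results: list[LocalMoranResult],
    fdr_threshold: float = DEFAULT_FDR,
    require_positive_lag: bool = True,
    spot_ids: list[str] | None = None,
) -> HotspotMatrix:
    """Threshold BH-adjusted p-values into the binary hotspot matrix.

    A spot is a hotspot for a gene iff p_adj <= fdr_threshold, its centered
    value is positive and (by default) its spatial lag is positive — the
    high-high quadrant of the Moran scatterplot. BH is applied per gene
    across its spots; there is no cross-gene adjustment.
    """
    if not results:
        raise ValueError("no local Moran results supplied")
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must be in (0, 1]")
    n = results[0].p_adj.size
    if any(r.p_adj.size != n for r in results):
        raise ValueError("results cover differing spot sets")
    X = np.zeros((len(results), n), dtype=np.int8)
    p_raw = np.ones((len(results), n))
    p_adj = np.ones((len(results), n))
    for g, r in enumerate(results):
        p_raw[g] = r.p_raw
        p_adj[g] = r.p_adj
        hot = (r.p_adj <= fdr_threshold) & (r.z > 0)
        if require_positive_lag:
            hot &= r.lag > 0
        X[g] = hot.astype(np.int8)
    gene_ids = [r.gene_id for r in results]
    if spot_ids is None:
        spot_ids = [str(i) for i in range(n)]
    elif len(spot_ids) != n:
        raise ValueError("spot_ids length does not match results")
    hm = HotspotMatrix(X, gene_ids, spot_ids, fdr_threshold, p_raw, p_adj)
    logger.info(
        "call_hotspots: %d genes, %d spots, %d hotspot calls at FDR %g",
        hm.n_genes, hm.n_spots, int(X.sum()), fdr_threshold,
    )
    return hm


def global_morans_i(values: np.ndarray, lattice: SpotLattice) -> float:
    """Global Moran's I under the same row-standardized KNN weights.

    Identity used in testing: mean of the local statistics equals the
    global statistic.
    """
    values = np.asarray(values, dtype=np.float64)
    z = values - values.mean()
    denom = (z**2).sum()
    if denom == 0:
        return 0.0
    lag = z[lattice.neighbor_idx].mean(axis=1)
    return float((z * lag).sum() / denom)


def write_hotspots(hm: HotspotMatrix, path) -> None:
    """Long-format TSV: gene, spot, p_raw, p_adj, hotspot."""
    import pandas as pd

    rows = []
    for g, gid in enumerate(hm.gene_ids):
        rows.append(
            pd.DataFrame(
                {
                    "gene": gid,
                    "spot": hm.spot_ids,
                    "p_raw": hm.p_raw[g] if hm.p_raw is not None else np.nan,
                    "p_adj": hm.p_adj[g] if hm.p_adj is not None else np.nan,
                    "hotspot": hm.X[g],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_hotspots_mtx(hm: HotspotMatrix, outdir) -> dict[str, str]:
    """Sparse binary MTX plus gene/spot ID sidecars (no p-values)."""
    from pathlib import Path

    import scipy.io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "hotspots.mtx",
        "genes": outdir / "hotspot_genes.tsv",
        "spots": outdir / "hotspot_spots.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(hm.X))
    paths["genes"].write_text("".join(g + "\n" for g in hm.gene_ids))
    paths["spots"].write_text("".join(s + "\n" for s in hm.spot_ids))
    return {k: str(v) for k, v in paths.items()}


def read_hotspots_mtx(outdir) -> HotspotMatrix:
    from pathlib import Path

    import scipy.io

    outdir = Path(outdir)
    X = np.asarray(
        sp.csr_matrix(scipy.io.mmread(str(outdir / "hotspots.mtx"))).todense()
    )
    genes = (outdir / "hotspot_genes.tsv").read_text().split()
    spots = (outdir / "hotspot_spots.tsv").read_text().split()
    return HotspotMatrix(X, genes, spots)


def read_hotspots(path) -> HotspotMatrix:
    """Read the long-format TSV written by :func:`write_hotspots`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "spot": str})
    gene_ids = list(dict.fromkeys(df["gene"]))
    spot_ids = list(dict.fromkeys(df["spot"]))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    spos = {s: i for i, s in enumerate(spot_ids)}
    X = np.zeros((len(gene_ids), len(spot_ids)), dtype=np.int8)
    p_raw = np.ones_like(X, dtype=float)
    p_adj = np.ones_like(X, dtype=float)
    gi = df["gene"].map(gpos).to_numpy()
    si = df["spot"].map(spos).to_numpy()
    X[gi, si] = df["hotspot"].to_numpy()
    p_raw[gi, si] = df["p_raw"].to_numpy()
    p_adj[gi, si] = df["p_adj"].to_numpy()
    return HotspotMatrix(X, gene_ids, spot_ids, p_raw=p_raw, p_adj=p_adj)
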
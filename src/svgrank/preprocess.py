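"""Input handling, gene filtering, log-normalization and the spot KNN graph.

Counts are held genes-by-spots throughout the package (the common indexing
in spatial statistics writes spots as *i* and genes as *j*; that orientation
is transposed here so that gene-wise operations are row operations).

Normalization follows the standard library-size/log1p transform used for
UMI data::

    r'_gj = ln( r_gj * scale_factor / sum_g r_gj  +  1 )

i.e. each spot's counts are scaled to ``scale_factor`` total, then
natural-log transformed with a pseudocount of one.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("svgrank")

DEFAULT_SCALE_FACTOR = 10_000.0
DEFAULT_MIN_SPOT_FRACTION = 0.01
DEFAULT_MIN_TOTAL_UMI = 10
DEFAULT_K = 6


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw UMI counts, genes x spots, with gene and spot identifiers."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.spot_ids = list(self.spot_ids)
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_genes} rows"
            )
        if len(self.spot_ids) != n_spots:
            raise ValueError(
                f"spot_ids has {len(self.spot_ids)} entries for {n_spots} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if len(set(self.spot_ids)) != n_spots:
            raise ValueError("duplicate spot_ids")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x spots, natural-log scale."""

    values: sp.csr_matrix
    gene_ids: list[str]
    spot_ids: list[str]
    scale_factor: float = DEFAULT_SCALE_FACTOR

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("normalized values must be non-negative")

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class SpotLattice:
    """Spot coordinates plus the K-nearest-neighbor graph over them.

    ``neighbor_idx[i]`` holds the indices of spot *i*'s K nearest neighbors
    (self excluded), sorted by ascending Euclidean distance with ties broken
    by ascending spot index.
    """

    coords: np.ndarray
    neighbor_idx: np.ndarray
    neighbor_dist: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.neighbor_idx = np.asarray(self.neighbor_idx, dtype=np.int64)
        n = self.coords.shape[0]
        if self.neighbor_idx.shape != (n, self.K):
            raise ValueError("neighbor_idx shape does not match (n_spots, K)")
        if np.any(self.neighbor_idx == np.arange(n)[:, None]):
            raise ValueError("a spot may not be its own neighbor")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    def weights(self) -> sp.csr_matrix:
        """Row-standardized binary KNN weights (each neighbor gets 1/K)."""
        n = self.n_spots
        rows = np.repeat(np.arange(n), self.K)
        cols = self.neighbor_idx.ravel()
        data = np.full(n * self.K, 1.0 / self.K)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# Reading Spaceranger-style matrix directories
# ---------------------------------------------------------------------------

def _open_text(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path: Path, column: int = 0) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]


def deduplicate_ids(ids: list[str]) -> list[str]:
    """Disambiguate repeated identifiers by suffixing ``.1``, ``.2``, ..."""
    seen: dict[str, int] = {}
    out = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


_POSITIONS_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col",
]


def read_positions(positions_path: Path) -> pd.DataFrame:
    """Read a tissue-positions CSV in either Spaceranger dialect.

    The headered dialect names the pixel columns ``pxl_row_in_fullres`` /
    ``pxl_col_in_fullres``; the headerless one has the same six columns in
    fixed order. Both are normalized to columns
    barcode, in_tissue, array_row, array_col, pxl_row, pxl_col.
    """
    positions_path = Path(positions_path)
    with _open_text(positions_path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(positions_path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise FormatError(
            f"{positions_path}: expected 6 columns "
            "(barcode, in_tissue, array_row, array_col, pxl_row, pxl_col), "
            f"got {df.shape[1]}"
        )
    df = df.iloc[:, :6]
    df.columns = _POSITIONS_COLUMNS
    df["in_tissue"] = df["in_tissue"].astype(int)
    return df


def read_counts(
    matrix_path,
    barcodes_path,
    features_path,
    positions_path,
    use_array_coords: bool = False,
) -> tuple[CountMatrix, np.ndarray]:
    """Read an MTX + barcodes + features triplet plus a positions table.

    Returns the counts restricted to in-tissue spots together with the
    per-spot (x, y) coordinates aligned to ``spot_ids``. Coordinates default
    to full-resolution pixel columns (x = pxl_col, y = pxl_row); pass
    ``use_array_coords=True`` to use the array row/column indices instead.
    """
    matrix_path = Path(matrix_path)
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    barcodes = _read_id_column(Path(barcodes_path))
    features = _read_id_column(Path(features_path), column=0)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{matrix_path}: {mat.shape[0]} rows but {len(features)} features "
            f"in {features_path}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path}: {mat.shape[1]} columns but {len(barcodes)} barcodes "
            f"in {barcodes_path}"
        )
    positions = read_positions(positions_path)
    pos_by_barcode = positions.set_index("barcode")
    missing = [b for b in barcodes if b not in pos_by_barcode.index]
    if missing:
        raise FormatError(
            f"{positions_path}: barcodes absent from positions table: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    pos = pos_by_barcode.loc[barcodes]
    keep = pos["in_tissue"].to_numpy() == 1
    if not keep.any():
        raise FormatError(f"{positions_path}: no in-tissue spots")
    kept_barcodes = [b for b, k in zip(barcodes, keep) if k]
    mat = mat[:, np.flatnonzero(keep)]
    if use_array_coords:
        coords = pos.loc[keep, ["array_col", "array_row"]].to_numpy(float)
    else:
        coords = pos.loc[keep, ["pxl_col", "pxl_row"]].to_numpy(float)
    cm = CountMatrix(mat, deduplicate_ids(features), kept_barcodes)
    logger.info("read %d genes x %d in-tissue spots", cm.n_genes, cm.n_spots)
    return cm, coords


def write_counts(cm: CountMatrix, coords: np.ndarray, outdir) -> dict[str, str]:
    """Write MTX + barcodes/features + positions CSV readable by read_counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "positions": outdir / "tissue_positions.csv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(cm.counts))
    paths["barcodes"].write_text("".join(b + "\n" for b in cm.spot_ids))
    paths["features"].write_text("".join(g + "\n" for g in cm.gene_ids))
    coords = np.asarray(coords, float)
    pos = pd.DataFrame(
        {
            "barcode": cm.spot_ids,
            "in_tissue": 1,
            "array_row": np.arange(cm.n_spots),
            "array_col": np.arange(cm.n_spots),
            "pxl_row": coords[:, 1],
            "pxl_col": coords[:, 0],
        }
    )
    pos.to_csv(paths["positions"], index=False)
    return {k: str(v) for k, v in paths.items()}


def read_table_counts(table_path, coords_path) -> tuple[CountMatrix, np.ndarray]:
    """Read a generic TSV count table (genes x spots, first column gene ids)
    plus a 3-column coordinate CSV/TSV (spot_id, x, y)."""
    tab = pd.read_csv(table_path, sep="\t", index_col=0)
    coords_df = pd.read_csv(coords_path, sep=None, engine="python")
    if coords_df.shape[1] < 3:
        raise FormatError(f"{coords_path}: expected spot_id, x, y columns")
    coords_df = coords_df.set_index(coords_df.columns[0])
    missing = [s for s in tab.columns if s not in coords_df.index]
    if missing:
        raise FormatError(f"{coords_path}: missing spots {missing[:10]}")
    coords = coords_df.loc[tab.columns].iloc[:, :2].to_numpy(float)
    cm = CountMatrix(
        sp.csr_matrix(tab.to_numpy()),
        deduplicate_ids(list(tab.index)),
        list(tab.columns),
    )
    return cm, coords


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(
    cm: CountMatrix,
    min_spot_fraction: float = DEFAULT_MIN_SPOT_FRACTION,
    min_total_umi: int = DEFAULT_MIN_TOTAL_UMI,
) -> CountMatrix:
    """Drop genes detected in too few spots or with too few total UMIs.

    A gene is kept iff it is detected (count > 0) in strictly more than
    ``min_spot_fraction`` of spots AND its total UMI count across spots is
    at least ``min_total_umi``. The spot set is unchanged.
    """
    if not 0 <= min_spot_fraction <= 1:
        raise ValueError("min_spot_fraction must be in [0, 1]")
    detected = (cm.counts > 0).sum(axis=1).A1
    totals = cm.counts.sum(axis=1).A1
    frac_ok = detected > min_spot_fraction * cm.n_spots
    umi_ok = totals >= min_total_umi
    keep = frac_ok & umi_ok
    n_frac = int((~frac_ok).sum())
    n_umi = int((~umi_ok).sum())
    logger.info(
        "filter_genes: %d/%d kept (%d failed detection fraction > %g, "
        "%d failed total UMI >= %d)",
        int(keep.sum()), cm.n_genes, n_frac, min_spot_fraction, n_umi,
        min_total_umi,
    )
    if not keep.any():
        warnings.warn("filter_genes removed every gene", stacklevel=2)
    idx = np.flatnonzero(keep)
    return CountMatrix(
        cm.counts[idx], [cm.gene_ids[i] for i in idx], cm.spot_ids
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(
    cm: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Library-size normalize each spot to ``scale_factor`` and ln(1+x).

    Spots with zero total count keep all-zero columns (with a warning):
    dropping them would silently alter the KNN graph downstream.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.counts.sum(axis=0).A1.astype(np.float64)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} spot(s) have zero total count; "
            "their normalized columns are all zeros",
            stacklevel=2,
        )
    safe_totals = np.where(totals > 0, totals, 1.0)
    out = sp.coo_matrix(cm.counts, copy=True).astype(np.float64)
    out.data = np.log1p(out.data * scale_factor / safe_totals[out.col])
    return NormalizedMatrix(
        out.tocsr(), cm.gene_ids, cm.spot_ids, scale_factor
    )


# ---------------------------------------------------------------------------
# KNN graph
# ---------------------------------------------------------------------------

def build_knn(coords: np.ndarray, K: int = DEFAULT_K) -> SpotLattice:
    """Euclidean K-nearest-neighbor lists per spot, fully deterministic.

    Distance ties are broken by ascending spot index, so results are
    reproducible across platforms (a KD-tree's tie order is not). Computed
    by chunked exhaustive distances; fine up to tens of thousands of spots.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n_spots, 2) array")
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    n = coords.shape[0]
    if n < K + 1:
        raise ValueError(
            f"need at least K+1={K + 1} spots for K={K}; got {n}. "
            "Use a smaller K."
        )
    neighbor_idx = np.empty((n, K), dtype=np.int64)
    neighbor_dist = np.empty((n, K), dtype=np.float64)
    chunk = max(1, int(2e7) // max(n, 1))
    idx_all = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = (
            ((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        for r, i in enumerate(range(start, stop)):
            order = np.lexsort((idx_all, d2[r]))
            order = order[order != i][:K]
            neighbor_idx[i] = order
            neighbor_dist[i] = np.sqrt(d2[r][order])
    return SpotLattice(coords, neighbor_idx, neighbor_dist, K)


def write_lattice(lattice: SpotLattice, path) -> None:
    """Write the KNN graph as an edge-list TSV (spot_a, spot_b, rank, distance)."""
    n, K = lattice.neighbor_idx.shape
    df = pd.DataFrame(
        {
            "spot_a": np.repeat(np.arange(n), K),
            "spot_b": lattice.neighbor_idx.ravel(),
            "rank": np.tile(np.arange(1, K + 1), n),
            "distance": lattice.neighbor_dist.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_normalized(nm: NormalizedMatrix, path, fmt: str = "tsv") -> None:
    """Write the normalized matrix as TSV (genes x spots) or MTX."""
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(nm.values))
    else:
        pd.DataFrame(
            nm.dense(), index=nm.gene_ids, columns=nm.spot_ids
        ).to_csv(path, sep="\t")
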
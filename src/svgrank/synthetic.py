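"""Visium-like synthetic datasets with planted spatial structure.

Spots sit on a hexagonal (or square) lattice; a set of geometric regions
(disk, annulus, half-plane, stripe) defines where planted spatially
variable genes (SVGs) are enriched. Each gene's per-spot mean is
``mean_in`` inside its target region and ``mean_out`` outside; noise genes
use one mean everywhere. Counts are drawn per gene from a Poisson or a
negative-binomial (gamma-Poisson) model — the NB dispersion theta gives
variance mu + mu^2/theta, the over-dispersion typical of UMI counts.
Everything is seeded and bit-reproducible, and outputs use the same
MTX/CSV dialects the input readers consume, so the whole pipeline is
testable offline with known ground truth.

The hex lattice places row r, column c at
x = c + 0.5*(r mod 2), y = r*sqrt(3)/2, so every interior spot has exactly
six equidistant neighbors — the Visium geometry that motivates K = 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from .preprocess import CountMatrix, write_counts

logger = logging.getLogger("svgrank")

HEX_ROW_SPACING = np.sqrt(3.0) / 2.0
REGION_SHAPES = ("disk", "annulus", "halfplane", "stripe")


@dataclass
class Region:
    """A planted spatial region on the lattice."""

    shape: str
    params: dict
    region_id: int

    def contains(self, coords: np.ndarray) -> np.ndarray:
        x, y = coords[:, 0], coords[:, 1]
        p = self.params
        if self.shape == "disk":
            return (x - p["cx"]) ** 2 + (y - p["cy"]) ** 2 <= p["radius"] ** 2
        if self.shape == "annulus":
            d2 = (x - p["cx"]) ** 2 + (y - p["cy"]) ** 2
            return (d2 >= p["r_inner"] ** 2) & (d2 <= p["r_outer"] ** 2)
        if self.shape == "halfplane":
            return p["a"] * x + p["b"] * y >= p["c"]
        if self.shape == "stripe":
            proj = p["a"] * x + p["b"] * y
            return (proj >= p["lo"]) & (proj <= p["hi"])
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass
class SyntheticGene:
    gene_id: str
    region_id: int | str  # a Region id, or "noise"
    mean_in: float
    mean_out: float
    dispersion: float = 2.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset; serializes to YAML."""

    lattice: str = "hex"
    n_rows: int = 40
    n_cols: int = 40
    regions: list[Region] = field(default_factory=list)
    genes: list[SyntheticGene] = field(default_factory=list)
    count_model: str = "negative_binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice not in ("hex", "square"):
            raise ValueError("lattice must be 'hex' or 'square'")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError("count_model must be poisson or negative_binomial")
        for g in self.genes:
            if g.region_id != "noise" and g.mean_in <= g.mean_out:
                raise ValueError(
                    f"planted SVG {g.gene_id}: mean_in must exceed mean_out"
                )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["regions"] = [Region(**r) for r in raw.get("regions", [])]
        raw["genes"] = [SyntheticGene(**g) for g in raw.get("genes", [])]
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth: per-spot region labels and per-gene class/target."""

    region_labels: np.ndarray        # 0 = background, else region_id
    gene_class: dict[str, str]       # gene_id -> "svg" | "noise"
    gene_region: dict[str, int | None]

    def svg_ids(self) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == "svg"]

    def noise_ids(self) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == "noise"]


def lattice_coords(lattice: str, n_rows: int, n_cols: int) -> np.ndarray:
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    if lattice == "hex":
        x = cols + 0.5 * (rows % 2)
        y = rows * HEX_ROW_SPACING
    else:
        x = cols.astype(float)
        y = rows.astype(float)
    return np.column_stack([x, y]).astype(np.float64)


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, np.ndarray, SyntheticTruth]:
    """Draw a seeded synthetic dataset from its specification.

    Counts for each gene are drawn in gene order from a single
    ``numpy.random.default_rng(spec.seed)`` stream, so output is
    bit-reproducible for a fixed spec.
    """
    coords = lattice_coords(spec.lattice, spec.n_rows, spec.n_cols)
    n_spots = coords.shape[0]
    region_masks: dict[int, np.ndarray] = {}
    region_labels = np.zeros(n_spots, dtype=np.int64)
    for reg in spec.regions:
        mask = reg.contains(coords)
        if not mask.any():
            raise ValueError(f"region {reg.region_id} contains no spots")
        region_masks[reg.region_id] = mask
        unclaimed = mask & (region_labels == 0)
        region_labels[unclaimed] = reg.region_id

    rng = np.random.default_rng(spec.seed)
    counts = np.empty((len(spec.genes), n_spots), dtype=np.int64)
    gene_class: dict[str, str] = {}
    gene_region: dict[str, int | None] = {}
    for g, gene in enumerate(spec.genes):
        if gene.region_id == "noise":
            mu = np.full(n_spots, float(gene.mean_out))
            gene_class[gene.gene_id] = "noise"
            gene_region[gene.gene_id] = None
        else:
            if gene.region_id not in region_masks:
                raise ValueError(
                    f"gene {gene.gene_id} targets unknown region {gene.region_id}"
                )
            mask = region_masks[gene.region_id]
            mu = np.where(mask, float(gene.mean_in), float(gene.mean_out))
            gene_class[gene.gene_id] = "svg"
            gene_region[gene.gene_id] = gene.region_id
        if spec.count_model == "poisson":
            counts[g] = rng.poisson(mu)
        else:
            theta = float(gene.dispersion)
            lam = rng.gamma(shape=theta, scale=mu / theta)
            counts[g] = rng.poisson(lam)
    gene_ids = [g.gene_id for g in spec.genes]
    spot_ids = [f"spot_{i:05d}" for i in range(n_spots)]
    cm = CountMatrix(counts, gene_ids, spot_ids)
    truth = SyntheticTruth(region_labels, gene_class, gene_region)
    logger.info(
        "generated %d genes x %d spots (%d planted SVGs, %d noise genes)",
        cm.n_genes, cm.n_spots,
        sum(c == "svg" for c in gene_class.values()),
        sum(c == "noise" for c in gene_class.values()),
    )
    return cm, coords, truth


def spatial_shuffle(cm: CountMatrix, gene_id: str, seed: int) -> CountMatrix:
    """Permute one gene's counts across spots (histogram preserved exactly).

    This is the spatial null: the gene keeps its count distribution but
    loses all spatial structure.
    """
    g = cm.gene_index(gene_id)
    rng = np.random.default_rng(seed)
    dense = np.asarray(cm.counts.todense())
    dense[g] = rng.permutation(dense[g])
    return CountMatrix(dense, cm.gene_ids, cm.spot_ids)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (permutation model)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.size == 0 or labels_b.size == 0:
        raise ValueError("label vectors must be non-empty")
    if labels_a.size != labels_b.size:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------------------------
# The standard benchmark
# ---------------------------------------------------------------------------

def default_benchmark(seed: int = 0) -> SyntheticSpec:
    """The shipped benchmark: 40x40 hex lattice, three disjoint regions
    (disk, annulus, stripe), 10 planted SVGs per region, 200 noise genes,
    negative binomial with dispersion 2.0.

    Means (in-region 4.0 UMI/spot vs 0.2 outside; noise 0.5 everywhere)
    reflect the strong regional markers vs low ambient background typical
    of Visium data.
    """
    regions = [
        Region("disk", {"cx": 10.0, "cy": 8.0, "radius": 6.0}, 1),
        Region("annulus", {"cx": 29.0, "cy": 9.0, "r_inner": 3.0, "r_outer": 7.0}, 2),
        Region("stripe", {"a": 0.0, "b": 1.0, "lo": 24.0, "hi": 30.0}, 3),
    ]
    genes = []
    for r in (1, 2, 3):
        for i in range(10):
            genes.append(
                SyntheticGene(f"svg_r{r}_{i:02d}", r, mean_in=4.0,
                              mean_out=0.2, dispersion=2.0)
            )
    for i in range(200):
        genes.append(
            SyntheticGene(f"noise_{i:03d}", "noise", mean_in=0.5,
                          mean_out=0.5, dispersion=2.0)
        )
    return SyntheticSpec(
        lattice="hex", n_rows=40, n_cols=40, regions=regions, genes=genes,
        count_model="negative_binomial", seed=seed,
    )


def export(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Generate and write the dataset plus truth TSVs to a directory."""
    from pathlib import Path

    cm, coords, truth = generate(spec)
    paths = write_counts(cm, coords, outdir)
    outdir = Path(outdir)
    spot_truth = outdir / "truth_spots.tsv"
    pd.DataFrame(
        {"spot_id": cm.spot_ids, "region": truth.region_labels}
    ).to_csv(spot_truth, sep="\t", index=False)
    gene_truth = outdir / "truth_genes.tsv"
    pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "class": [truth.gene_class[g] for g in cm.gene_ids],
            "region": [
                truth.gene_region[g] if truth.gene_region[g] is not None else ""
                for g in cm.gene_ids
            ],
        }
    ).to_csv(gene_truth, sep="\t", index=False)
    spec_path = outdir / "spec.yaml"
    spec.to_yaml(spec_path)
    paths.update(
        truth_spots=str(spot_truth), truth_genes=str(gene_truth),
        spec=str(spec_path),
    )
    return paths
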
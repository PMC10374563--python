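# Methods

`svgrank` ranks spatially variable genes (SVGs) in spot-based spatial
transcriptomics (10X Visium-style data) and scores combinations of them.
This note records the statistical model, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmark does
and does not demonstrate.

## Pre-processing

Genes are kept only if they are detected (count > 0) in strictly more than
1% of spots **and** carry at least 10 total UMIs; both thresholds are
configurable (`min_spot_fraction`, `min_total_umi`). Expression is
library-size normalized per spot and natural-log transformed:

    r'_gj = ln( r_gj * s / Σ_g r_gj + 1 ),   s = 10 000 by default

so every nonzero spot satisfies Σ_g (e^{r'} − 1)/s = 1 exactly (a
conservation identity asserted in the tests). Spots with zero total count
are kept, with all-zero normalized columns and a warning — dropping them
would silently change the neighbor graph for every remaining spot.
Internally the matrix is genes × spots.

## The spot lattice

All spatial statistics run on the K-nearest-neighbor graph of spot
coordinates (Euclidean, K = 6 by default: Visium spots are hexagonally
packed, so interior spots have exactly six equidistant neighbors). The KNN
search is a chunked exhaustive all-pairs computation with a fixed tie
rule — ascending distance, then ascending spot index — rather than a
KD-tree, trading a little speed for bit-level reproducibility across
platforms. Coordinates default to full-resolution pixel positions from
the tissue-positions table; array row/column indices can be selected
instead.

## Hotspot detection: local Moran's I

For centered values z (mean removed) with m2 = Σz²/n, the local Moran
statistic at spot i is I_i = (z_i/m2) Σ_j w_ij z_j with row-standardized
KNN weights (each neighbor 1/K). The mean of the local statistics equals
global Moran's I under the same weights; the tests assert this identity.

Significance is one-sided (a hotspot is a *high* value among high
neighbors; dispersion is not of interest here) and conditional: z_i is
held fixed while its K neighbor values are re-drawn from the remaining
n − 1 spots. Two modes:

* **Permutation** (`n_permutations`, default 999, seeded): pseudo p-value
  (#{I_perm ≥ I_obs} + 1)/(n_perm + 1), so p ≥ 1/(n_perm + 1) and log p is
  always finite. Sampling draws `rng.permutation(n−1)[:K]` per
  permutation from a single `default_rng(seed)` stream, spots in index
  order — a scheme simple enough to re-code independently, which the test
  suite does, matching p-values exactly at matched seeds.
* **Analytic** (default in the full pipeline): a normal tail with the
  *exact* conditional mean and variance of the permutation distribution,

      E[lag_i] = −z_i/(n−1),
      Var[lag_i] = s²_i (n−1−K) / (K (n−2)),

  where s²_i is the variance of the non-focal values. This matches the
  conditional scheme (rather than the total-randomization moments) and
  costs one matrix product for all genes at once. Analytic p-values are
  floored at 1e-300.

Per gene, p-values are Benjamini–Hochberg adjusted across spots (no
cross-gene adjustment: each gene's hotspot map is its own family of
spot-level tests) and thresholded at FDR 0.05. A hotspot additionally
requires z_i > 0 and a positive spatial lag — the high-high quadrant of
the Moran scatterplot, the standard LISA hotspot class; the lag condition
can be relaxed with a flag. Constant-expression genes get p = 1
everywhere and an all-zero hotspot row, without error.

## The aggregation index

For a gene with hotspot indicator h, the local aggregation density at
hotspot i is D_i = Σ_{j∈KNN(i)} w_j h_j with

    w_j = log(p_j) / Σ_{l∈KNN(i)} log(p_l),

p_j the neighbor's **raw** local-Moran p-value (the test's own p-value,
not the FDR — the weights describe evidence strength, not a decision
rule). Both numerator and denominator are negative for p < 1, so the
weights are nonnegative and sum to one, and D_i ∈ [0, 1]; a neighbor with
p = 1 contributes zero weight, and in the degenerate case where *all* K
neighbors have p = 1 the weights fall back to uniform 1/K. The
aggregation index is AI = mean of D_i over the gene's n_g hotspots, and
AI := 0 when n_g = 0 (the 0/0 case; "no hotspots" is the least aggregated
state and ranks last). Genes are ranked by descending AI, ties broken by
descending hotspot count, then ascending gene id. The neighborhood size
for the density step (`K_density`) is exposed separately from the Moran
weights (`K_moran`); both default to 6, and AI rankings are empirically
stable across K ∈ {4, 6, 8} (Spearman ρ > 0.9 on the benchmark).

## SVG clustering

High-ranking SVGs (top `top_k` by AI; 500 by default, matching the usual
top-SVG selection on ~20k-gene datasets) are clustered on the Jaccard
distance between their binary hotspot vectors — expression magnitude is
deliberately ignored, since genes sharing a spatial pattern can differ
greatly in level. Agglomerative clustering uses average linkage by
default (a common choice for Jaccard; complete and single are available),
cut either at a cluster count or a distance threshold. Genes with no
hotspots are excluded first (Jaccard is undefined on two empty sets; a
pairwise distance of two all-zero vectors is reported as 1 with a
warning). Each cluster is summarized by its hotspot-frequency map — per
spot, the fraction of member genes hot there. Two clusters are
"neighbors" when the cosine similarity of their frequency maps is at
least 0.2 (configurable); this operational definition stands in for the
informal notion of same/overlapping clusters used to restrict the
combinatorial search.

## Combination scoring

With X the binary hotspot matrix over m selected genes, C = X·Xᵀ counts
shared hotspots and E = (1−X)·Xᵀ counts spots hot for one gene but not
the other, both in exact integer arithmetic. C is symmetric with
C_ii = n_g; E is asymmetric with zero diagonal; C_ij + E_ij = C_jj always
(asserted on every run). Pairs are ranked by raw C_ij for
co-localization; for a single exclusion ranking E is symmetrized as
min(E_ij, E_ji), since mutual exclusion requires both directions (both
raw directions are always reported). A normalized overlap coefficient
C_ij / min(C_ii, C_jj) is emitted as an additional, clearly separate
column. For 2–3 named genes a joint hotspot map labels every spot by the
subset of genes calling it hot; the category sizes reproduce the C/E
entries by construction. Larger combinations are only supported through
the joint map's Venn partition, as the matrix formulas are pairwise.

## The synthetic benchmark

The generator plants geometric regions (disk, annulus, half-plane,
stripe) on a hex or square lattice and draws counts per gene from a
Poisson or gamma-Poisson (negative binomial, variance μ + μ²/θ) model:
`mean_in` inside the gene's target region, `mean_out` elsewhere, one flat
mean for noise genes. The shipped benchmark is a 40 × 40 hex lattice with
three disjoint regions (a disk, an annulus and a stripe; 131, 145 and 280
spots), 10 SVGs per region with mean 4.0 in-region vs 0.2 outside, 200
noise genes with mean 0.5, and dispersion θ = 2.0 — strong regional
markers over a low ambient background, the regime the method targets.
All draws come from one seeded generator, so output is bit-reproducible,
and datasets export in exactly the MTX/CSV dialects the readers consume,
with ground-truth TSVs alongside.

On this benchmark the whole pipeline runs in a few seconds in analytic
mode, which is why the test suite and the acceptance script use it
end-to-end; permutation mode is validated against an independent
brute-force loop on small grids. Benchmark evaluation selects the top 30
SVGs — as many as are planted, the top-k selection scaled to a 230-gene
dataset — and clusters them at k = 3. The ranking-order check cuts the
ranked gene list into consecutive groups of 50, derives a spot partition
per group (each spot to its argmax cluster-frequency cluster, background
when all frequencies are zero) and scores it against the planted regions
with the adjusted Rand index; the sequence must be non-increasing within
an additive 0.02 allowance for Monte-Carlo jitter between near-zero
noise-group values. A group with too few hotspot-bearing genes maps all
spots to background and scores exactly 0.

What passing these checks does **not** show: the generator has uniform
library sizes, no spatial autocorrelation in the noise, no bleed between
adjacent spots, sharp region boundaries, and no dominant highly expressed
housekeeping background — real tissue violates all of these, so recovery
rates here are upper bounds, not forecasts, for real data.

## Numerical conventions and edge cases

- Natural log throughout (normalization and p-value weights).
- p-value floors: 1/(n_perm+1) in permutation mode by construction,
  1e-300 in analytic mode; weights clamp p into [1e-300, 1].
- KNN ties broken by ascending spot index; duplicated coordinates give
  zero-distance neighbors, same rule.
- Gene-rank ties broken by hotspot count then gene id; cluster labels
  relabeled contiguously 1..k in order of first appearance.
- Filtering all genes out returns a valid empty-gene matrix with a
  warning; a positions table with zero in-tissue spots is an error.
- Duplicate feature names are disambiguated with ".1", ".2", ... suffixes.

## Known limitations

- The analytic mode assumes a normal tail for the conditional permutation
  distribution; for very zero-inflated genes on small lattices its
  p-values are approximate (the permutation mode is exact up to Monte
  Carlo error and is the cross-check).
- The exhaustive KNN is quadratic in spot count; fine for Visium-scale
  (≤ ~10⁵ spots), not for subcellular-resolution platforms.
- Cluster-count selection is manual by design (`n_clusters` or a distance
  threshold); the method's original workflow curates clusters by eye, and
  no automatic selection is attempted.
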
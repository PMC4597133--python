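# Methods

This note records the models, conventions, and numerical choices behind
`gapkit`, and what its synthetic worlds do and do not demonstrate.

## Geometry and rasters

All analysis happens on a north-up rectangular lattice of square cells
in geographic coordinates (`GridLayer`). Distances are great-circle on a
sphere of radius 6371 km; at the 50-km scale of occurrence buffers the
spherical-vs-ellipsoidal error is far below one cell width, and the
formula stays hand-checkable. Cell area is
`(cell_size · π/180 · R)² · cos(center latitude)`; rows with center
latitude beyond ±89.5° are rejected rather than silently degenerate.

Buffer membership is decided at cell *centers*: a cell belongs to the
CA50 distribution iff the great-circle distance from its center to the
nearest occurrence point is at most the radius (default 50 km, the
field-standard "collection catchment"). The any-part-of-cell convention
would grow ranges by up to half a cell diagonal; the center rule is the
simpler, exactly testable choice and is a documented module constant.

Raster I/O is single-band ESRI ASCII grid, with the nodata sentinel
honoured bit-exactly. Resampling between native resolutions is
nearest-neighbour for categorical layers and block-mean for continuous
ones, and only between grids sharing an origin with an integer cell-size
ratio — anything else is an alignment error, never a silent reprojection.
Depth-weighted soil aggregation uses the profile slices 0–5, 5–15,
15–30, 30–60, 60–100 cm, i.e. weights (5, 10, 15, 30, 40)/100, with
nodata at any depth propagating.

## Occurrence records

Records are germplasm accessions (G) or reference records (H). The
duplicate key is (taxon, type, coordinates rounded to 4 decimals ≈ 11 m);
type is part of the key so an accession never erases a voucher at the
same site, which is conservative for SRS. Coordinate-free records are
kept (they count toward SRS) and never merged. Native-area filtering is
mask-based; country-polygon machinery is out of scope.

## Distribution validation and fallback

The suitability model itself is external input; `gapkit` evaluates it.
Fold AUC is the rank-based two-sample statistic
`P(pos > bg) + ½P(pos = bg)` against (by default 10,000) background
points. A model passes when ATAUC > 0.7 (strict), the sample (n−1)
standard deviation of fold AUCs is < 0.15, and at least 10% of valid
cells have an across-fold prediction SD below 0.15 (ASD15). The ASD15
criterion as printed in the gap-analysis literature we follow is
unusually permissive; a stricter variant (at most 10% of cells with SD
*above* the cut) is available as `asd_variant="strict"`, with the
permissive form the default. The ROC threshold maximizes
sensitivity + specificity over the observed presence ∪ background score
values; ties resolve to the lowest candidate (most inclusive range), and
binarization is `value ≥ threshold`. Failed or absent models fall back
to the CA50 buffer distribution; provenance is recorded per taxon.

## Gap scores

SRS uses *all* records; GRS and ERS use coordinate-bearing germplasm
only — mirroring the distinction between total samples and mappable
samples. GRS is an area ratio with cosine-latitude weighting; ERS counts
ecoregion classes by presence/absence (not area), because ecological
representativeness across ecosystem types is categorical; the exact ERS
formula is a reconstruction from the method's description, flagged as
such. FPS bands are half-open on the left: (3, 5] is medium priority, so
FPS = 3.0 is still high priority and 7.5 still low priority, matching
the printed band edges (3.01, 5.01, 7.51 as the next-band starts at the
two-decimal precision the bands are stated in). All scores are on 0–10;
the SRS ratio is scaled ×10 so the FPS bands apply.

## Niche and range overlap

D and I compare two suitability surfaces normalized to probability
distributions over their *shared* valid cells; binary (buffer) ranges
enter as uniform distributions, mirroring the model-passed vs
buffer-fallback split. `I` is computed in the Hellinger-difference form
and equals the Bhattacharyya coefficient algebraically; the test suite
checks both forms to 1e−10. Of the two printed range-overlap ratios the
second is garbled in its source; it is implemented as
`shared / min(|A|, |B|)` (overlap relative to the smaller range), with
the Sørensen form `2·shared/(|A|+|B|)` always reported alongside so no
information is lost. Sympatry means ≥ 1 shared cell at the analysis
resolution (configurable). "Perfect overlap" in cohort summaries is
`max(D, I) ≥ 1 − 1e−6` by default — the notion is not standardised — and
the summary table records the rule used. The range-asymmetry statistic
is the mean of (frac_smaller − frac_larger) over sympatric pairs, in
percentage points.

## Ordination, clustering, phylogenetic statistics

Per-taxon traits are the **median** of occurrence-point extractions per
environmental layer (mean available); taxa with fewer than 3 usable
points are excluded with a warning. PCA standardizes columns by default
and fixes signs so each component's largest-magnitude loading is
positive. HCPC is Ward-linkage agglomeration of occurrence points on the
first 3 PC scores, cut at k = 3 clusters (both configurable); a taxon
takes the cluster holding the majority of its points, ties to the
smaller cluster id.

Blomberg's K uses the shared-branch-length matrix C implied by the tree:

    K = [ (x−â)ᵀ(x−â) / (x−â)ᵀC⁻¹(x−â) ] / [ (tr C − n/ΣC⁻¹) / (n−1) ]

with â the GLS phylogenetic mean. On a star tree with equal branches
C is proportional to the identity and K = 1 exactly for any trait vector
— the suite asserts this to 1e−12, and agreement with an independently
coded dense-matrix oracle to 1e−6. Significance permutes trait values
across tips and ranks the observed 1/MSE among (default) 1000
permutations, matching the randomization convention of the R packages
standard in this literature; the alternative "K > 1 and p < 0.05" decision rule is
exposed for the conservatism summary. Permutation p-values always carry
the +1 correction and are never exactly 0.

The Mantel statistic is the Pearson correlation of off-diagonal entries,
with a row/column co-permutation null (one-sided, upper). Distance
builders: Mahalanobis on the trait table (pooled covariance, ridged with
1e−8 × mean diagonal if singular), great-circle between taxon occurrence
centroids, and cophenetic path length on the tree. All three matrices
are produced; no pair is privileged, since which pair a given study
correlates is a design decision.

Across the per-variable K tests the pipeline reports raw permutation
p-values alongside Benjamini–Hochberg adjusted ones; the conservatism
fraction uses raw p < 0.05 by default, as signal screens in this
literature conventionally do.

## The synthetic world

`make_world` emulates, at desk scale, the structure of a continental CWR
study: 36 taxa on a 60 × 60 grid of 0.25° cells (mid-latitudes,
30–45° N), 26 environmental variables, 10 ecoregion classes, ~5%
excluded (urban/water/bare) cells, 40 coordinate-bearing plus 68
coordinate-free records per taxon (≈ 37% mappable, the proportion typical
of mixed genebank/herbarium compilations). Environmental fields are
moving-average-smoothed white noise (window 7 cells), standardized, with
a shared-latent mixing weight of 0.7 emulating the strong collinearity
of real bioclimatic sets. Suitability is a Gaussian niche response
`exp(−½ Σ((env − center)/breadth)²)` on 3 niche axes, rescaled to max 1
— an explicit surrogate for a fitted distribution model, usable because
every downstream computation consumes an arbitrary suitability surface.
Occurrence cells are sampled without replacement with probability
proportional to suitability and jittered within the cell.

The phylogeny is a Kingman-coalescent ultrametric tree; each niche
axis's centers evolve by Brownian motion along it (then standardized),
so relatives genuinely share environmental preferences and the K and
Mantel stages measure a real signal. Per-taxon germplasm fractions are
uniform on (0, 0.7), spreading taxa across the priority bands the way
uneven genebank holdings do. Every generator is a deterministic function
of the seed (sub-seeds via `SeedSequence.spawn`), and `truth.json`
records all parameters.

What passing tests on these worlds shows: the algebra, contracts, and
calibration of every statistic, and the integrity of the full chain.
What they do not show: robustness to the pathologies of real data —
georeferencing error, sampling bias toward roads and rivers, taxonomic
synonymy, non-Gaussian niches, range disjunctions — nor the predictive
skill of any particular distribution model.

## Problem sizes and numerical choices

Default analysis constants: buffer 50 km, k = 5 folds, 10,000 background
points, ATAUC/STAUC/ASD cuts 0.7/0.15/0.15, 3 PCs, 3 clusters, 1000
permutations. Test and calibration runs use the sizes stated in the
suite (e.g. 50-tip trees with 200 Brownian replicates for K calibration,
1000 null simulations at 199 permutations for the Mantel size check,
40 × 40-cell worlds for end-to-end determinism) — chosen as the smallest
sizes at which the checked properties are statistically sharp. Pipeline
reruns with identical seed and config are byte-identical in all tabular
outputs. Degenerate inputs fail loudly: empty point sets, empty ranges,
zero-total surfaces, misaligned grids, zero-variance columns under
standardization, and name mismatches between tree and traits all raise
errors naming the offender.

## Known limitations

- No projection support: everything assumes WGS84 geographic grids.
- ERS is class-presence-based; an area-weighted variant may rank taxa
  differently when ranges straddle very unequal ecoregions.
- The buffer fallback ignores landscape connectivity and barriers.
- The Mahalanobis trait distance pools covariance across all taxa; group
  structure in niche space will distort it when clusters are very tight.
- K assumes the tree is correctly rooted with meaningful branch lengths;
  unit-length imputation (applied with a warning when lengths are
  missing) changes its value.
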
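# Methods

This note documents the models and procedures implemented in `bacumorph`,
the parameters that matter, the numerical choices made where the design was
open, what the synthetic data do and do not emulate, and known limitations.

## Canonical alignment

A segmented bone is an unordered set of x-y-z points (interior included).
The canonical frame is built from the geometry alone:

1. **Provisional axis.** The diameter of the cloud — the two points
   furthest apart, found exactly on the convex hull — defines a provisional
   z-axis. Ties are broken by lexicographic order of the pair so the result
   is deterministic.
2. **End-centroid registration.** The 10% (`end_frac`) most proximal and
   distal slabs of the provisional z-extent are cut out and the centroid of
   each slab's convex hull computed. By default this is the
   volume-weighted centroid of the hull polyhedron (tetrahedral
   decomposition from an interior point), which is insensitive to uneven
   point density; the plain mean of hull vertices is available via
   `PipelineConfig(hull_centroid_mode="vertices")`. The rigid transform
   mapping the proximal centroid to the origin and the distal centroid onto
   +z is applied. Which end is proximal is decided by cross-section area:
   the slab with the larger minimum-bounding-rectangle area is the base
   (`proximal_end="auto"`; can be forced per specimen). The registration is
   a single pass; the mapped reference centroids land exactly on the
   contract, while slab centroids *recomputed* in the new frame move by
   O(1%) of the length for curved bones. A second pass is idempotent.
3. **MBR orientation.** The points at 15.00–15.25% (`mbr_band`, half-open)
   of the z-extent are projected to the x-y plane and their minimum-area
   bounding rectangle found by rotating calipers over hull edges (the
   optimum has a side collinear with a hull edge, so the search is exact).
   A rotation about z aligns the long side with x. The angle is defined
   modulo 180°; the ambiguity is resolved by the next step.
4. **Dorsoventral resolution.** Bacula bow dorsally toward the distal end.
   If the mean y of the most-distal quarter of points is negative, the
   cloud is rotated by 180° about z (a proper rotation — it flips dorsal
   and left-right together, preserving chirality and the proximal-distal
   convention). If the mean y is numerically zero *or statistically
   indistinguishable from zero* (within twice its standard error), no flip
   is applied and a warning marks the orientation as ambiguous; a straight
   bone genuinely has no dorsoventral signal in this recipe.

Empty bands and slabs are widened by symmetric doubling, at most five
times, with a warning. All fractional slices are measured along the current
z after each re-registration and use half-open intervals [lo, hi).

Because every step is a deterministic function of the point set, the
composed alignment is invariant under rigid motions of the input to
floating-point precision, and aligning an already-aligned cloud reproduces
it to well below 1e-6 of the length.

## Semilandmarks and centroid size

Fifty slice bands (`n_slices`), each 0.25% of the length thick
(`slice_thickness_frac`), are centred at the fractions (i + 0.5)/50 of the
z-extent — the half-offset avoids empty half-bands at the tips, which the
recipe leaves unspecified. Within a band of x-extent W, seven lines
(`n_lines`) sit at the interior fractions ℓ/8 of W (the end positions are
already captured by the leftmost/rightmost landmarks). Points within 4% of
W of a line (`projection_tol_frac`) are projected onto it (x set to the
line, y and z kept); the max-y and min-y projected points are the dorsal
and ventral semilandmarks. An empty projection window doubles its
tolerance, at most five times; a band with fewer than two distinct-x points
doubles its thickness under the same policy. All extremal choices break
ties deterministically (smallest z, then lexicographic), so extraction is a
pure function of (points, config). Landmark order is fixed: per slice
dorsal_1..7, ventral_1..7, leftmost, rightmost; tips last. Centroid size is
CS = √Σₖ‖pₖ − p̄‖² over the 802 points.

## Procrustes shape analysis

Pairwise superimposition centres both configurations, scales them to unit
centroid size and rotates one onto the other by the SVD solution restricted
to proper rotations (bacula are chiral; a reflection is never allowed even
when it would fit better). The reported distance is the Euclidean norm
between the superimposed unit-size configurations. Generalized Procrustes
analysis iterates rotation-to-consensus and consensus re-estimation
(consensus renormalised to unit size) to a 1e-9 tolerance.

**Sliding.** With `slide=True`, semilandmarks may move in their estimated
tangent planes to minimise the thin-plate-spline bending energy between the
consensus and the specimen (3D kernel U(r) = −r; the bending-energy matrix
is the upper-left block of the inverted TPS system and annihilates affine
transforms). Tangent directions are estimated from neighbouring landmarks
of the specimen itself, since no surface mesh exists: dorsal/ventral points
get a within-slice and an across-slice direction, leftmost/rightmost points
slide only along the bone margin (across slices), and the two tips are
fixed. The quadratic sliding system is Tikhonov-damped (λ = 1e-3 of the
mean diagonal) and each landmark's step is capped at half the median
nearest-landmark spacing: the undamped minimal-norm solution can move
landmarks arbitrarily far along near-affine null directions of the bending
energy without reducing it, which destroys the superimposition. Each
sliding pass is asserted never to increase the bending energy; slid
configurations are re-centred, rescaled and re-rotated. Sliding runs for
the first three GPA iterations (`slide_iter`), after which plain GPA
iterations polish convergence. An alternative objective (minimising
Procrustes distance rather than bending energy) was considered and not
implemented; bending energy is the conventional default for surface
semilandmarks and gives the smoother deformations.

## The LD1 shape score

A scalar shape phenotype is anchored on the two parental strains. A
discriminant "on the distance matrix" is not directly well-posed (the
training block of a distance matrix is wider than it is tall), so the
default construction is:

1. classical multidimensional scaling (PCoA, double-centred
   eigendecomposition) of the full distance matrix, keeping positive
   eigenvalues only;
2. components retained up to min(those explaining ≥ 95% of the positive
   variance, n_parentals − 2);
3. a two-class linear discriminant fit on the parental specimens in that
   embedding with a **shrinkage-regularised** within-class covariance
   (Ledoit–Wolf), direction normalised to unit length. With few parental
   specimens relative to the embedding dimension, the unshrunk estimate
   makes both the direction and the scale of the axis unstable — in
   experiments the parental separation varied by a factor of ~40 across
   seeds without shrinkage and is stable with it.
4. sign fixed so the first-listed parent scores lower;
5. out-of-sample specimens embedded by Gower's interpolation formula from
   their distances to the fit specimens, then projected on the axis.
   Projecting a fit-time specimen reproduces its fit-time score exactly.

An alternative reading — LDA on distance-to-parental-specimen feature
vectors with shrinkage covariance — is available via
`fit_ld1(..., mode="distance_lda")`. Both are interpretations; the PCoA
route is the default because it supports principled out-of-sample
projection.

## Quantitative genetics

- **Size repeatability** = 1 − median over re-scanned specimens of
  (unbiased SD / mean) of centroid size.
- **Shape repeatability** cannot use the CV of LD1 (the score spans zero),
  so for each replicate group and each other specimen the CV of the
  replicate-to-specimen Procrustes distances is computed; the statistic is
  1 − the mean CV over all (group, other) pairs. "Averaging" is taken as
  the mean; the median variant would differ only in the tails.
- **Lab effects**: sequential (type-I) sums of squares for strain, then lab
  within strain, then residual; F-test on the nested term and the fraction
  of total SS attributable to lab.
- **Heritability** (broad sense, inbred panel): the fraction of the total
  sum of squares explained by strain in a one-way ANOVA — the model R².
  Strains with fewer than 3 individuals are excluded from h² but kept for
  mapping. Note this estimator is *defined* as the realized SS fraction;
  in finite samples it exceeds the population variance ratio in
  expectation (between-strain SS absorbs within-strain noise: about +0.06
  at 60 strains × 5 for a true ratio of 0.6). The synthetic generator
  therefore plants heritability as an exact realized SS fraction
  (`generate_strain_phenotypes(mode="exact")`, which centres residuals
  within strains and scales the two components) when the estimator's
  algebra is being verified, and offers `mode="sampled"` for studies of the
  estimator's sampling behaviour.
- **Strain-mean correlation**: Pearson r between per-strain mean CS and
  mean LD1, two-sided t-test.

## QTL mapping

RILs are homozygous, so Haley–Knott regression reduces to an ordinary
regression of strain means on P(second-parent allele); there is no
dominance term. LOD = (n/2)·log₁₀(RSS₀/RSS₁); the variance explained at a
position satisfies R² = 1 − 10^(−2·LOD/n) exactly. A perfect fit caps the
LOD at 300 with a flag.

Missing genotypes are imputed as the conditional expectation given the
nearest flanking observed markers under a two-state chain whose
interval-wise switch probabilities are the sib-mating-expanded
recombination fractions r\* = 4r/(1+6r), r from the Haldane map function.
The expanded fraction is **not additive over distance**, so the transition
between a missing marker and its flank is composed interval-by-interval
through any intervening missing markers; this makes the imputation exactly
consistent with the panel generator's Markov chain (verified against full
hidden-state enumeration on small chromosomes). Missing runs at chromosome
ends copy the nearest observed genotype; a fully missing chromosome gets
probability 0.5 with a warning. Genotype codes outside {B, D} (residual
heterozygosity) are treated as missing. The X chromosome is not
special-cased (limitation).

Significance is empirical: the phenotype vector is permuted against strains
(the exchangeable-null equivalent of permuting phenotypes and genotypes),
the genome rescanned per permutation, and the 95th quantile of the maximum
LOD scores taken as the genome-wide threshold (type-7 linear quantile
interpolation, bit-reproducible given the seed). The empirical p of an
observed LOD is the fraction of permutation maxima at least as large; a
LOD exceeding all permutations reports p < 1/n_perm. Support intervals
drop 1.5 LOD units from the chromosome peak; the endpoints are the
outermost markers still within the drop (no expansion beyond the drop
boundary — conventions differ between mapping-software versions, and this
one matches the interval read directly off the LOD curve). Linkage
disequilibrium between two QTL is the uncorrected Pearson χ² (df = 1) on
the 2×2 strain-allele table; with Yates correction the statistic would be
systematically smaller. Scanning is at markers only; a pseudomarker grid
is future work.

## Synthetic data

**Bone phantoms** sweep superellipse cross-sections (exponent 2 by
default; closed-form extremes give landmark oracles) along a circular-arc
centerline whose sagitta is the dorsal bow. Width and height taper linearly
from base to tip, so the base is the broad end, as the proximal-end
heuristic assumes. Points fill the section except a scaled-down central
cavity (the hollow medullary core); isotropic Gaussian jitter
(`noise_sd = 8 μm` at the millimetre scale) stands in for segmentation
noise, and each phantom is returned in a random rigid pose so alignment is
always exercised. The default 2×10⁴ points keep tests fast; real
segmentations run ~1.75×10⁵ points, and the density flag restores that
regime. Two presets span the parental extremes: a shorter, broader,
strongly bowed form and a longer, slimmer, nearly straight form; morph
continua interpolate every numeric parameter linearly. What the phantoms
do **not** emulate: CT physics (beam hardening, noise spectra), surface
texture, trabecular interior structure, or asymmetric cross-sections —
passing tests show the geometry pipeline is correct, not that real scans
are this clean.

**Replicate scans** re-pose the same point cloud with small random rigid
motions (rotation SD 0.05 rad, translation SD 0.2 mm) plus fresh point
noise — reloading a specimen into the holder, but not re-projection of a
new physical scan.

**RIL panels** simulate each chromosome as a two-state Markov chain along
the marker map with interval-wise expanded recombination fractions, a fair
coin at the first marker (genome-wide second-parent fraction 0.5 in
expectation). Defaults — 70 strains, 5 chromosomes × 20 markers at 5 cM,
2.2% missing data — scale the real panel (73 strains, 2953 kept markers,
19 autosomes) down to test size; thresholds are correspondingly lower than
with a full map because the permutation null maximises over fewer
effectively independent tests. Phenotypes are strain means: ±a per planted
QTL (from the true, unmasked genotypes) plus Gaussian residuals; a QTL with
effect a = σ·√(h²/(1−h²)) explains the target fraction h² of strain-mean
variance in expectation. Planted effects can instead act through phantom
geometry (`strain_params_from_genotype`) for end-to-end integration tests.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use scaled study sizes chosen
once: 100 random poses for alignment invariance; 10-specimen morph continua
at the default 2×10⁴-point density for the discriminant checks; 70-strain
panels with 200-permutation thresholds for the 400-run type-I calibration
and the 100-run power study; 1000 permutations where a single scan's
threshold is reported. Every stochastic routine takes an explicit seed and
is bit-reproducible given it.

## Known limitations

- The dorsoventral heuristic assumes measurable distal curvature; straight
  bones are flagged, not resolved.
- Sliding relies on neighbour-estimated tangents, not a surface mesh, and
  on a damped quadratic step; it reduces parameterisation noise but is not
  geomorph's mesh-projected slide.
- The discriminant construction on a distance matrix is an interpretation
  (two variants provided); absolute LD1 scales are not comparable across
  fits, only orderings and group contrasts.
- Haley-Knott here is single-QTL, no covariates, no kinship; related-line
  panels (advanced intercross lines) need a mixed model and are out of
  scope.
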
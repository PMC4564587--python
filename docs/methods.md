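# Methods

This note documents the models and procedures implemented in `morphokin`,
the defaults chosen where the design was genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Superimposition

Configurations are K ordered 3D landmarks. We use the partial Procrustes
convention: every configuration is centred and fixed at unit centroid size
(CS = √Σᵢ‖xᵢ − x̄‖²), and the rotation aligning a configuration to a
reference is the proper orthogonal matrix from the SVD of the cross-product
matrix with the determinant forced to +1. Reflections are never permitted:
left/right anatomy must not be flipped to improve a fit. Generalized
Procrustes Analysis iterates align-to-consensus / re-average / re-normalise
until the consensus moves by less than 1e-10 (root summed squared change) or
100 iterations; both bounds are far below landmark digitising noise. The
consensus is initialised from the first configuration; order invariance of
the result up to a joint rotation is enforced by a property test rather than
by a canonical initialisation.

The Procrustes distance between two shapes is the root summed squared
landmark difference after full superimposition of one onto the other
(unit-size, centred, optimal proper rotation). On this representation it is
a metric; symmetry and the triangle inequality are property-tested.
Distances are computed in the Procrustes representation itself; an
orthogonal tangent-space projection (residuals projected orthogonally to the
consensus direction) is available as a PCA option but is not applied to
distances.

Digitising repeatability is assessed by superimposing all repeated trials of
a specimen together and comparing the per-trial RMS residuals of the two
sessions with a paired two-sided t-test; identical sessions give t = 0,
p = 1 by construction.

## Shape PCA and growth regressions

PCA is an SVD of the flattened aligned coordinates about their sample mean.
At most min(n−1, 3K−7) components are retained (seven similarity degrees of
freedom are removed by superimposition). Scores are exactly isometric to the
aligned coordinates, and reconstruction from all components is exact; both
are tested. Components explaining more than 5% of variance are flagged as
the axes worth visualising by wireframe morphing (consensus + s·component).

PC scores are regressed by ordinary least squares on (a) numeric age and
(b) log centroid size, for the pooled sample and per population. Two-sided
p-values are reported, with α = 0.05 for the significance tables. Age
categories are scored from dental eruption; their numeric coding is the
midpoint of each stage's rough chronological range — AC1 → 2.5, AC2 → 8.5,
AC3 → 15.5 years. Adults have no eruption-based age estimate; they default
to a nominal 21.0 years and the encoding is configurable, since any adult
value is a convention. By default adults enter superimposition, PCA and
visualisation but not the per-stage distance matrices.

## Population distances and classification

Population mean shapes are the per-group means of aligned coordinates,
re-normalised to unit centroid size so that between-mean distances remain
shape distances. Pairwise significance uses a permutation test: the two
groups are pooled, labels reshuffled preserving group sizes, and the
between-mean distance recomputed; p = (1 + #{permuted ≥ observed})/(1 + B)
with B = 1000 by default (add-one convention; smallest attainable p is
1/(B+1)). The joint superimposition is not refit per permutation — refitting
would change the coordinates only by a rotation, which the statistic is
invariant to.

Classification uses linear discriminant analysis (pooled within-group
covariance, scikit-learn implementation) on PC scores, evaluated by
leave-one-out cross-validation. The PC basis is computed once on the full
sample and not refit per fold, mirroring discriminant analysis run on
precomputed PC scores; this admits a mild leakage through the basis, which
is documented rather than removed. By default the leading components
covering 95% cumulative variance are used, capped at n − g − 1 so the pooled
covariance is estimable in every fold. Groups with a single specimen cannot
be left out and refit and are excluded with a warning. Note that under a
true null, LOOCV accuracy sits slightly *below* 100/g because the left-out
specimen's class is under-represented in its training fold; the chance-level
checks use a ±5-point band.

## F_ST, R_ST and linearised distances

Differentiation is estimated by a three-level nested ANOVA — among
populations / among individuals within populations / between the two gene
copies of an individual. Applied to the 0/1 indicator of each allele and
summed over alleles and loci, the variance components are exactly the
classical Weir–Cockerham components, and the multilocus θ is the ratio of
summed components (verified against an independently coded frequency-form
oracle, including a hand-derived single-locus case with θ = 4/9). Applied to
allele repeat sizes, the same machinery yields the allele-size R_ST
convention; because the components are invariant to affine recoding, R_ST
coincides with θ whenever only two allele sizes segregate, which is tested.

Missing genotypes are dropped per locus and individual (pairwise deletion);
a locus enters a pairwise estimate only if both populations have at least
`min_individuals` (default 2) typed individuals. Negative per-locus
components are retained in the sums; only the final multilocus ratio is
floored at zero in the distance matrix, with the raw value kept alongside.
The default output is raw θ (not linearised), with D = F/(1−F) one flag
away; the bundled molecular reference matrix is consumed as printed, since
whether such published matrices are raw or linearised is often ambiguous.

## Mantel tests

The Mantel statistic is the Pearson correlation over the n(n−1)/2 unordered
off-diagonal pairs, after reconciling the two matrices by label (never by
position). The null permutes the labels of one matrix (simultaneous
row/column shuffle). For n ≤ 8 all n! permutations are enumerated — the
identity permutation is part of the null, p = #{r_perm ≥ r_obs}/n!, and the
result is deterministic; otherwise seeded Monte-Carlo with the add-one
convention is used, and the two agree within binomial error (tested). The
headline p is one-sided upper-tail (large positive correlation = evidence of
concordance), but both tails and the two-sided p are always carried on the
result, and the linearised-molecular variant is one call away: published
correlation tables do not always state their tail or transformation
conventions, so every result object is explicit about its own.

A point worth recording: the bundled reference suite reproduces only part of
the correlation column published alongside these matrices. From the printed
matrices, the exact Mantel gives r = 0.60 (combined subadults), −0.00 (AC1),
0.23 (AC2), 0.52 (AC3), and 0.83 / 0.36 / 0.69 excluding Egypt, whereas the
published column reads 0.48 / −0.58 / 0.36 / 0.33 and 0.83 / 0.57 / 0.91.
Only the excluding-Egypt combined-subadult value matches within rounding.
No convention we tried (Slatkin-linearised molecular distances, squared
morphological distances, Spearman instead of Pearson, either tail) closes
the gap, which points to the published correlations having been computed
from a molecular matrix other than the printed one (it was described as
computed separately from raw genotypes). The package therefore treats the
printed matrices as the ground truth it can verify against, reports both
tails and the linearised variant wherever a discrepancy exists, and freezes
its own deterministic values in the tests.

The exclusion scan re-runs the Mantel test once per single-population
removal (plus the full baseline), flagging populations that unduly drive or
destroy the concordance.

## Synthetic study system

The generator emulates the sampling design of a seven-population subadult
cranial series: per-population specimen counts over AC1/AC2/AC3 shaped like
the reference design (totals 48/51/85) plus eight adults per population, a
44-landmark scheme partitioned into overlapping occipital (13), temporal
(24) and sphenoid (12) regions sharing landmarks {1, 2, 13, 33, 36}, and a
50-locus STR panel as a fixture-scale stand-in for a genome-wide panel.

**Genotypes.** Each locus draws 3–6 contiguous repeat sizes within 8–30 and
an ancestral Dirichlet(1.5) frequency spectrum. Population frequencies
deviate from the ancestral ones with a covariance Σ obtained by
double-centring the target F_ST matrix, so that the first-order expected
pairwise θ, (Σpp + Σqq − 2Σpq)/2, equals the target entry. Clipping the
deviated frequencies to the simplex shrinks realized divergence below this
calculation by ~25–30% at the upper end of the target range, so the
generator recalibrates internally: three rounds of frequency-only simulation
(300 loci), comparison of the implied large-sample θ with the target, and
multiplicative adjustment of the effective target. After calibration the
median realized pairwise θ over 10 seeds is within ±0.01 of every target
entry. Genotypes are drawn under Hardy–Weinberg within populations.

**Landmarks.** Population mean offsets in tangent space are a classical
scaling (principal coordinates) embedding of the genetic distance matrix,
carried into shape space along random orthonormal directions kept orthogonal
to the consensus direction, and scaled by `between_pop_scale` (default 1.0,
which makes between-population shape distances numerically comparable to the
F_ST targets, ~0.03–0.15 — the range in which the reference morphological
matrices live). The concordance dial c ∈ [0, 1] blends these offsets with
random offsets: offsets(c) = c·u_genetic + (1−c)·u_random, where the random
offsets share one common norm (the RMS of the genetic offset norms).
Per-population norm matching would leak the genetic outlier structure into
the supposedly unstructured component and was observed to inflate the c = 0
null correlation to ~0.7; with a common norm the c = 0 recovered Mantel r
averages ~0.15 in magnitude. Each specimen is the template plus its
population offset, an age-linear allometric deformation (a fixed random unit
tangent vector times 0.004 per year — chosen so the full subadult ontogeny
spans ~0.07 shape units, comparable to between-population separation), and
isotropic Gaussian coordinate noise (default sd 0.004 in unit-size scale,
i.e. per-specimen shape scatter ≈ 0.05 — an internal calibration chosen so
that realistic distance magnitudes are attainable, not a value derived from
any empirical study). Raw coordinates are then produced by a random
rotation, translation, and an age-dependent centroid size (80/95/105/110 mm
with 4% lognormal jitter), so the pipeline must genuinely undo similarity
transforms.

The landmark template is a deterministic, bilaterally symmetric
pseudo-anatomical configuration on a half-ellipsoid shell (synthetic; not
derived from any specimen).

**What the synthetic bed does not show.** Noise is isotropic and
landmark-independent (real digitising error is not), allometry is linear and
shared across populations (real ontogenies can diverge), STR evolution has
no explicit mutation model, and within-population shape variance is an
internal convention. Passing recovery tests therefore demonstrates that the
pipeline detects structure it is pointed at — not that real cranial data
carry such structure.

## Numerical conventions

Degenerate configurations (fewer than 3 landmarks, or collinear landmarks)
are rejected before iteration. Distance matrices enforce symmetry to 1e-9,
zero diagonal, and nonnegativity at every construction. LDA posterior ties
are broken deterministically by the scikit-learn label order (sorted).
Permutation and Monte-Carlo p-values use the add-one convention; exact
enumerations do not (the identity permutation already guarantees p > 0).
All randomness flows from explicit integer seeds; the generator refuses to
run without one.

## Problem sizes

Default analysis sizes are those of the emulated design (232 landmark
specimens, 7 × 30 genotyped individuals, 50 loci); null-calibration checks
use 200–1000 replicate simulations of reduced systems (e.g. 12 specimens of
10 landmarks for permutation tests), and recovery checks use 5–20 seeds.
These sizes give Monte-Carlo error comfortably inside the asserted bands
while keeping a full run of the suite and the acceptance script in the
low minutes on a single CPU.
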
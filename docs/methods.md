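# Methods

This note documents the models and numerical choices behind `morphodtt`,
what the synthetic generator does and does not emulate, and the known
limitations.

## Superimposition

GPA is run with full-Procrustes conventions: every specimen is centred and
fixed at unit centroid size, then rotated onto the consensus by the proper
(determinant +1) Kabsch rotation; reflections are never used, since all
specimens are assumed digitized in the same view. The consensus is the
specimen mean re-normalized to unit centroid size, iterated until its RMS
change falls below `tol = 1e-10` (cap 100 iterations; exceeding the cap is
an error that reports the last change). Semilandmarks are treated as fixed
landmarks throughout: sliding (bending-energy or perpendicular projection)
is deliberately out of scope because it can introduce substantial
artificial deformation when shapes are heterogeneous.

Two details deserve explicit statement:

- **Residual reference.** The mean of unit-size aligned specimens has
  centroid size 1 − O(shape variance), so a unit-size consensus cannot be
  exactly the specimen mean. Residuals are therefore taken about the raw
  specimen mean (they then sum exactly to zero, which is what a covariance
  matrix assumes), while the reported consensus is that mean re-normalized
  to unit size. PCA centres its input regardless, so downstream statistics
  are unaffected by this choice.
- **Canonical frame.** GPA determines the aligned set only up to one
  common rotation. After convergence the consensus is rotated so its major
  principal axis lies along x, the 180° ambiguity resolved by the sign of
  the third moment of the x coordinates (falling back to y, then to the
  first landmark). This makes residuals invariant (to ~1e-6) under
  per-specimen similarity transforms and specimen reordering.

No tangent-space projection is applied before PCA; at the small shape
variances the pipeline targets (Procrustes distances ≲ 0.2) the difference
from working in the tangent plane is far below the statistical noise of
any disparity estimate.

## Ordination

PCA is the eigendecomposition of the (n−1)-divisor covariance matrix of
residuals; variance percentages are divisor-invariant. Eigenvector signs
follow a deterministic rule (largest-|loading| entry positive) so scores
reproduce across linear-algebra backends; every downstream statistic is
sign-invariant anyway. The broken-stick rule retains the contiguous block
of leading components whose observed proportions strictly exceed the
broken-stick expectation, stopping at the first failure — the contiguous
form is chosen because downstream analyses use a leading block of PCs, and
strict inequality is adopted as the tie-break.

## Time calibration and ancestral states

Tips are fixed at midpoint ages (FAD+LAD)/2 in Ma. Internal nodes are
dated post-order at `max(child age + min_bl)` with `min_bl = 0.1` Myr, the
most conservative (youngest) placement consistent with the minimum branch
length — hypothetical ancestors fall in the youngest bin they could
occupy, and calibration is monotone in tip ages. The tree is
non-ultrametric by construction.

Squared-change parsimony minimizes Σ (Δ)²/ℓ over branches (weighted form;
an unweighted switch exists because legacy software does not always state
its weighting). The criterion is a positive-definite quadratic, so the
optimum is the exact solution of the linear stationarity system; polytomies
need no special treatment, and zero-length branches are rejected in
weighted mode rather than regularized. The weighted root estimate equals
the Brownian-motion GLS/ML root, which the tests verify independently.
Ancestors are reconstructed for the same leading block of PCs used in the
disparity analyses (8 by default).

## Binning and disparity

Bin assignment uses `older ≥ age > younger` (older edge inclusive) so
boundary ages are deterministic; ages outside every bin are reported, not
silently dropped. Disparity is the sum of per-PC sample variances (SoV),
chosen for robustness to unequal sample sizes; cells with fewer than
`min_taxa = 3` members keep their count but no SoV. Group membership is
set-based: each terminal carries its own group, each ancestor the union of
its descendants' groups, and a node counts toward a (possibly composite)
named group iff its carried set is contained in that group's base groups.
A crown subclade's ancestors therefore count for the subclade and the
crown, while backbone ancestors with mixed descendants count only for
groupings spanning all their descendants — a conservative rule that never
attributes an ancestor to a group some of its descendants lie outside.

The disparity comparison statistic is |SoV(A) − SoV(B)| (two-sided), with
group sizes held fixed and taxa reshuffled between groups without
replacement; NPMANOVA uses the pseudo-F from the Euclidean
squared-distance decomposition with label permutation. Both tests use the
add-one estimator p = (1 + exceedances)/(1 + replicates), and tie counting
uses a 1e-12 relative tolerance so float summation order cannot drop exact
ties. Bonferroni correction (min(1, m·p)) is applied per results table.
Disparity-vs-sample-size correlations use Spearman's rank correlation with
pairwise deletion of undefined bins; with 7 or fewer defined bins the
p-value comes from the exact permutation distribution of rho rather than
the large-sample approximation.

## Synthetic studies

The generator emulates the statistical structure the pipeline assumes: a
forward birth–death tree started at a fixed root age with extinct lineages
retained as dated fossil tips (births stop at the tip budget, so the tip
count is exact); independent Brownian motion of each landmark coordinate
along branches (rate σ² per coordinate per Myr); per-specimen nuisance
rotation/translation/scaling with no reflection; symmetric stratigraphic
ranges whose midpoints equal true tip ages; a stem grade plus two crown
subclades (the crown picked as the deep clade closest to half the tips);
and equal-width time bins, the oldest widened to catch calibrated
ancestors slightly older than the root.

Defaults are one study of 40 taxa, 53 landmarks (15 fixed + 38
semilandmark-like outline points on an elongate template), root age 35
Myr, σ² = 2×10⁻⁴ — placing tip shapes a few percent Procrustes distance
from the ancestor, i.e. the small-variation regime of real cranial
datasets, with birth 0.25 and death 0.12 per Myr giving a realistic mix of
short- and long-lived fossil lineages.

What the generator does **not** emulate: correlated evolution among
landmarks (coordinates are independent BM, real skulls are strongly
integrated), digitization error, missing landmarks, non-Brownian dynamics
(trends, OU), or biased fossil sampling. Passing tests therefore show the
pipeline recovers truth when its own model assumptions hold; they do not
show robustness to violations of those assumptions.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale sizes chosen to
make Monte-Carlo conclusions stable: 1000 null datasets for the type-I
error of the disparity permutation test (199 permutations each, where the
add-one estimator is exactly nominal at α = 0.05), 500–1000 simulations
for NPMANOVA null uniformity (499 permutations each), 100 replicate
studies for ancestral-score recovery, and 200 fresh-tree replicates for
the SoV-growth trend. All randomness flows through
`numpy.random.Generator` seeded explicitly; pipeline sub-tests derive
per-comparison seeds from the run seed via `SeedSequence`, so rerunning a
configuration is byte-identical.

## Limitations

- 2D landmarks only; no NEXUS input; no semilandmark sliding by design.
- Lazarus gaps (a clade sampled in two bins but absent between them) are
  not modelled; handling them would require explicit evolutionary
  modelling beyond squared-change parsimony.
- Rarefaction and alternative disparity metrics (sum of ranges, mean
  pairwise distance) are out of scope; SoV was chosen for sample-size
  robustness.
- The permutation disparity test conditions on the pooled sample; with
  very small groups its p-values are coarse (the 3-vs-3 case has only 20
  distinct splits).
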
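# Methods

This note documents the models, numerical choices and limitations behind
`talogm`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Superimposition

Configurations are (k, 3) point sets in mm, one template topology per
study: anatomical (fixed) landmarks, curve semilandmarks with an ordering
and optional fixed anchors at curve ends, and surface semilandmarks.
Right-sided specimens are mirrored across the plane normal to the first
coordinate axis before analysis; the choice of reflection plane is
immaterial after superimposition but fixed for reproducibility, and the
mirror operation is an involution that preserves all inter-point
distances and centroid size.

Generalized Procrustes Analysis iterates: center each configuration,
scale to unit centroid size, rotate to the running consensus by the
Kabsch solution with the proper-rotation (det = +1) constraint, update
the consensus as the mean of the aligned specimens, until the consensus
moves less than `tol` (default 1e-10) or `max_iter` (100) is reached.
Size is recorded from the raw coordinates as centroid size CS and lnCS;
the returned consensus is the plain arithmetic mean of the aligned
specimens. The per-iteration total squared Procrustes residual is logged
(`residual_log`) and is non-increasing.

Because GPA output is only defined up to a global rotation, the final
consensus is canonicalized: rotated onto its principal axes, with the
sign of the first two axes fixed by the largest-|loading|-positive rule
and the third axis sign forced so the map is a rotation, never a
reflection. This makes the output invariant (to ~1e-8 and in practice
machine precision) under arbitrary rigid motion and scaling of any input.
A final clean-up pass re-rotates every specimen onto the canonical
consensus so that projecting a training specimen into a fitted
morphospace reproduces its stored scores exactly.

## Thin-plate splines and sliding

The 3D TPS uses the radial kernel U(r) = r, the standard choice in
landmark morphometrics. Fitting solves the dense (k+4) system exactly
(interpolation at control points); a ridge of 1e-10 × trace is added with
a warning when the kernel matrix conditioning exceeds 1e12, which can
happen with tightly clustered points. In 3D the upper-left k×k block of
the inverted system is negative semidefinite (the biharmonic fundamental
solution carries a negative constant), so the bending-energy matrix B
exposed by the package is that block negated: symmetric PSD with a
4-dimensional affine null space (constants plus the three coordinate
columns). The bending energy of a fitted map is trace(YᵀBY): zero iff the
map is affine, invariant to rigid motion of the target.

Semilandmark sliding minimizes total bending energy against the current
consensus. Per specimen, with B computed from the consensus and U the
sparse matrix of tangent directions (one column per curve point, two per
surface point), the tangent amplitudes solve

  (G ∘ B_sub) t = −rhs,

where G is the Gram matrix of the tangent directions, B_sub the
corresponding block of B, and rhs gathers the tangent components of
B(Y − C); the structure follows because each column of U touches exactly
one landmark. The step is the exact minimizer of a PSD quadratic form, so
bending energy never increases within a sliding iteration; re-centering,
re-scaling and consensus updates between iterations can move it slightly,
which the `sliding_log` records (energy before/after per cycle, consensus
change). The outer loop runs at most 5 sliding+GPA cycles with a 1e-8
consensus-change stop, matching common practice for recursive consensus
updates.

Tangent directions: curve points use the central difference of their
curve neighbours (one-sided at ends, through the anchoring fixed landmark
when declared); surface points use the two leading principal directions
of the local covariance of their K = 8 nearest neighbours (configurable).
K = 8 is the smallest neighbourhood that gave stable plane fits at the
template's surface density; on a unit sphere sampled at ~500 points the
estimated tangent planes are within 5° of the analytic ones, degrading at
sparser sampling as the neighbourhood cap grows.

Sliding is a tangent-space displacement without re-projection onto an
underlying surface: this is a coordinates-only pipeline (no meshes), and
it is the main expected source of small numeric divergence from
digitizer-based workflows that re-project on the mesh after each slide.

## Morphospaces

PCA is covariance-based (the variables share units) via SVD of the
centered data; each eigenvector is oriented so its largest-magnitude
loading is positive, pinning the arbitrary axis signs. Form space appends
one lnCS column to the flattened shape coordinates, centered but never
re-scaled — with realistic size variation the leading form axis then
carries nearly all size information (|r| with lnCS ≈ 1). New specimens
are projected after an ordinary Procrustes fit (center, unit CS, optimal
rotation) onto the model consensus, matching how the training rows were
built. Axis warps return mean + score·eigenvector reshaped to points,
with the implied lnCS reported separately in form space.

## Dimorphism statistics

Two-group comparisons use one-way ANOVA (df = 1, n−2; identical to the
squared equal-variance t). Cohen's d is (female − male)/pooled SD, so
male-larger size gives negative d. Achieved power uses the standard
two-sided two-sample noncentral-t formulation; published power figures
computed with other conventions can differ substantially from this one,
and the package deliberately implements only the standard form.

A group's allometric trajectory is the OLS slope vector of its shape or
form variables on lnCS. Trajectory "length" defaults to ‖slope‖ × the
group's observed lnCS range — the predicted shape-change magnitude across
the group's size range — with the raw norm behind `length="norm"`.
Pairwise angles are arccos of the unit-slope dot product. The permutation
test reassigns group labels (cell sizes preserved), recomputes
trajectories, and reports +1-corrected p-values (one-sided for angles,
absolute-difference for lengths); it is deterministic given the seed, and
the +1 correction keeps it valid (conservative). Degenerate permutations
(constant lnCS within a permuted group) are counted as extreme rather
than discarded. Empirically the angle test holds its nominal 5% level
(type-I error 0.03–0.05 over 500 null simulations) with power ~100% at
orthogonal trajectories and n = 100/group. Angles are computed in the
full variable space by default; on all PCs jointly this equals the
PC-space computation.

## Classification

LDA uses class means, a pooled within-class covariance with the n−2
denominator, and either frequency-proportional priors (the default for
cross-validated accuracy tables) or equal priors (the forensic convention
for single-specimen calls; fragment reports show both). Posteriors come
from the Gaussian class-conditional densities under the shared
covariance. Leave-one-out CV refits the LDA without each specimen; the
PCA itself is computed once on the full sample, matching common practice
in GM sex-estimation studies — this carries a small selection optimism,
and a stricter analysis can pass per-fold PCA scores to `loo_cv`
directly. The PC-count search evaluates m = 1..10 leading PCs and returns
the smallest m attaining the maximum LOO accuracy. CS-only classification
uses raw CS (not lnCS) as the single variable. On Gaussian equal-variance
data the LOO accuracy tracks the oracle Φ(Δ/2); with lnCS dimorphism
d = 2.5 at n = 98 this predicts ≈ 89% for CS-only classification, which
the synthetic experiments reproduce within a few points.

## Fragment reconstruction

Virtual resection flags every point strictly on the discard side of an
oriented cutting plane (boundary tolerance 1e-9 mm). Reconstruction fits
the reference mean onto the fragment's surviving points by ordinary
Procrustes superimposition *with scaling* — preserving the fragment's
pose and natural size so the completed CS is meaningful — then extends a
TPS fitted on the surviving points to the reference's missing positions.
Present points are never modified, the estimate is equivariant under
similarity transforms of the fragment, and at least 5 surviving points
are required. The completed specimen is not re-slid against the
consensus: sliding assumes trustworthy surface geometry that an estimated
region lacks. Assessment then superimposes the completed specimen on the
trained consensus, projects it into the stored form space, and reports
the discriminant call with P_post under both prior conventions.

Reconstruction error behaves as a bias-variance trade-off. Because the
TPS interpolates the surviving points exactly, their landmark noise is
transmitted into the estimated region with near-unit gain close to the
cut; this noise floor dominates at small resections, so the mean error is
nearly flat between 5% and 20% missing under realistic noise, and only
the deterministic extrapolation error grows with the resected fraction.
The experiments therefore separate the two: (i) under the noisy
study-scale conditions, the mean error at 20% plane resection against the
noise-free ground-truth morphology stays below the per-landmark noise SD
(≈ 0.73× at the preset conditions); (ii) the monotone growth of the
geometric extrapolation error is shown on noise-free specimens, measuring
a fixed tip region (the deepest 5% of points) as the resection deepens
through 5/10/20/40% — strictly increasing in every replicate.

## Synthetic generator

The generator is the package's study design in code. The base
configuration is a smooth ellipsoid blob (semi-axes 1.3 : 1.0 : 0.8) with
well-spread fixed landmarks, curve semilandmarks along bulged surface
arcs between fixed anchors, and surface semilandmarks over quadrant
patches; the study-scale template is 15 + 105 + 131 = 251 points. Each
specimen draws lnCS ~ Normal(μ_pop + sex offset, σ), adds the
population's allometric displacement slope·(lnCS − pivot)·v in the
tangent space of the base shape plus isotropic tangent noise, renormalizes
to unit CS, embeds at scale exp(lnCS) with a random rotation and
translation, and adds digitization jitter in mm. The allometric pivot is
the mid-sex mean; the sex offset is d·σ for a target lnCS Cohen's d.
Allometric direction vectors are spatially smooth displacement fields
(Gaussian-kernel-smoothed random fields with length scale ≈ the rms
centroid distance), projected orthogonal to all similarity directions
(translations, rotations, scaling) and combined through the Cholesky
factor of the cosine Gram matrix so requested pairwise trajectory angles
are exact. Smoothness matters: real allometric change is regionally
coherent, and landmark-wise white fields would make reconstruction
experiments meaningless because they carry no spatial structure to
extrapolate.

The study-scale preset uses the real sampling design (39 + 36 + 23
specimens in three populations with unbalanced sex cells), lnCS
dimorphism d = 2.5 with within-sex σ_lnCS = 0.05 (≈ 5% size CV, typical
of adult long bones; male CS ≈ 13% larger), female mean lnCS ≈ 5.7
(CS ≈ 300 mm for a 251-point talar configuration) with small population
offsets, allometric slope 0.03 shape-units per unit lnCS (modest, so
shape-space allometry is weak while form space is size-dominated),
per-coordinate tangent noise 0.0032 (placing the non-size shape variance
on the same footing as size variance, so form PC1 carries ≈ 50% of the
variance), and 0.05 mm jitter (surface-scanner accuracy scale).

What passing synthetic tests show — and what they do not. The generator
matches the analysis model exactly: linear allometry, isotropic Gaussian
noise, perfect landmark homology, no digitization bias, no asymmetry or
outliers, and an ellipsoid geometry far simpler than a talus. Passing
therefore demonstrates correctness and calibration of the algorithms
under their own assumptions (parameter recovery, test levels, oracle
agreement), not that real tali satisfy those assumptions; published
accuracy figures on real material remain the benchmark for field
performance, and `talogm.study` can re-run the pooled pipeline against a
deposited coordinate table when one is supplied.

## Numerical conventions and degenerate inputs

Flattening is point-major (x₁,y₁,z₁,x₂,…). Rotation fits reject rank-<2
configurations; TPS rejects <5, duplicated, or coplanar sources (advising
regularization); centroid size rejects coincident points; LDA rejects
singular pooled covariances with advice to reduce the PC count;
permutation tests guard degenerate groups. Text landmark tables are
written with 17 significant digits and read with round-trip float
parsing, so CSV/TSV round-trips are bit-exact. All stochastic components
(generator, permutation tests, experiment scripts) take explicit integer
seeds and are bit-reproducible.

Problem sizes in the shipped experiments: the study-scale preset (98 ×
251, GPA with sliding in a few seconds), 500 null permutation simulations
at n_perm = 200, 200 power simulations, n = 200/group trajectory-angle
recovery, 30–40 reconstruction replicates and 100 fragment replicates —
sizes chosen so the full suite runs in well under a minute of compute per
experiment while keeping Monte-Carlo error small relative to the bands
being checked.

## Known limitations

* Sliding without surface re-projection can let semilandmarks drift off
  the (unknown) true surface when displacements are large; with the ≤5
  cycle cap and realistic noise this stays small, but it is the main
  divergence from mesh-based pipelines.
* Partial/weighted GPA for incomplete specimens is deliberately absent:
  fragments are reconstructed first, then superimposed.
* The classifier is strictly linear (no quadratic or regularized DA);
  with small, unbalanced cells the pooled-covariance assumption is doing
  real work.
* Exact-interpolation TPS chases noise near resection boundaries (see
  above); a smoothing-spline variant would trade exactness at the
  surviving landmarks for lower variance in the estimated region.
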
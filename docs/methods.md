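# Methods

`srnfshape` implements elastic shape analysis of closed genus-zero
surfaces — the kind produced by model-based subcortical segmentation
(hippocampus, amygdala, putamen) — together with the statistical layer
that relates shape to clinical outcomes. This note records the model,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Surfaces and discretization

A surface is a map `f : S² → ℝ³` sampled on a regular
colatitude/longitude grid. The grid is staggered in colatitude
(`θ_j = (j + ½)π/n_θ`), so the poles — where the spherical area element
vanishes — are never node points. Quadrature uses the product rule with
weights `sin θ · Δθ · Δφ`, which converge to the sphere area `4π` under
refinement.

Derivatives are second-order finite differences: central in the
interior, one-sided at the first/last colatitude rows, periodic in
longitude. The longitude derivative is taken per unit arc length
(`f_v = (1/sin θ) ∂f/∂φ`), so the normal field `n = f_u × f_v`
satisfies `|n| dA = ` surface area element with respect to the round
measure `dA = sin θ dθ dφ`. This single convention makes every identity
of the framework hold discretely with one quadrature rule: the area is
`α_f = ∫ |n| dA`, the squared SRNF norm equals the area, constant
fields have `⟨h,h⟩ = 4π|h|²`, and reparameterization is norm-preserving
with the round-measure Jacobian. On the unit sphere `n(s) = f(s)`.

Interpolation at arbitrary sphere points (needed to evaluate `f∘γ`) is
a cubic spline on the grid extended exactly across the poles: a field
on the staggered grid satisfies `F(−θ, φ) = F(θ, φ+π)`, so for even
`n_φ` the ghost rows are mirrored rows rolled by half a period.

## SRNF representation and the elastic metric

The square-root normal field is `q(s) = n(s)/|n(s)|^½`. Its L² distance
is invariant under simultaneous rotation and reparameterization of both
surfaces, which turns the elastic comparison of shapes into

    d_s([q₁],[q₂]) = inf over O ∈ SO(3), γ ∈ Γ of ‖q₁ − O (q₂∘γ)√J_γ‖,

with Γ the orientation-preserving sphere diffeomorphisms. Translation
is removed for free (SRNFs ignore it); scale is removed by normalizing
every surface to unit area (coordinates divided by `√α_f`). Nodes with
degenerate normals are clamped at `10⁻¹² ×` the mean normal magnitude
before the SRNF division.

### Registration optimizer

- **Rotation**: solved in closed form by Procrustes SVD of the weighted
  cross-covariance, with the usual determinant correction; refreshed at
  every energy evaluation.
- **Coarse search**: the 60 rotations of the icosahedral group act as
  rigid domain reparameterizations (60 placements of the pole axis,
  `J ≡ 1`); all are scored and ties broken by group-element index.
- **Γ-descent**: the map is built up by composing small diffeomorphisms
  `p ↦ normalize(p + δ · b(p))`, where `b` ranges over the tangential
  gradients of the Cartesian monomials of degree ≤ 3 (restricted to the
  sphere these span the spherical harmonics of the same degrees) plus
  the three rotational Killing fields — 22 fields in total. The
  coefficient gradient is computed by forward differences of the energy
  (step `10⁻⁴`), the step chosen by a backtracking line search (initial
  0.1, halving, ≤ 20 halvings) that rejects any step with `J_γ ≤ 0`.
  The energy trace is non-increasing by construction; iteration stops
  at a relative decrease below `10⁻⁵` or 60 iterations.
- **Multi-start**: descent is run from the 3 best coarse candidates and
  the lowest-energy result kept. This guards against the coarse
  search's discrete minimum sitting in the wrong basin, at 3× the
  descent cost. A damped Gauss–Newton variant was evaluated and
  rejected: the sphere renormalization invalidates its quadratic model
  and it stalls at higher energies than plain descent.

The composition is applied on the *left* (`γ ← ψ_δ ∘ γ`) because the
basis fields are analytic and can be evaluated exactly at the image
points; small generators on either side generate the same group.

**Accuracy floor.** With 32×32 grids the two routes to a reparameterized
SRNF — `srnf(f∘γ)` versus `(q∘γ)√J_γ` — differ by a finite-difference
inconsistency of order `10⁻²` (L²), roughly quartering at 64×64. The
achievable registration energy sits at or above this floor, which is
why self-registration is exact but the recovery of a random
diffeomorphism leaves a shape distance of ~0.02–0.03 on unit-area
surfaces. Quantities that compare registered populations inherit this
noise; the triptych discussion below spells out the consequence.

## Karcher mean, PCA, scores

The Karcher mean alternates (i) registering every surface to the
current mean and (ii) replacing the mean with the nodewise average of
the registered surfaces, starting from the first surface in input
order. The Karcher variance `Σᵢ d_s(μ, fᵢ)²` is recorded per round; if
registration noise ever bumps it upward the previous round is kept, so
the reported trace is always non-increasing. Convergence: relative L²
change of the mean below `10⁻⁴`, at most 20 rounds.

Shape PCA vectorizes `fᵢ* − μ` and takes the thin SVD of the stacked
data matrix — identical, up to sign, to eigendecomposing the scatter
matrix `C = Σ VᵢVᵢᵀ` without forming it. The inner product is the plain
Euclidean one on vectorized surfaces (scores `z_d = ⟨vec(f−μ), U_d⟩`),
matching the covariance definition; on near-uniform grids it is close
to the area-weighted product. Reported "singular values" are the
eigenvalues of `C`. Null directions are dropped (at most `n−1` remain);
each direction's sign is fixed so its largest-magnitude entry is
positive. Reconstruction `f̂ = μ + Σ z_d U_d` is exact at full rank and
its Euclidean error is non-increasing in the number of components.

Geodesics are linear interpolations between `f₁` and the registered
`f₂*` — a visualization of the optimal deformation, not an exact
geodesic of the elastic metric.

## Synthetic data

The generator stands in for a restricted clinical imaging cohort, so
its defaults are chosen to emulate that setting at desk scale.

- **Base shapes** are analytic: a triaxial ellipsoid, optionally bent
  quadratically in the x–z plane into a banana-like tube reminiscent of
  a hippocampus. Closed-form areas and collinearity give test oracles.
- **Deformation modes** are random smooth scalar fields times the unit
  normal of the base, orthonormalized. Normal-direction modes change
  shape in a way reparameterization cannot absorb at first order —
  mimicking principal directions estimated from registered populations.
  Modes are additionally made area- and centroid-neutral to first order
  (exact functional derivatives by finite differences), because the
  per-sample unit-area normalization would otherwise fold a
  score-correlated scaling/translation component into the family and
  bias PCA recovery.
- **Mode scales** default to a few percent of the unit-area surface
  scale (standard deviations 0.03/0.02/0.01 in Euclidean norm) — large
  enough to dominate quadrature noise, small enough that the linear
  mode model stays faithful.
- **Random diffeomorphisms** compose a random icosahedral rotation with
  the flow of a random smooth tangent field integrated in 10 normalized
  Euler steps; amplitude 0.3 is the default scrambling level in the
  clustering experiment. Positivity of `J_γ` is verified and the
  amplitude internally halved if violated.
- **The two-class line**: 40 surfaces `fᵢ = μ + xᵢ v₁` with `xᵢ`
  uniform in (0,1] for the first twenty and [−1,0) for the last twenty
  (the stated intervals; uniform is the agnostic choice within them),
  `v₁` a unit-norm planted direction on a bent-tube mean.
- **Clinical covariates**: age uniform on 18–61 years; depression
  score (BDI) from a right-skewed Beta scaled to 0–63; intracranial
  volume Gaussian (1.4·10⁶ ± 1.2·10⁵ mm³). Outcomes (PSS 0–42,
  CTQTOT 25–125) are linear in planted score/main/interaction terms
  plus Gaussian noise (default SD 3), clipped to the instrument ranges
  *after* noise — clipping mildly biases coefficients near the
  boundaries, so planted models keep outcomes interior.

What the synthetic families do **not** emulate: segmentation artifacts,
spatially correlated measurement noise, non-linear mode interactions,
population covariance between shape and covariates, or any real
anatomy. Passing tests demonstrate correctness of the machinery and
recoverability under the planted model, not clinical validity.

## The clustering triptych

The registration diagnostic generates the two-class line, then (i)
clusters the raw distance matrix (and its 2-D classical-MDS embedding)
with an exact 2-medoid partition, (ii) scrambles every surface with an
independent random diffeomorphism and re-clusters, (iii) elastically
registers every scrambled surface to the mean and clusters the
registered distances. Registration to the mean (40 registrations) is
used instead of all-pairs registration (780): for a collinear family
through that mean the two protocols measure the same separation at a
fraction of the cost.

Expected behavior: aligned accuracy ≈ 100%, scrambled accuracy near
chance, restored accuracy ≈ 100%. Two caveats are inherent to the
design and worth stating plainly. First, `x` is sampled *densely up to
0*, so some draws place surfaces arbitrarily close to the class
boundary; even the aligned stage then has no margin and a single
boundary point can be assigned to either medoid. Second, the restored
stage inherits the registration floor (~0.02–0.03 in shape distance):
surfaces with `|x|` below roughly 0.2 sit within registration noise of
the mean, and their cluster assignment after restoration is not
guaranteed. On the raw restored distance matrix, accuracies of 90–100%
are the realistic range at 32×32. Clustering the low-dimensional
classical-MDS embedding of the same matrix — the representation the
original diagnostic is read from — is more robust, because the
registration residuals are close to isotropic in the high-dimensional
surface space and the embedding projects most of that noise away while
keeping the one-dimensional class structure.

## Regression layer

Ten designs relate an outcome (PSS or CTQTOT) to: covariates only
(age+BDI), scores only, main effects, main effects + score×age and
score×BDI interactions, and the interaction model + ICV. Main effects
use the first 15 scores per structure, interactions the first 5 per
structure (the "15 scores for each surface" is read as per-structure —
45 total over three structures). Score columns are z-scored before
product terms to tame interaction collinearity; a raw-scale option
exists. Fits are OLS with adjusted `R² = 1 − (1−R²)(n−1)/(n−p−1)` and
unadjusted two-sided t-test p-values (a Benjamini–Hochberg option is
off by default).

Stepwise selection is bidirectional on AIC (deterministic; best
add-or-drop move per step, stop when none improves), with a classic
p-value enter/remove variant (0.05/0.10) behind a flag. AIC's
per-variable false-inclusion rate under the null is ≈ `P(χ²₁ > 2) ≈
16%`, so with ~20 candidate predictors a pure-noise fit selects ~3–4
spurious terms; "near-null" behavior is therefore judged by the
selected model explaining < 5% adjusted variance (which holds in ~80%
of null replicates), not by literal emptiness — an impossible standard
for AIC.

Classical MDS is the Torgerson construction (double-center `−½D∘D`,
eigendecompose, scale by root-eigenvalues). The 2-medoid partition is
exact (exhaustive over medoid pairs, n ≤ 40).

## Spherical parameterization of meshes

Closed triangle meshes (legacy-VTK/OFF/PLY) are validated (manifold,
consistently oriented, Euler characteristic 2, outward via signed
volume) and embedded on the sphere in two stages: projected gradient
descent on the uniform-weight (Tuette) edge energy — whose minimizer is
unique up to rotation and supplies a bijective initialization — then
harmonic relaxation with cotangent weights (negatives clamped to zero)
and center-of-mass renormalization to prevent the Möbius collapse.
Both descents use backtracking line searches, so their recorded energy
traces are non-increasing. The parameterized surface is evaluated on
the regular grid by locating the spherical triangle containing each
grid direction (nearest face centroids first, brute force fallback) and
interpolating barycentrically. Grid resolution defaults to 64×64
(32×32 in the fast tests); the tooling accepts any size ≥ 3.

## Problem sizes used in the shipped experiments

Unit and acceptance tests run at 32×32 (registration-heavy protocols)
and 64×64/128×128 (pure-field identities such as invariance), with 40
surfaces in the clustering experiment, 100 surfaces in the PCA
recovery, and 100 replicates in the regression ensembles. These sizes
were chosen so the full suite exercises every claim at comfortably
interactive runtimes; all scale parameters are plain function arguments
and can be raised.

## Known limitations

- The registration optimizer guarantees monotone descent from the best
  coarse starts, not a global optimum; strongly symmetric shapes can
  tie in the coarse search (ties broken deterministically).
- `d_s` is evaluated on the discretized energy, so it is a metric only
  up to the discretization floor; symmetry holds to a few percent.
- PCA uses the Euclidean inner product on vectorized surfaces (the
  covariance definition printed in the field's formulas); an
  area-weighted variant is available but not the default.
- The mesh parameterization does not certify discrete conformality and
  does not handle genus > 0.
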
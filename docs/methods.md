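# Methods

## Atomic local frames and features

Each atom owns a right-handed axis system: the atom itself is the origin,
its highest-priority bonded neighbour defines the x-axis, the second-highest
the xy-plane, and ẑ = x̂ × v̂(plane) (right-hand rule), which places the
xy-plane atom at positive y. Priorities follow Cahn–Ingold–Prelog in spirit:
atomic number first, ties resolved by breadth-first comparison of
neighbour-sphere atomic-number multisets in the bond graph (origin excluded),
and any residual exact tie by the lower atom index — full CIP (isotopes,
stereodescriptors) is deliberately not implemented, since the frame only
needs a deterministic, chemically sensible choice. Terminal atoms (one
neighbour) borrow their xy-plane atom from the x-axis atom's neighbours.
Connectivity uses the covalent-radius rule `d < 1.2 (r_i + r_j)` with a
shipped radius table; the factor 1.2 is the common heuristic and is not
otherwise tuned.

Features of one atom: the two frame distances and the frame valence angle,
then (r, θ, φ) of every other atom in ascending index order — 3N−6 numbers.
θ ∈ [0, π], φ ∈ [−π, π]; every third non-ALF feature (indices 5, 8, 11, …)
is azimuthal and flagged cyclic. Distances are in Å by default with a
documented Å↔bohr converter; models record their unit in metadata.
Feature vectors invert to Cartesian coordinates up to a rigid motion
(`reconstruct_geometry`), which the tests use as a round-trip oracle and the
conformer sampler uses as its rebuild step.

One consequence of the right-handed construction worth knowing: a mirror
image of a molecule maps θ → π−θ while *preserving* azimuthal angles and all
distances (for a reflection M, (Ma)×(Mb) = −M(a×b), so the local z-axis
flips). Enantiomers are therefore distinguishable in feature space through
the polar angles.

Degenerate frames (the three ALF atoms collinear within 1e-8 rad) raise
rather than silently producing an ill-defined axis.

## GP regression

One model per atom per property. The kernel is a correlation function
(unit diagonal): the product over dimensions of

* `exp(−Δ_d² / (2 l_d²))` on ordinary dimensions,
* `exp(−2 sin²(Δ_d/2) / l_d²)` on azimuthal dimensions (period fixed at 2π),

the canonical forms tagged `rbf-expsin2-v1` in every model file so stored
lengthscales are unambiguous. The nugget σ² (default 1e-8, floor 1e-12) is
added to the covariance diagonal; Cholesky factorization gets exactly one
retry at 10× nugget before raising with the smallest eigenvalue — scrubbed
training data should be smooth, so persistent failure means bad inputs, not
something to paper over.

Both the constant mean and the process variance are profiled out of the
marginal likelihood: μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1), σ̂² = (y−1μ̂)ᵀR⁻¹(y−1μ̂)/n, and
the concentrated log-likelihood −(n/2)[ln(2πσ̂²)+1] − ½ln|R| depends only on
the lengthscales. σ̂² is floored at 1e-16 so constant targets stay finite
(the likelihood then degenerates gracefully and the optimizer returns an
interior point). Prediction weights w = R⁻¹(y−1μ̂) are precomputed at fit
time, making each prediction O(n).

The predictive variance is the mean-corrected ordinary-kriging form,
reported on the correlation scale:
`s² = 1 − rᵀR⁻¹r + (1 − 1ᵀR⁻¹r)²/(1ᵀR⁻¹1)`.
On this scale the contracts are exact: s² ≈ σ² at a training point and
s² → 1 + 1/(1ᵀR⁻¹1) far from all training data (where the prediction itself
reverts to μ̂). Multiply by σ̂² (`scale="process"`) for property units; the
active-learning ranking is scale-invariant either way.

## PSO hyperparameter search

Lengthscales are optimized in log₁₀ space over [−3, 3] per dimension
(positivity plus a scale-free search). The velocity update is the canonical
`v ← ωv + c₁r₁(p_pb−p) + c₂r₂(p_gb−p)` with r₁, r₂ drawn per particle *and*
per dimension (strongest decorrelation; common practice). Positions are
clamped to the box and the offending velocity component zeroed. Package
defaults — 50 particles, 300 iterations, ω decaying linearly 0.9→0.4,
c₁ = c₂ = 2, relative-improvement stall-stop (50 iterations at 1e-8) — are
our defaults, not values taken from any reference; all are configurable.

Initialization is mixed: half the swarm uniform over the whole box, half in
the long-lengthscale half [0, 3]. The smooth contingent is essential in high
dimension (90+ hyperparameters), where almost every fully random particle
contains a correlation-killing short lengthscale and the swarm otherwise
only ever sees the flat white-noise plateau of the likelihood; the uniform
contingent keeps low-dimensional searches from stalling on the equally flat
long-lengthscale plateau. Within the active-learning loop each retrain
warm-starts particle 0 from the previous iteration's best lengthscales.

## Active learning

Per-atom splits: every atom owns its training set and sample pool; all atoms
share one validation set. The seed training set is the min–max–mean
selection (per feature dimension: the frames holding the minimum, the
maximum and the value nearest the arithmetic mean, ties to the lower frame
index; duplicates removed, so ≤ 3D points) plus, by default, 1000 random
frames. Default split sizes are a 100 000-point sample pool and 500
validation points, scaled proportionally when the trajectory is smaller.
Each iteration: retrain (PSO) → score validation → pick the `batch`
(default 5) pool points with the highest predictive variance (ties to the
lower index) → label them → scrub → extend. Scrubbing removes points with
integration error L(Ω) > 0.001 a.u. — strictly greater, so a point exactly
at the threshold survives. The loop stops at the iteration cap, a target
RMSE, or pool exhaustion, and appends one row per iteration to a
machine-readable learning-curve table.

## Multipolar electrostatics

Moments are real spherical components Q_lm, l ≤ 4, Racah-normalized and
Condon–Shortley-free, ordered m = 0, 1c, 1s, … within each rank; every
moments file declares this convention in its header so a mismatched
convention fails loudly instead of silently rotating wrongly.

Rather than transcribing Wigner-matrix and interaction-tensor tables (and
inheriting some textbook's phase convention), both objects are built
numerically from the package's own harmonic basis:

* the 25×25 rank-block rotation matrix is Δ_ij = ∫ Y_i(Wr̂) Y_j(r̂) dΩ,
  evaluated by Gauss–Legendre × trapezoid product quadrature — the integrand
  is a polynomial of degree ≤ 8 on the sphere, so the quadrature is *exact*
  to machine precision, not an approximation;
* the interaction matrix T of the bipolar expansion
  `1/|Rẑ + b − a| = Σ R_l1m1(a) R_l2m2(b) T` is obtained once (cached) by
  projecting the exact Coulomb kernel onto the product harmonic basis of two
  spheres of radius 0.33 bohr about sites 1 bohr apart; orthogonality
  isolates each (l₁, l₂) block exactly and aliasing decays geometrically
  with the quadrature order (40×80 nodes per sphere leaves relative errors
  near 1e-9 on the rank-4 blocks). Blocks rescale as R^−(l₁+l₂+1).

A general pair energy rotates both (global-frame) moment sets into the frame
whose +z is the inter-site vector and contracts through T, truncated at
rank L′ per atom (L′ = 0 is exactly q_Aq_B/R; L′ = 4 includes everything up
to hexadecapole–hexadecapole). Joint-rotation invariance is automatic by
construction. Correctness is validated exclusively against exact
point-charge Coulomb sums, which ties every convention choice together
end to end. Penetration energy is excluded by construction (point
multipoles); separations below a configurable 1 Å guard are refused or
warned about, since the multipole series need not converge there. Moments
are in atomic units, distances in Å (converted internally), energies
reported in kJ/mol; 1 kcal = 4.184 kJ is pinned in one place.

Dimer fixtures are built by applying an orthonormal (optionally improper)
matrix plus a translation to a copy of the monomer, with a clash guard that
names the offending atom pair. The transform distribution used in tests is
our own; per-pair RMSE heatmaps store linear values, log colour scaling
being a rendering option.

## Validation metrics

Signed prediction error is true − predicted; the molecular total is the
difference of sums over atoms (cancellation expected). S-curves sort
*absolute* errors (our choice; signed curves are also defensible) and assign
point k of n the percentile 100k/n; `percentile_at_threshold` is inclusive
(≤) and right-continuous. The MAE correlation report pairs two properties'
per-atom mean absolute errors by atom tag and returns Pearson r and r² — a
strong positive correlation is the justification for reusing an
energy-optimized training set for multipole models instead of running one
active-learning campaign per property.

## Synthetic data generator

The sampler perturbs all 3N−6 internal degrees of freedom of a template by
distorting the atom-0 feature vector and rebuilding Cartesians: distances by
±0.05 Å, polar/valence angles by ±0.15 rad, azimuthal angles by ±0.3 rad or
— in full-rotation mode — redrawn uniformly on [−π, π) (free-rotor
behaviour). Frames with any interatomic distance below 0.5 Å are resampled
and counted. Defaults emulate a room-temperature ensemble of a semi-rigid
molecule; what the generator does *not* emulate is anharmonic mode coupling,
correlated backbone motion, or Boltzmann weighting — so passing tests show
the pipeline machinery is correct on smooth periodic surfaces, not that any
particular molecule's property surface is learned to chemical accuracy.

The label surface is a sum of Morse-like terms `De(1 − e^{−a(r−r₀)})²` in
each distance feature (r₀ = template value), low-order cosine series in
polar/valence angles, and full sine+cosine series (3 harmonics) in each
azimuthal feature — 2π-periodic and C¹-smooth by construction. Per-dimension
coefficients are frozen from the seed, and each term is weighted by
exp(−rank/2.5) in the owning atom's non-ALF rank: a locality decay emulating
the fact that an atomic property depends mostly on nearby atoms. Without it
a 93-dimensional additive surface with uniform weights is unlearnable by
any GP at a few hundred training points and the learning-curve checks would
measure nothing. Simulated integration errors L(Ω) are log-normal about
1e-4 a.u. with a 2% heavy tail above the 0.001 a.u. scrubbing threshold, so
scrubbing always has real work in tests. Labels and errors are reproducible
from (seed, frame index) regardless of evaluation order. Four idealized
templates ship as plain-text XYZ (3, 19, 24 and 33 atoms), covering feature
dimensions 3 through 93.

## Desk-scale problem sizes

The package's own test and acceptance runs use deliberately small problems:
the 93-dimensional learning-curve check samples 1200 conformers, seeds
training with the min–max–mean set only (no random extras), keeps a
700-point pool and 200 validation points, and runs PSO with 16 particles ×
60 iterations (stall 20) warm-started between the 10 retrains; lengthscale
recovery uses n = 60 in 3 dimensions with the default swarm. These sizes
are the package's choices for a self-contained demonstration; production
campaigns would use the full defaults (100 000-point pools, 500 validation
points, 50×300 PSO).

## Known limitations

* No prediction gradients/forces, periodic-boundary electrostatics, sparse
  GPs, or multi-output models.
* Lengthscale bounds [−3, 3] in log₁₀ assume features in Å/radians of
  roughly unit scale; heavily rescaled features need rescaled bounds.
* The CIP tie-break (neighbour-sphere multisets, then lowest index) is a
  documented choice; molecules whose frames depend on stereodescriptors
  would need full CIP.
* Whether upstream feature sets are in bohr or Å must come from the model
  metadata; the converter changes distances only.
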
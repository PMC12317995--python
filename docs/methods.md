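# Methods notes

This note records the scientific and numerical choices behind `curvmap`:
what each stage computes, which knobs matter, what the synthetic fixtures do
and do not emulate, and where the open design decisions were settled.

## Surfaces

Two routes produce the triangulated molecular surface the descriptors live
on.  `import_msms` reads the `.vert`/`.face` dialect written by the MSMS
program (1-based face indices; per-vertex normals and nearest-sphere
indices), for users who already run an external mesher.  The native mesher
`build_surface` triangulates the **solvent-accessible** surface — the zero
level set of f(x) = minᵢ(|x−cᵢ| − (rᵢ + r_probe)) — by marching cubes on a
regular grid, with normals from the outward distance gradient.  It is
watertight by construction and handles disconnected components, but it is
not a reduced-surface (SES) computation; which surface a feature table was
built on is recorded in its provenance.  Defaults: probe 1.4 Å (water),
grid spacing 0.6 Å (area of a probe-inflated atom converges to well under
2% there; 0.8 Å is adequate for the toy fixtures, 0.3–0.4 Å for convergence
studies).  Per-vertex area weights allocate one third of each incident
triangle.

SASA follows Shrake–Rupley: 960 Fibonacci-spiral test points per atom on the
probe-inflated sphere (quadrature error well under 1% for an isolated atom);
a point is buried if it falls inside any other inflated sphere.

## Curvature

Principal curvatures come from a local quadric fit: the 1-ring neighborhood
(2-ring when fewer than 5 neighbors) is projected onto the tangent plane of
the vertex normal and w = a·u² + b·uv + c·v² fitted by least squares; κ₁ ≥ κ₂
are the negated eigenvalues of [[2a, b], [b, 2c]].  Omitting linear terms is
deliberate — the mesher provides trustworthy normals, and constraining the
fit to pass through the tangent plane stabilizes it on the ~5–8-neighbor
stencils marching cubes produces.  Accuracy on analytic fixtures: ≤1% on a
R = 10 Å icosphere, ≤3% on a unit saddle, ≤5% on cylinder and torus.

**Orientation.**  Shape index is computed as s = (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂))
with κ₁ ≥ κ₂, so the denominator is non-negative and the sign of s equals
the sign of the mean curvature: convex protrusions → +1, cavities → −1.
The opposite printed convention (κ₂−κ₁ in the denominator) circulates in the
literature; the penalties below assume protrusion-positive, so this package
commits to it everywhere (fields, fixtures, docs).  Umbilic points take the
continuous limit s = ±1; flat points take s = 0 by convention.  Isolated
vertices with no usable neighborhood are flagged invalid and excluded from
patch averages and feature sums rather than aborting the surface.

Patch averaging is the unweighted mean of (s, c) over the **closed**
Euclidean ball (the point itself always included, so the mean is total);
an area-weighted variant exists behind a flag.  Penalties are evaluated on
the averaged (s̄, c̄), not averaged after evaluation.  Cut-offs 1, 5, 10 Å
correspond to atom-, residue- and neighborhood-scale shape.

## Physico-chemical fields

MLP weights are the Fermi kernel g(d) = 1/(e^{1.5(d−4.0)}+1) (half-decay at
4 Å — the carrier range of the hydrophobic effect; g < 0.01 beyond ~7.1 Å).
Atoms with g < 1e−4 (d ≳ 10.1 Å) are dropped from numerator and denominator;
this changes values by < 1e−3 relative while keeping the sum local.  The
projection is a convex combination, so MLP is bounded by the extreme atomic
f values.

Two hydrophobicity scales ship as packaged CSVs, each min/max-normalized to
[−1, 1] with the affine parameters stored on the scale object: a
residue-level interfacial-partitioning scale (values sign-flipped so
hydrophobic residues are positive, aligning its "+" channel with the logP
convention) and an atomic logP-contribution scale typed by a residue/atom-
name heuristic (aromatic-ring carbons, backbone carbonyl, polar N/O, S,
hydrogens by partner) with element-level fallback — a bonded topology is
not available from a bare PDB, so SMARTS-exact typing is out of reach; the
class table is labelled non-normative.

The electrostatic field is honest about its fidelity: `screened_coulomb` is
a linearized Debye–Hückel sum (kT/e units; Bjerrum length ≈ 7.0 Å and Debye
length ≈ 7.9 Å at the 0.15 M / 298 K defaults) in a uniform solvent
dielectric — *not* a Poisson–Boltzmann solution, as it has no low-dielectric
protein interior.  `grid_import` interpolates an OpenDX grid produced by a
real PB solver and is the faithful path; the potential source is recorded in
provenance.  Distances under 0.1 Å from a point charge are clamped.
Partial charges default to a coarse bundled table (±1 split over the
terminal atoms of Arg/Lys/Asp/Glu side chains and the C-terminal
carboxylate; everything else neutral — appropriate for formulation pH ≈ 6,
where His is treated as neutral); a PQR file overrides both charges and
radii when force-field values are needed.

## Features

F = Σ_A φ·P(s̄, c̄) is an **unweighted** sum over mesh points whose nearest
atom's residue carries the region label, matching the defining equation as
written; because an unweighted sum scales with mesh density, the pipeline
fixes density per run and records it, and an area-weighted mode (φ·P·dA) is
available.  The "−" signature uses the φ⁻ channel kept negative (taking
|φ⁻| would silently flip correlation signs downstream).  Empty regions
contribute 0, not NaN, so a small CDR absent from the surface of one frame
cannot poison a whole table.  Frame statistics are MIN/MAX/AVG and the
population variance; frame subsampling (stride) is supported and recorded.

## Regression protocol

Screening keeps descriptors with two-sided Pearson |r| ≥ 0.4 and p < 0.05
(t distribution, n−2 dof) after dropping constant columns and columns with
any value beyond 3σ of the column mean.  An optional dataset-level
pre-filter likewise drops molecules whose *response* lies beyond 3σ.  All
C(m, 3) combinations of survivors are then evaluated by LOOCV.

Model defaults (hyperparameters are a documented choice, configurable, not
fitted): linear OLS; k-NN with k = 3 (sensible at n ≈ 20); RBF-kernel SVR
with C = 1, ε = 0.1; random forest and gradient boosting with 500 trees
(depth 2, learning rate 0.1 for boosting).  k-NN and SVR standardize
features inside each training fold via a pipeline, so no fold sees held-out
statistics; tree models and OLS use raw features.

For OLS the LOOCV residuals are computed exactly via the hat-matrix identity
e_i/(1−h_ii), vectorized across all combinations (the refit-per-fold loop is
retained as the general path for the other models and as an independent
cross-check; the two agree to ~1e−14).  Ranking is by out-of-fold r
descending, ties broken by MSE then lexical feature names, so results are
deterministic.  R² is computed on pooled out-of-fold predictions as
1 − SS_res/SS_tot and can be negative.

**Permutation analysis.**  Response vectors are shuffled with controlled
degree (Pearson r between original and permuted y).  Pure random
permutations of 20 values cluster near degree 0, so the generator mixes
swap ladders started from the identity (k = 1..n random pairwise swaps,
cycled — degrees decaying from +1) with full random shuffles, the ladder
dominating 4:1 so the informative high-degree range is well sampled; the
identity is always vector 0 and reproduces the unpermuted metrics exactly.
Note that strongly *anti*-correlated responses (degree ≈ −1) are not a good
null for a linear model — it fits a sign-flipped signal equally well — which
is why the generator does not manufacture them deliberately.

## Synthetic fixtures: what they do and do not show

Analytic meshes (icosphere, plane, open cylinder, saddle graph, torus) carry
exact normals and closed-form κ₁/κ₂ from the fundamental forms; they
validate the estimator but are far smoother than molecular surfaces.
Toy proteins are jittered-lattice carbon clusters (single-atom residues
cycling a few amino-acid names across chains H and L) with optional motifs:
a 3-atom stalk whose tip raises the 5 Å patch shape index well above the
globule baseline, and an 8-atom rim ring whose central pocket is concave at
the 1 Å patch scale (at 5 Å the convex rim dominates the average — pocket
detection is a local-scale signal).  Trajectories add isotropic Gaussian
jitter (default σ = 0.3 Å), enough to exercise MIN/MAX/AVG/VAR but in no
way an MD ensemble.

The planted-signal study generator draws 20 molecules × 40 descriptor
columns; three planted columns share a latent factor (pairwise ρ = 0.5, so
each correlates ~0.8 marginally with the response, comparable to real
retained descriptors), coefficients (1.0, 0.9, 0.8), noise σ = 10% of the
signal SD, and the response affinely placed at mean 0.5, SD 0.3 on the
10⁻⁴ mL/(mg·week) scale.  Passing the recovery checks shows the
filter-search machinery finds a true sparse linear signal at this n/p and
noise level; it says nothing about whether real aggregation rates *are*
linear in three descriptors.  With Gaussian columns the 3σ screen
occasionally (≈1 column in 30) discards a planted column outright — a
faithful property of that filter at n = 20, visible as sporadic recovery
misses.

## Problem sizes and determinism

The shipped tests and the acceptance script run on deliberately small
instances chosen as converged-enough for their tolerances: subdivision-3
icospheres (642 vertices), 625–2048-vertex parametric grids, 10–30-atom toy
proteins at 0.5–0.8 Å grid spacing, 2-frame trajectories, 50 replicate
studies.  Every stochastic step takes an explicit seed; feature tables are
bit-identical across repeated runs on identical inputs.

## Known limitations

* The native surface is SAS, not SES; curvature magnitudes on real proteins
  differ between the two conventions.
* The screened-Coulomb field is a stand-in; quantitative ECM features should
  use imported PB grids.
* Atom typing for the logP scale is heuristic without a bonded topology.
* No protonation prediction, missing-residue modelling, or MD: trajectories
  are consumed, never generated (beyond Gaussian jitter for testing).
* Exact reproduction of published per-dataset performance numbers requires
  the corresponding measured rates and trajectories, which are not
  redistributable; the planted-signal study is the in-repo analogue.
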
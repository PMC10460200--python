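# Methods

`fdot` simulates frequency-domain (FD) diffuse optical tomography of the
neonatal head with two forward solvers and quantifies, on a synthetic
phantom population, the approximation error incurred when an
atlas-style anatomy replaces the subject's own anatomy.  This note
records the models, the numerical choices and the limits of what the
synthetic experiments can show.

## Physical model and units

Units are fixed package-wide: lengths in mm, time in ns, absorption and
scattering coefficients in mm⁻¹, modulation frequency in GHz (so that
2πf·t is in radians), speed of light c₀ = 299.792458 mm/ns.

The head is a bounded voxel (or tetrahedral) domain segmented into five
tissue compartments — combined scalp-and-skull (S&S), subarachnoid
semidiffusive CSF (CSF-1), clearer sulci/ventricle CSF (CSF-2), grey
matter (GM), white matter (WM) — each with constant absorption μₐ,
scattering μₛ, anisotropy g and refractive index n.  The default table
holds literature values for neonatal tissue at 800 nm; CSF-2 is solver
specific (clear for the Monte Carlo solver; identical to CSF-1 for the
diffusion solver, where a near-void layer would invalidate the
diffusion approximation).  n and g default to the common value 1.4 /
0.9 in every compartment but may be set per tissue.

Sources and detectors are circular patches of radius R = 1.5 mm on the
boundary.  Measured quantities per source-detector pair are the complex
intensity X + iY of the photon density wave at modulation frequency f
(default 0.1 GHz), reported as log-amplitude ln A = ln√(X²+Y²) and
phase delay φ = atan2(Y, X).  Pairs with source-detector separation
(SDS) ≥ 55 mm are masked out of all analysis vectors, and the same mask
is applied to measurements and Jacobians.

## Monte Carlo solver

Voxel-based photon-packet transport under the microscopic Beer-Lambert
law (mBLL): trajectories are sampled from μₛ and g only; absorption
enters afterwards through the detected weight w_p = exp(−Σⱼ μₐ,ⱼ l_pj),
where l_pj is the exact chord of photon p in voxel j, accumulated by
axis-aligned ray marching.  Free paths consume a dimensionless optical
depth across voxel interfaces, which is equivalent to rescaling the
remaining step by the ratio of old to new μₛ; zero-μₛ voxels are
crossed ballistically.  Deflections are Henyey-Greenstein.  At the
exterior boundary a binary reflect/exit decision is drawn from the
unpolarized Fresnel reflectance with the face normal; exits within R of
a detector centre are recorded (detector id, per-voxel partial paths,
time of flight).  Launch is uniform on the source disk, collimated
toward the probe's centre of curvature, starting just inside the
boundary with full weight (no specular launch loss).

Each photon's random stream is derived from (seed, launch index) with a
counter-based generator (splitmix64 seeding, xorshift64* stream), so a
stored detection record can be *replayed* bit-exactly from its handles;
the strict-replay path re-traces only the detected photons and is
tested for bit equality with the stored records.

Termination: exit through the boundary or a time-of-flight cutoff
(default 5 ns ≈ 1.07 m path at n = 1.4).  No Russian roulette is needed
because absorption is not applied during transport.  The cutoff
truncates the extreme late tail at large SDS; it is configurable and
its default was chosen so that the truncated weight is negligible at
the separations used here.

FD measurements per unit source strength are X = Σ w_p cos(2πf t_p),
Y = Σ w_p sin(2πf t_p), divided by the number of launched photons.

### Replay Jacobians

Because trajectories are absorption independent, the derivatives of X
and Y with respect to per-voxel absorption are exact sums over detected
photons (−Σ l_pj w_p cos/sin(2πf t_p)); ln A and φ rows follow from the
chain rule dlnA = (X dX + Y dY)/A², dφ = (X dY − Y dX)/A².  Difference
quotients under μₐ ± δ need only reweighting (no re-transport) and
serve as the independent validation; the two routes agree to ≲10⁻⁸
relative (the 1% acceptance bound is extremely conservative; the
residual is the O(δ²) truncation of the quotient).  Jacobian values are
normalized per absorption change in 1 mm³ (divided by the voxel
volume), in mm (ln A) and rad·mm (φ).

## Diffusion-approximation solver

P1 (linear tetrahedral) FEM for
−∇·(κ∇Φ) + (iω/c + μₐ)Φ = 0 with κ = 1/(3(μₐ+μₛ′)), μₛ′ = (1−g)μₛ, and
Robin boundary condition (1−ρ)Φ + 2(1+ρ)ν·κ∇Φ = 4Q.  The effective
reflection coefficient ρ is computed once from the tissue refractive
index against air by numerically integrating the unpolarized Fresnel
reflectance moments over the hemisphere of incidence angles
(ρ(1.4) ≈ 0.4935), cached per index pair.  The source Q is the
characteristic function of the source patch divided by its area; the
sensor functional is M = ½(1−ρ)/(1+ρ)∫P Φ dS with P the characteristic
function of the sensor patch.  A boundary facet belongs to a patch if
its centroid lies within R of the optode centre (nearest facet as
fallback so patches always have positive area); geometrically
overlapping optode disks are rejected.

All P1 products are integrated exactly (element stiffness from constant
barycentric gradients, element mass V/20·(1+δᵢⱼ), boundary mass
A/12·(1+δᵢⱼ)).  The complex symmetric system is factorized once
(SuperLU) and reused for all source and adjoint (4P boundary source)
right-hand sides; for CW (ω = 0) systems a Jacobi-preconditioned CG
path is available and used for fine validation meshes.

The Fréchet derivative of M with respect to element absorptions,
¼(1−ρ)∫ζ(∇Φ·∇Φ*/(3(μₐ+μₛ′)²) − ΦΦ*)dx, treats κ as a function of μₐ
(first term) and is *exact for the discrete system*: the
perturb-and-resolve validation solves the perturbed system through a
rank-4 Woodbury update of the base factorization, so central
differences at δ = 10⁻⁵ mm⁻¹ match to ~10⁻⁷ relative.  Phase sign
convention: the complex measurement is conjugated so that φ is the
(positive) phase delay, matching the MC convention.

Validation: the CW ball solution is checked against the exact
Legendre–Bessel series for a homogeneous sphere with a polar-cap
diffuse source (median nodal error ~1% at production mesh density), and
the assembly against a manufactured plane-wave solution.  MC and DA
agree on a homogeneous diffusive slab to ~2.5% in the ln A-vs-SDS slope
and ~1% in the phase slope over SDS 16–32 mm.

### Meshing

Tetrahedral meshes are built by a conforming Kuhn 6-tet subdivision of
the voxel grid (every cube split along the same main diagonal, hence
face-consistent), preserving per-tissue volumes exactly.  Optional
refinement splits marked voxels into 8 subvoxels; the surrounding layer
becomes star-shaped transition cells (fans from the cube centre with
face triangulations chosen by a global rule) so the mesh remains
conforming without hanging nodes.  Structured icosphere shell and ball
meshes are provided for validation against closed forms.  Simulation
meshes are built from majority-label downsampled voxels (default
2.5 mm for the population study); the staircase boundary is shared by
construction across all registered anatomies, which is what makes their
Jacobians element-wise comparable.

## CSF two-compartment split

The CSF outside the ventricles is split by solving Δu = 0 on the CSF
domain minus a one-voxel plate along the longitudinal fissure (the
plate spans the midline from the bottom of the cerebrum, taken as the
minimum z of GM∪WM, upward).  Dirichlet data: u = 0 on facets touching
brain (GM/WM), u = 1 on facets touching S&S or the plate.  Nodes within
a neighbourhood radius a (default 1.0 mm — two fine voxels, just enough
to buffer single-voxel junction artefacts) of any node carrying both
conditions are left unconstrained (natural Neumann condition), which is
exactly the "leave the Dirichlet condition undefined at junction nodes"
device that keeps the problem well posed; if the two Dirichlet sets
still meet (a = 0 with a genuine brain-skull contact) the construction
fails loudly.  The discrete system is solved with Jacobi-CG to 10⁻¹²;
on the right-tetrahedra meshes the discrete maximum principle holds, so
u ∈ [0, 1].

Voxels are relabelled by the value of u at their centre (the mean of
the 8 corner nodes, which is the exact P1 average): u > θ → CSF-1,
u ≤ θ → CSF-2, ventricles always CSF-2; plate voxels take the nearest
node value.  θ = 0.6 follows the expert-chosen operating point of the
segmentation algorithm this reimplements; whether it is optimal for
phantoms is untested and it is exposed in the configuration.  On
concentric shells (r 10→12 mm) the FEM field matches the closed form
(1/r_in − 1/r)/(1/r_in − 1/r_out) to ~10⁻⁵ at mid-radius on structured
meshes, and the θ = 0.6 interface lands at 100/9 mm within half a voxel
on the voxelized phantom.  The split is applied to the MC tissue model;
the DA optics table maps CSF-2 to CSF-1 values, reflecting that a clear
layer is outside the diffusion model's validity.

## Registration

Cranial point sets (249 grid positions + Iz, Nz, LPA, RPA, Cz) drive an
affine fit minimizing RE = SRE + γ₁·LRE1 + γ₂·LRE2 (mean squared
distances over all 254 points, over {Iz, Nz}, and over {LPA, RPA}).
The stacked least-squares system carries diagonal weights
√(γ)/√(#observations) per block and is solved about the nasion after
matching the subject's Nz to the reference Nz; γ₁ = 0.45, γ₂ = 0.55 are
fixed midpoints of the visually-tuned ranges used by the procedure this
reimplements (an automated pipeline has no visual step).  Reflections
(negative determinant) are rejected.  A second stage solves per-axis
anisotropic scales from closest-point surface pairs in the probe region
(all surface points within 60 mm of the probe centroid); pairing and
scales are iterated ICP-style because a single pass under-recovers
larger deformations.

The warped subject is resampled onto the reference grid (nearest
label), the reference's 2 mm S&S shell is stamped on top, exterior
bumps are cut and interior slack is relabelled S&S, so that every
accepted anatomy shares the reference exterior bit-exactly (and hence
the optode placement).  QC mirrors the study rules: (1) within the
probe region, pre-fill head-mask differences may involve only S&S and
CSF-1, with at most 10 mm³ of CSF-1 difference (volume reading of the
ambiguous "10 mm³ voxels"; configurable); (2) no WM voxels may be
removed from the probe region.  Failing subjects are rejected and
counted.

## Phantom population

The synthetic stand-in for a segmented-MRI database is a layered
ellipsoidal head: S&S shell (≥ 2 mm), subarachnoid CSF, GM with
CSF-filled sinusoidal grooves (the sulci stand-in: radial grooves
around the vertical axis with per-head random count, phase and depth),
WM core and two ventricles.  Default outer semi-axes (32, 36, 30) mm —
a compact neonatal-scale head whose probe SDS range matches the
physics of interest; population spread defaults emulate a neonatal
cohort's relative head-circumference spread (σ ≈ 3.5%, scaled to
phantom size) plus independent jitter of shell/CSF/GM thicknesses and
sulci geometry.  Cranial points are built by fractional angular
subdivision of rings between the vertex and the landmark equator,
projected radially onto the scalp (for these star-shaped phantoms
angular fractions are arc-length fractions to good accuracy); the count
(249 + 5) and the by-index correspondence across heads follow the
convention of dense cranial grids.

The probe is a planar interleaved source/detector grid (default 4 + 4
at 12 mm pitch; a 16 + 16 high-density template ships for scaled-up
runs) pressed onto the head by radial projection toward the centre of a
sphere fitted to the covered surface, followed by gradient-free
coordinate relaxation on the surface that minimizes the squared
mismatch between on-head (fitted-sphere geodesic) and planar template
separations.  A flat probe cannot be isometrically embedded in a curved
scalp; the residual separation distortion is of order L²/(24R²) (~1.6%
for the default probe on an R = 50 mm sphere), which bounds what the
relaxation can achieve.  The sphere fitted to the final optode
positions provides the common launch target.

What the phantoms do *not* emulate: realistic cortical folding,
age-dependent maturation gradients, segmentation error, scalp-skull
separation, or anatomical asymmetry.  Passing the population tests
therefore demonstrates the *machinery* (registration, shared-exterior
construction, error propagation, detectability contrast) under
controlled variation, not the magnitude of anatomical error in real
neonates: the study's database-specific numbers (registration RMSEs,
eigenvalue counts, visibility ratios) are geometry-dependent and are
not reproduced by phantoms.

## Approximation-error statistics

For absolute measurements, e = y_ref − y_i over the N accepted
anatomies gives the sample mean μ_e and unbiased covariance Γ_e; the
eigensystem is computed through the SVD of the centred differences
(identical nonzero spectrum to the m×m covariance, clean rank N−1
handling).  STD_e = √tr(Γ_e).  Diagnostics: ‖P_v μ_e‖/STD_e (expected
shift vs spread, with P_v the projector onto the positive-eigenvalue
span), ‖P_v Δy_ref‖/STD_e (visibility of a perturbation), per-direction
projections |Δy_ref·v_i|, and the smallest eigenvalue count capturing
95% of the trace.  For difference (linearized) measurements the same
statistics are formed for e_Δx = (J_ref − J_i)Δx; since only J·Δx is
needed, the pipeline evaluates directional derivatives (one adjoint
pass per detector) instead of assembling full Jacobians.  ln A and φ
are treated as separate real vectors throughout.  All ratios are
invariant to a common rescaling of the measurements.

Study perturbations: tissue-wide absorption changes of the reference
(default ∓60% GM / +60% S&S; a ±20–90% sweep in 5% steps is available),
and a local ball of radius 5 mm with Δμₐ = 0.005 mm⁻¹ placed just
inside the GM under the probe centroid.  Cylinder depth-sensitivity
profiles (radius 2.5 mm, depth 20 mm, per-slice unit absorption
perturbation) are computed from Jacobian rows with population envelopes
as empirical SD and 2.5/97.5-percentile bands.

## Study driver

The default desk-scale study (N = 20 phantoms, 4+4 probe, DA solver at
2.5 mm mesh, CSF split on, f = 0.1 GHz) runs in a few minutes on one
CPU and is bit-reproducible from its config (serialized as YAML with a
content digest).  The deterministic solver was chosen for the driver so
that the population statistics carry no sampling noise; the MC path
(mBLL reweighting for tissue sweeps, directional replay derivatives for
the ball) is exercised by the same statistics code and validated
separately.  Problem sizes (photon counts 10⁶–4·10⁶, mesh spacings
2–2.5 mm, population 20) are the package's default desk-scale
conditions; all are configurable upward.

## Known limitations

* Voxel staircase boundaries for both solvers (the DA mesh is
  voxel-derived); smooth-surface meshing is out of scope.
* The MC detector accepts all exit angles within the patch (no
  numerical aperture), and internal refractive-index mismatches between
  tissues are not refracted (n is constant in the defaults).
* The DA treats CSF-2 as semidiffusive; radiosity/hybrid clear-layer
  models are out of scope.
* The 10-5-style cranial grid is a ring construction, not the full
  nomenclature-faithful 10-5 system; only counts, coverage and by-index
  correspondence matter for registration.
* Absolute MC and DA intensities differ by a model-dependent offset
  (source/detector models); comparisons are made on slopes and
  differences, as in FD practice.
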
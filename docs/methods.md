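# Methods

`dermafold` models the mechanics of head-scale patterning in tortoises: the
central dorsal head skin — a thin, stiff, keratinizing epidermis on a soft
dermis, both adhering to the rigid skull — grows faster than the bone it is
attached to, and the frustrated growth puts the skin under biaxial
compression until it buckles into a disordered network of folds ("unjoined
scale edges" and polygonal scale domains). The package contains the growth
simulator, the supporting measurement stages (volumetric segmentation of
layered stacks, Hertzian nanoindentation analysis), a fold-pattern
quantifier, and synthetic generators that supply every input with known
ground truth.

## The growth model

**Kinematics.** Deformation decomposes multiplicatively, `F = F_e G`. The
growth tensor is transversely isotropic about the layer's reference
mid-surface normal `n`:

    G = (1 + g_t)(I − n nᵀ) + (1 + g_n) n nᵀ,   det G = (1+g_t)²(1+g_n),

with tangential and normal growth fractions homogeneous within each layer
(the measured proliferation is roughly homogeneous *within* layers but
differs *between* them). Growth is relative to the bone, which is rigid and
non-growing: its mesh nodes are clamped and its elements carry no energy.
Normals are evaluated once on the undeformed geometry and held fixed
(total-Lagrangian growth).

**Constitutive law.** Compressible neo-Hookean energy density per unit
grown volume,

    W(F_e) = μ/2 (tr F_eᵀF_e − 3) − μ ln J_e + λ/2 (ln J_e)²,

with Lamé parameters from each layer's Young's modulus and Poisson's ratio.
Element energy is `W · V_ref · det G`; nodal forces are the exact analytic
gradient (verified against finite differences to <1e-6 relative error, and
against the uniaxial closed form μ(s − 1/s) at ν = 0). Moduli are relative:
every derived scale (time step, damping, contact stiffness, residual
tolerance) is proportional to the stiffest P-wave modulus, so multiplying
all moduli by a constant reproduces the trajectory step for step — only the
epidermis:dermis stiffness *ratio* matters.

**Quasi-statics.** Growth ramps linearly over 50 increments. After each
increment the state relaxes by damped semi-implicit Euler dynamics
(pseudo-density 1, lumped masses) until the constraint-projected residual
force maximum falls below `tol · E_scale` (default 2e-5) or the step budget
runs out. The time step is `0.5 · h_min √(ρ/(λ+2μ))` from the stiffest
element; drag is `0.02` of that element's frequency. The light damping is
deliberate: a buckling mode with negative stiffness −κ grows at rate
`≈ √κ` when underdamped but only `κ/c` when overdamped, and with heavy drag
the residual test declares convergence while the instability is still
infinitesimal. With ζ = 0.02 the flat-bilayer wrinkling oracle reproduces
the classical wavelength `λ = 2πh (Ē_f/3Ē_s)^{1/3}` within ~1%; with
ζ = 0.2 it produces no wrinkles at all.

**Self-contact.** Node-triangle penalty between the free skin surface and
itself: pairs within 0.5 epidermis thicknesses (candidates refreshed every
25 steps via a k-d tree, excluding reference-space neighbours closer than
2.5 units) feel a linear repulsion, distributed barycentrically to the
triangle so momentum is conserved and the force vanishes continuously at
the detection radius. No friction.

**Boundary conditions.** Bone nodes are clamped. Rim nodes of the excised
patch slide in their own cut plane (the cut-surface normal is projected
out); the outer surface is free.

**Failure handling.** An element inversion (`J_e ≤ 0`) or numerical blow-up
aborts the ramp and returns the partial trajectory with the failure
recorded in the diagnostics; an increment that merely exhausts its step
budget is recorded as unconverged and the ramp continues.

## The default study geometry

Lengths are nondimensional with 1 unit = initial epidermis thickness (the
fold wavelength is proportional to the folding layer's thickness, so this
is the natural scale). The default domain is a spherical-cap patch:
epidermis 1 unit over dermis 5 units over a clamped bone shell, outer
radius 150 units, patch half-width 10 units, meshed with Kuhn-subdivided
structured hexes (~17k tetrahedra at the default resolution).

The large radius-to-skin-thickness ratio (R/h = 25) is essential, not
cosmetic. On a strongly curved cap (R/h = 5) the growing skin can thicken
and inflate radially, gaining area like r² and relieving the tangential
compression to ~0.25 — *below* both the film-wrinkling threshold at
modulus contrast 2–3 (ε_c ≈ 0.28–0.36) and the surface-creasing threshold.
Such a cap stays smooth for every tabulated parameter set. A flat-ish dome
over a broad skull, like the real anatomy, offers no such escape and folds.

## Stochastic fluctuations

Patterns in real animals vary between individuals and between the two head
sides; the model attributes this to small spatial fluctuations of the
growth parameters. Two seeded noise sources are implemented:

* a multiplicative growth-field fluctuation, `g(x) → g(x)(1 + η(x))`, with
  η smooth (correlation length 2 units) and RMS 10%. This is the
  symmetry-breaking agent that nucleates folds — creasing below the linear
  instability threshold is subcritical and needs finite-amplitude seeds.
  Because the fluctuation multiplies the growth, zero growth is *exactly*
  unperturbed: an ungrown cap is pristine, which is the control condition
  for fold-emergence tests.
* a correlated geometric node jitter of RMS 1e-3 units (tie-breaking only;
  it leaves the surface curvature far below any crease threshold).

An earlier design used geometric jitter alone: at 1e-3 it never nucleates
the subcritical creases of the weakly-driven parameter sets, and at 0.05
the jittered stress-free reference surface itself reads as creased. The
growth-noise formulation avoids both failure modes.

## Fold quantification

Discrete mean curvature uses the cotangent Laplace–Beltrami operator with
barycentric vertex areas; the sign convention is convex-outward positive,
so creases (valleys seen from outside) are negative. Boundary vertices get
no curvature. Crease vertices are thresholded, thinned on the surface graph
to ~1-vertex-wide ridge lines (peeling the least-creased removable vertices
first), and extended one vertex through the patch boundary so a fold that
runs off the patch edge still separates domains. Components with an
endpoint (degree < 2) are *open* — the operational definition of an
"unjoined edge"; components whose vertices all have degree ≥ 2 are closed
loops. Domains are flood-filled over non-crease vertices; the dominant
wavelength is the radially averaged 2-D spectral peak of the detrended
height field (peak annulus refined by a power-weighted centroid).

Two threshold modes exist. The adaptive mode (10th curvature percentile,
but never above −0.01/unit) is for exploring a single surface; by
construction it marks a similar vertex fraction on any rough surface, so it
is *not* used for comparisons. Cross-species comparisons use the fixed
threshold −0.05/unit: well above the curvature of the smooth dome (1/150)
and of the jitter ripple, well below deep fold valleys.

The cross-species protocol simulates the three tabulated parameter sets on
the default cap with ≥3 seeds each and ranks species by median crease
length density (total crease length / surface area), with a bootstrap
stability estimate. Desk-scale caveat: per-seed densities of the two
weakly-folding species are dispersed, and with 3 seeds the median ordering
is reproducible but not deterministic across arbitrary seed sets.

## Segmentation stage

The phantom emulates a nuclear-stain volume: a bright epidermis band (dense
nuclei, intensity 0.8) over a dim dermis (0.25) in a spherical dome, with
Gaussian-blob labelled cells (radius 3 voxels, constant integrated
intensity, pairwise separation > 2 radii) and a bone-shell mask. It does
not emulate optical artefacts (attenuation, striping, deconvolution
residues) or clearing-induced shrinkage, so passing tests validate the
algorithmic chain, not robustness to real optics.

3-D Canny: Gaussian smoothing (σ = 1.5 voxels), gradient, non-maximum
suppression with trilinear sampling along the gradient, hysteresis on the
surviving ridge magnitudes with quantile thresholds 0.10/0.40. The
quantiles are deliberately low: the epidermis–dermis boundary is a weaker
edge (0.8→0.25) than the outer surface (0.8→0), and high quantiles starve
it of hysteresis seeds entirely. Edge components are classified by probing
the intensity a few voxels inside/outside along the normals: the two
components bounding the brightest interior are the skin surfaces, and of
those the one facing background is the outer surface.

Normals are the negated normalized smoothed gradient (outward from bright
tissue). Surface reconstruction evaluates a signed moving-least-squares
field (k = 10 nearest oriented points, Gaussian weights) on a coarse grid
and extracts the zero level set by marching cubes — any oriented-point
reconstruction satisfying the area/Hausdorff/compression contracts would
do; this one is dependency-free and deterministic. Thickness is the inward
ray-cast distance from the outer to the inner surface (in-package
Möller–Trumbore), with nearest-vertex fallback for misses.

Cell detection computes the Hessian of the scale-smoothed stack (σ = 1.5 ≈
cell radius/2); voxels where all three principal curvatures are negative
and the smallest-magnitude one exceeds 0.02 (calibrated on phantoms: blob
responses are ~0.04, layer-boundary plate responses <0.01) are merged into
components and reported at intensity-weighted centroids. Per-layer
proliferation densities come with a binned coefficient-of-variation
homogeneity statistic (CV → 1/√(mean count) for Poisson-homogeneous cells).

## Indentation stage

Hertz spherical contact, `F = (4/3) E_eff √R δ^{3/2}`, with the instrument
protocol as defaults: tip radius 99 μm, maximum depth 2 μm (safely inside
the small-contact regime δ ≪ R), 30 indentations per sample in a 3×10 grid
(3×3 for the smaller-headed species). `E_eff` is the instrument-style
effective modulus without a (1−ν²) correction; divide by (1−ν²) for a
sample modulus. The fit is linear in `E_eff` after the δ^{3/2} transform
(closed-form least squares); an optional contact-point offset is profiled
on a coarse grid. Curves with R² < 0.95 are discarded (threshold
inclusive), and retained moduli are summarised as mean ± SD per replicate.
Synthetic curves use multiplicative Gaussian noise, which preserves
F(0) = 0.

## Numerical choices and limitations

* Linear tetrahedra are stiff in bending; two element layers across the
  epidermis and ~1-unit in-plane spacing resolve wavelengths ≥5 units
  marginally. Wavelength errors of a few percent and slightly elevated
  effective buckling thresholds are expected at this resolution.
* Problem sizes (patch half-width 10, ~17k tets, 3 seeds per species;
  bilayer oracle at ~35k tets) are chosen so a full validation pass runs on
  a laptop-class single core; they are the package's desk-scale defaults,
  not physical claims.
* The relaxation is quasi-static only to the tolerance of the residual
  test; sub-tolerance creep can continue to deepen marginal folds.
* Degenerate inputs fail loudly: inverted reference tets, ν ≥ 0.5,
  non-unit growth normals, non-manifold surfaces, incoherent point-cloud
  orientations and unplaceable phantom cells all raise with context.
* No viscoelasticity or plastic flow; no time-dependent stiffening (the
  developmental stiffening appears only through static parameter sets); no
  reaction–diffusion or placode chemistry — the mechanics-only scope is the
  point of the model.
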
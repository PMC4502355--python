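# Methods

## Physical model

Head tissues at tDCS frequencies (DC) are purely resistive, so the
injected current distributes according to the quasi-static continuity
equation

    ∇·(σ ∇V) = 0,     E = −∇V,     J = σ E,

with isotropic per-tissue conductivity σ (S/m): skin 0.465, fat 0.025,
skull 0.01, CSF 1.65, gray matter 0.276, white matter 0.126, saline-soaked
sponge or conductive gel 1.4, electrode metal 5.99 × 10⁷. Air is
insulating; rather than carrying its nominal ~1e-15 S/m through the linear
algebra, air voxels are excluded from the domain, which imposes the
zero-flux (insulated) condition on every outer surface exactly and keeps
the system well conditioned.

Note on J = σE: some of the tDCS literature prints the relation as
"J = E/σ" while reporting numbers that satisfy J = σE (e.g. a 0.18 V/m
brainstem field at σ = 0.126 S/m quoted alongside 0.0227 A/m²). This
package implements the physically correct J = σE; the acceptance test for
that value checks the product, which reproduces the printed pair.

Boundary conditions: all conductor voxels of the anode(s) are held at one
Dirichlet value and all cathode conductors at 0 V. This reflects that the
electrodes are essentially perfect conductors (5.99e7 S/m — equipotential
metal), and it makes the current split among multiple anodes or cathodes
(the 4×1 ring, the 2×2 pairs) an *outcome* of the physics rather than a
prescription. After the solve, the current actually delivered through the
anode contact is integrated discretely and the potential is rescaled
linearly so the delivered total equals the requested current (1 mA by
default) — exact by linearity. The delivered and returned currents agree
to ≈1e-6 relative, far inside the 0.5% contract.

## Discretization

Structured-grid cell-centered finite volumes with the 7-point stencil: the
conductance of the face between neighboring voxels i, j is

    g_ij = harmonic_mean(σ_i, σ_j) · A / h = 2σ_iσ_j/(σ_i+σ_j) · h,

for cubic voxels of edge h (A = h²). Interior rows of the operator sum to
zero (discrete conservation); after eliminating the Dirichlet electrode
voxels the system is symmetric positive definite. It is solved with
conjugate gradients under a Jacobi preconditioner to a relative residual
of 1e-8 (deterministic; no randomness anywhere in the pipeline). The
default 2 mm phantom yields ≈4.1 × 10⁵ unknowns and converges in ≈700
iterations, a few seconds on one core.

E is recovered by central differences inside the conductive domain and
one-sided differences at its boundary (exact for linear potentials;
interior truncation error is second order, verified by a Richardson ratio
of 4 on cubic potentials).

The choice of a voxel finite-volume scheme over body-fitted tetrahedral
finite elements is deliberate: it consumes the labeled lattice directly
(no meshing step), is dependency-light and deterministic, and leaves the
physics — same equation, same σ, same boundary conditions — unchanged.
Its accuracy cost is quantified below.

## Head phantom

The synthetic head is a set of concentric spherical shells with default
outer radii (mm): white 58, gray 72, CSF 76, skull 83, fat 85, skin 92 —
conventional spherical-head values; the tissue list matches the standard
segmentation (including a fat layer). A voxel takes the label of the shell
containing its center. The lattice is sized so the world origin is a voxel
center (+z vertex, +y nasion, +x right preauricular), with a 12 mm air
margin for electrode assemblies. The voxel size must not exceed the
thinnest shell (2 mm for the default radii, hence 2 mm is the coarsest
default phantom; geometries without the fat shell are used when a 4 mm
lattice is needed, e.g. in grid-refinement studies).

An optional midsagittal CSF conduit — a vertical CSF-labeled cylinder from
the vertex toward the head center (default off, radius 2 mm) — emulates a
highly conductive intracerebral vessel that gives current under a vertex
electrode a preferential path toward medial structures.

Regions of interest are geometric stand-ins carved from the gray/white
shells: PFC and occipital cortex as 30° anterior/posterior gray caps; M1
as a 12° gray sector under the C3 direction with S1 in an 11° sector
rotated 24° posterior; left/right insula as 25° mid-depth gray patches
(r ≤ 66 mm); cingulate as a parasagittal gray slab (|x| ≤ 6 mm, z ≥ 10);
thalamus as a central 10×12×8 mm ellipsoid in white matter; brainstem as
an inferior axial cylinder (radius 8 mm, −70 ≤ z ≤ −25). ROIs are
assigned with a fixed precedence into a single label lattice, so they are
pairwise disjoint by construction. They are *positional* stand-ins only —
no gyral geometry, no anatomical boundaries.

## Electrode montages

Scalp positions use the proportional-arc construction of the 10-10 system
on the spherical head: the midline nasion–inion arc and the ear-to-ear arc
through Cz in 10% steps; the 10% ring (polar angle 72°) in 18° azimuthal
steps; interior rows (F, FC, CP, P) on the circle through their two ring
anchors and midline anchor, subdivided proportionally. This reproduces the
definitional angles exactly (Cz–C3 = 36°, Cz–T7 = 72°) and gives exact
left/right mirror symmetry. Directions are projected radially onto the
actual voxelized scalp.

Electrode assemblies are stamped as scalp-conforming shells: a sponge
(pads, 5 mm) or gel (disks, 2 mm) layer at 1.4 S/m topped by a 2 mm metal
conductor, with constant cross-section over height (a prism, not a
widening cone). Pads are 50 × 70 mm; "vertical" aligns the 70 mm axis with
the local meridian toward the vertex, "horizontal" with the local
parallel. At the vertex, where the meridian degenerates, the nasion
direction is the reference — so the Cz pad of the vertex–occipital montage
runs ear to ear, as that montage specifies. The 4×1 ring's cathodes are
derived from their named 10-10 positions (Cz, F3, T7, P3), which places
them 36° (≈58 mm arc) from the C3 anode, 90° apart in azimuth; the named
labels are treated as authoritative over any nominal ring radius.

## Analytic oracle

For an N-layer concentric sphere with point current electrodes (+I, −I)
on the outer surface, the potential in layer l is a Legendre series with
per-layer radial coefficients; continuity of V and of σ∂V/∂r propagates
(A, B) outward through a 2×2 transfer per interface and degree, the
innermost B vanishing by regularity and the outer flux condition
(2n+1)·I/(4πR²) per degree setting the scale. Source and sink n = 0 terms
cancel, so the series starts at n = 1 and has zero mean over the outer
surface (the gauge). Per-layer normalization of the radial powers by the
layer's own outer radius keeps all terms representable at degree 300–400.
The implementation is verified against the independent closed form for the
homogeneous sphere (agreement to ~1e-14 relative), interface-continuity
spot checks, truncation convergence (N = 200 vs 400 below 1e-6 on the
mid-gray shell; last-term tail below 1e-8 at the default N = 300), and
the antisymmetry/rotation/linearity identities.

`validate_solver` closes the loop: it voxelizes the same layers, stamps
two 8 mm disk electrodes, solves at 1 mA, and compares |E| on a mid-gray
sample shell (≥2000 quasi-uniform points, excluding 20° caps under each
electrode where point and disk electrodes legitimately differ).

## Solver accuracy: what the validation shows

On a homogeneous sphere the pipeline is accurate to the discretization
floor: median |E| error 0.9% at 2 mm (p90 1.6%). On the layered head
(white/gray/CSF/skull/skin) the voxel solver systematically
*overestimates* the interior field: median |E| error ≈17% at 2 mm, ≈8% at
1 mm — first-order convergence, dominated by the staircase representation
of the thin high-contrast shells (skull at 0.01 S/m and CSF at 1.65 S/m
contribute ≈8% and ≈4% in isolation at 2 mm).

This bias is a property of the voxelized *geometry*, not of the stencil:
re-solving the identical 2 mm label lattice on a 2× subdivided grid leaves
it essentially unchanged, and neither exact per-face analytic conductance
integration nor a vertex-based trilinear FEM on the same labels removes it
(the latter roughly halves it). Any label-lattice pipeline at this
resolution carries an error of this order for thin resistive shells; only
body-fitted meshes built from smooth segmented surfaces avoid it.
Users comparing montages should note that the bias is common-mode — it is
nearly uniform across the brain and across montages — so montage
*rankings*, focality orderings and ratios are far more reliable than
absolute field magnitudes.

## What the phantom does and does not show

The generator emulates the conductivity *structure* of a segmented head —
layer ordering, thicknesses, the CSF shunt, skull resistance — but not
cortical folding, tissue anisotropy, vasculature (beyond the optional
conduit), or inter-individual variability. Passing tests therefore
establish that the pipeline solves the stated physics correctly on
sphere-like geometry and reproduces the *relative* montage phenomenology
(HD focality, deep-structure sparing, sub-1 V/m magnitudes at 1 mA); they
do not certify absolute field predictions for any real head. Absolute
peaks computed on an individual's folded cortex cannot be reproduced on a
phantom and serve as order-of-magnitude context only.

## Numerical choices and defaults

- Voxel size: 1 mm native default for the phantom; 2 mm for solves in the
  tests, the montage comparison and the acceptance script (problem size
  ≈4.1 × 10⁵ unknowns per solve, ≈105³ lattice).
- CG relative residual 1e-8, iteration cap 500·N^(1/3); Jacobi
  preconditioner; everything deterministic, so repeated runs are
  byte-identical.
- Robust peak percentile 99.9 for masks of ≥10⁴ voxels, plain maximum for
  smaller masks (order statistics are noisy there); both robust and
  absolute peaks are always reported, since voxel lattices produce
  discretization spikes at electrode edges that mesh-smoothed values
  would not show.
- Focality fraction 0.5 (volume at half the robust peak) — a standard
  half-maximum convention; the depth profile uses 5 mm bins of
  distance-to-air computed by Euclidean distance transform.
- Deep/superficial ratio: max robust peak over insula∪cingulate∪thalamus∪
  brainstem divided by max over PFC∪M1∪S1∪occipital.
- Montage current 1 mA; every reported magnitude is exactly linear in the
  injected current (tested to machine precision).
- Legendre truncation N = 300 (tail < 1e-8); oracle E by central
  differences with a 0.1 mm step.
- The phantom's `random_seed` is provenance only: the default generator is
  fully deterministic and applies no stochastic perturbation.

## Known limitations

- Absolute interior fields on layered phantoms carry the staircase bias
  quantified above (≈ +17% at 2 mm, +8% at 1 mm).
- Spherical geometry only; ROIs are angular stand-ins, not anatomy.
- Isotropic conductivities; no frequency dependence; no electrode–skin
  interface impedance.
- The point-electrode oracle cannot validate the near field under the
  electrodes (hence the 20° exclusion caps).
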
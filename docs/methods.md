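# Methods

`cz3geom` quantifies the stochastic geometry of a compartmentalized
extracellular-matrix (ECM) surface mesh — the wall-like CZ3 compartment
boundaries that each somatic cell of a *Volvox*-type spheroid builds around
itself — from planar "top view" outlines, and provides a seeded synthetic
generator of such configurations so that every analysis step can be
validated against ground truth without microscopy data.

## Per-compartment metrics

All per-compartment quantities derive from exact polygon integrals
(per-edge shoelace accumulation; nothing is rasterized):

* area *a* (μm²), centroid, perimeter ℓ (μm);
* the central second-moment matrix **M₂** = ∫ (x − x̄)(x − x̄)ᵀ dA (μm⁴) and
  its normalization **Σ** = **M₂**/a (μm²), interpretable as a strain tensor
  relative to an isotropic shape. The square roots of its eigenvalues
  λ_max ≥ λ_min are the principal axis lengths.

From these:

* **aspect ratio** α = λ_max/λ_min (default; the axis-length ratio
  √(λ_max/λ_min) is available via `sqrt_aspect=True` and the convention is
  echoed in all outputs). Note α is the *eigenvalue* ratio: α ≈ 1.2 means a
  nearly round compartment (axis ratio ≈ 1.1).
* **circularity** q = 4πa/ℓ², the isoperimetric quotient (1 for a circle;
  π√3/6 ≈ 0.907 for a regular hexagon, exported as `QHEX`). We use the
  squared-perimeter form because it is the unitless quantity that equals 1
  for a circle, which is how circularity is used throughout.
* **cell offset** Δx = x_cell − x_cz3, r = |Δx|, and the **whitened
  offset** r_w = Δx·Σ⁻¹Δx (unitless quadratic form; √ variant behind
  `sqrt_whiten=True`). Whitening measures the offset in shape-adapted
  coordinates, so a pure local dilation leaves it invariant.
* **offset angle** θ ∈ [0, π/2], the acute angle between Δx and the
  principal stretch axis; undefined (flagged) when Δx = 0 or when
  λ_max − λ_min < 10⁻⁶ λ_max (isotropy tolerance — no tie-breaking).
* **Voronoi error** e_V = 1 − area(P ∩ V)/area(P ∪ V) against the Voronoi
  cell V of the compartment's own cell. We report an *error* (0 = perfect
  Voronoi agreement, growing to 1) rather than the raw IoU so that the
  metric increases as compartments depart from Voronoi geometry.

Similarity invariance (α, q, r_w, θ unchanged; a ∝ c², r ∝ c under
rotation + scaling by c) holds to machine precision and is asserted in the
tests, as is the local dilation law: scaling a compartment and its cell
offset about the centroid by √ρ multiplies a by ρ and r by √ρ while leaving
α and r_w unchanged.

## Spheroid-level analysis

* **Outline**: direct least-squares ellipse fit (Halir–Flusser, via
  scikit-image) to boundary points; circular radius R = √(ab) and spheroid
  aspect a/b.
* **PA axis**: normal to the total-least-squares line through offspring
  centroids, anterior sign pointing away from their centre of mass
  (offspring sit posteriorly); falls back to the elliptical major axis,
  which approximates the PA axis well. PA coordinate u ∈ [0,1]
  (0 = posterior) by projection normalized by the outline extent; profiles
  use 8 equal bins of u (per-bin mean, SD, count).
* **Voronoi reference**: planar (top-view, not geodesic) Voronoi
  tessellation of the somatic cell centroids clipped to a window polygon;
  the cells tile the window to 10⁻⁶ relative area. Two generators are
  handled by the perpendicular bisector.
* **Covering fraction** φ = area(∪ compartments)/area(window), computed
  with exact polygon unions. The window is an explicit argument (outline
  ellipse by default in summaries).
* **Partition cost** n·Σᵢ Tr(M₂⁽ⁱ⁾)/(Σᵢ a⁽ⁱ⁾)², the standardized sum of
  second moments. With the squared *sum* of areas in the denominator the
  cost is scale- and n-invariant, equals 1/6 on any square tiling,
  5√3/54 ≈ 0.1604 on equal regular hexagons (its minimum over tilings),
  is bounded below by 1/(2π) (a disc), and strictly increases with area
  polydispersity at fixed shape (Cauchy–Schwarz). The non-invariant
  Σ(a²) variant is available for sensitivity analysis
  (`denominator="sq_sum"`).
* **Boundary handling**: compartments touching the analysis window are
  flagged and excluded from distributional statistics (clipping biases
  shape metrics) but kept in covering fractions; every filter count is
  logged.
* **Distortion correction** is a strategy interface. The provided
  orthographic-sphere model treats the top view as an orthographic
  projection of a sphere of radius R: a compartment anchored at planar
  radius ρ is corrected in its locally isometric tangent frame by
  stretching radial components by 1/cosθ, cosθ = √(1 − (ρ/R)²), and moving
  the anchor to its arc-length radius R·arcsin(ρ/R). Features are then
  *recomputed* from the corrected polygons, never rescaled post hoc.
  Vertices at ρ ≥ R cannot be deprojected; such compartments are excluded
  with a warning. This is a physically minimal model chosen by this
  package; alternative mount-deformation models can be plugged in.

## Gamma ("k-gamma") fits

Compartment areas and aspect ratios are fitted with the gamma family
p(x; k, λ) = λᵏxᵏ⁻¹e^(−λx)/Γ(k) after standardization: areas are
mean-scaled (x/⟨x⟩); aspect ratios are shifted by their lower bound
(α − 1, since the support must be (0, ∞)) and then mean-scaled. Both
choices are recorded in the fit output and configurable. The estimator is
maximum likelihood: Newton iteration on the digamma score equation
log k − ψ(k) = log⟨x⟩ − ⟨log x⟩, started from the moment-matched
k₀ = mean²/var, tolerance 10⁻¹⁰, deterministic; the moment estimate is
retained in the output for comparison. At fixed mean, k is an order
parameter: large k ⇒ narrow, nearly Gaussian (crystalline) distributions;
small k ⇒ broad, disordered ones. Hemisphere fits split the sample at
u = 0.5 and require ≥ 10 compartments per side.

## Synthetic generator

The generator is phenomenological, not mechanical — no force-based foam
relaxation is simulated; it reproduces the *statistical* structure the
analysis assumes:

1. **Cell centers**: jittered triangular lattice in a disc window
   (jitter SD = `lattice_sigma` × spacing; the lattice is laid ~10% denser
   than needed and the outermost excess is shed, so exactly `n_cells`
   remain). An anterior-ward area gradient is imposed by an exponential
   *conformal* map of the lattice (locally a pure similarity), so local
   density falls by the factor (1 + `pa_gradient`) from posterior to
   anterior rim without making cells anisotropic. An optional `target_k`
   dial replaces a fraction of lattice points with uniform points
   (pure Poisson-Voronoi areas have k ≈ 3.6), monotonically lowering the
   fitted area-k; the mapping is approximate by construction.
2. **Compartments**: the Voronoi partition of the window; rim-touching
   cells are tagged boundary.
3. **Acircular relaxation**: each polygon is morphed vertex-wise along rays
   from its centroid toward its moment-matched ellipse of area
   `shrink`² · a (γ = `relaxation` interpolates; boundaries are densified
   first so γ = 1 yields a smooth ellipse). This preserves α by
   construction (< 3% batch drift), raises q, and opens extracompartmental
   space, dropping φ toward `shrink`² at γ = 1 — emulating the observed
   polygonal → elliptical packing transition at fixed aspect ratio.
4. **Cells**: placed at the compartment centroid plus an offset of
   magnitude `offset_coeff`·√a·|N(0,1)| in a uniform direction,
   rejection-resampled to stay inside the compartment (flagged at the
   centroid after 100 failures). This reproduces the r ∝ √a power law and
   an approximately constant whitened offset simultaneously, with the
   offset angle uniform on [0, π/2].
5. **Rendering**: 16-bit label masks at a chosen pixel size; walls are
   drawn centred on compartment boundaries (half of `wall_thickness`,
   default 1.6 μm, to each side), as physical walls of finite width.

Stage presets I–IV and S bundle parameters so the pipeline readouts follow
the observed trends: window radii follow stage-mean spheroid radii
(106–422 μm), somatic cell radii 2.8–4.2 μm, PA area gradient growing from
44% to 130%, jitter/relaxation/shrink increasing with stage so that φ falls
from ≈1.0 (I–II) to ≈0.81 (IV), mean α stays near 1.2 at every stage, and
the fitted area-k decreases monotonically. These presets were calibrated
once against those stated targets and then frozen. Because α ≈ 1.2 (as an
eigenvalue ratio) forces small jitter, the synthetic area distributions are
much more ordered (k ≈ 20–100) than confocal data (k ≈ 2–3): the presets
validate the generator→pipeline loop and direction-of-effect trends, not
absolute biological disorder. Other features of real data the generator
does not emulate: gonidial defects, double-wall merging/splitting noise,
segmentation artefacts, curvature of the spheroid surface (a planar disc
stands in for the viewed cap), and imaging noise. Passing tests therefore
demonstrate correctness of the measurement pipeline, not fidelity of any
biological inference.

## Mask ingestion

Label pixel (i, j) covers [j, j+1) × [i, i+1) in pixel units; ingestion
maps pixel centers to the analysis frame (x right, y up, μm) by
x = x₀ + (j + 0.5)·px, y = y₀ + (H − i − 0.5)·px — area-preserving, with
the origin taken from mask metadata. Outlines are the 0.5 iso-contour of a
lightly Gaussian-smoothed (σ = 1 px) per-label indicator, simplified at
0.25 px: the smoothing is symmetric about the boundary, so straight edges
stay put to first order (100×100 px square: 0.08% area error) while the
marching-squares staircase — which otherwise inflates perimeters (a
rasterized disc of radius 50 px would read q ≈ 0.91 instead of > 0.99) —
is removed. Interior holes are discarded with a warning; border-touching
labels are flagged clipped. `segment_walls` is a deliberately simple
baseline (threshold → closing → labelled non-wall components, border
components excluded, min-area filter) intended for rendered or
well-contrasted wall images, not a replacement for interactive
segmentation. Because walls have finite thickness t, the segmented
interiors sit ~t/2 inside the wall mid-line; `segment_walls` can reclaim
the wall region by nearest-label expansion capped at t/2
(`reclaim_half_wall`, +0.75 px for the centre-to-centre metric of the
distance transform). Label competition splits merged double walls at their
mid-line, and — unlike a plain outward buffer of the interior outline —
the expansion also recovers the wedges that the third wall cuts out of
compartment corners at wall triple junctions. For compartment masks
segmented elsewhere, a mitre-joined outward buffer is available instead
(`PipelineConfig.wall_compensation`, in μm). Without either, areas are
biased low by roughly one wall thickness per compartment diameter.

## ECM volume bookkeeping

Parental ECM volume per stage is estimated as the spheroid volume minus
the estimated volume of offspring and somatic cells, all treated as
spheres: V = (4/3)π(R³ − n_o·r_o³ − n_c·r_c³), reported in mm³. With the
stage-mean radii (R = 106/221/244 μm, r_o = 16/29/30 μm,
r_c = 2.8/3.9/4.0 μm for stages I/II/III) and n_o = 16, n_c = 2000, the
stage I→II change is 0.039 mm³ (0.0026 mm³/h over 15 h) and II→III is
0.015 mm³. Negative results raise an error (inconsistent inputs).

## Problem sizes and numerical choices

Default test and acceptance runs use 600-cell spheroids rendered at
0.25 μm/px (chosen so the thinnest walls span ≥ 2 px and compartment
diameters span ≳ 30 px), 100 random polygons against a 4096²-pixel moment
oracle, and n = 1000 samples × 30 replicates for gamma-shape recovery.
Gamma fits require n ≥ 10 positive values and nonzero variance; degenerate
samples and non-convergence raise typed errors. Seeds are explicit
everywhere; identical configuration + seed gives bitwise-identical
polygons and outputs.

## Known limitations

* All analysis is planar; geodesic/3D moments, spherical Voronoi and
  cross-sectional shape are out of scope.
* The distortion model is a stand-in; mount-specific elastic deformation
  is not modelled.
* `target_k` is an approximate, monotone dial — k values between ~3.6 and
  the lattice regime are reachable only coarsely, and k < 3.6 not at all.
* `segment_walls` assumes bright walls on a dark background and one cell
  per compartment; gonidial compartments surface as ambiguous pairings and
  are excluded with flags rather than modelled.
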
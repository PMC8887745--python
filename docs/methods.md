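# Methods

## Flow model

The chamber is 3.8 mm wide, 17 mm long and 0.4 mm high, driven at
0.2 μl/min. With a Reynolds number far below one and height ≪ width, the
depth-averaged in-plane velocity is a potential (Hele-Shaw) flow; around a
rigid circular obstacle it has the classical closed form "uniform stream +
doublet", written here as a complex velocity f(z) = iU(1 + a²/z²) with the
stream along −y and mean speed U = Q/(w·h) ≈ 2.19 μm/s. The analytic form
gives exact incompressibility, the exact 2U tangential speed at the
obstacle's sides, and an exact velocity gradient for the rod kinematics;
the test suite cross-checks it against an independent finite-difference
solve of the Laplace equation for the streamfunction (relative L2 < 2%
away from the discretized obstacle boundary).

Assumptions: the spheroid is a rigid, impermeable disk spanning the
channel depth; side-wall no-slip is neglected (obstacle diameter ≈ 0.2 mm
versus 3.8 mm width — image corrections would enter at the (a/w)² ≈ 0.3%
level, which is also the size of the mass-flux closure error the tests
tolerate); the imaged plane is identified with the depth-averaged plane.

Coordinates: origin at the obstacle center, flow from top to bottom
(−y), axial orientation angles in [0°, 180°) with 90° the flow axis.

## Rod advection and the orientation field

Collagen fibers are rigid slender rods (47.5 μm × 5 μm). In the
infinite-aspect-ratio (Jeffery) limit the orientation vector obeys
ṗ = Lp − (pᵀLp)p: vorticity rotates the rod rigidly, strain aligns it
with the extensional axis. Rods released flow-aligned upstream therefore
tip perpendicular to the flow at the upstream stagnation region, sweep
tangentially around the spheroid and leave the wake flow-aligned — i.e.
radial with respect to the spheroid on the downstream side.

`synthesize_orientation_field` integrates a cohort of rods (midpoint
scheme, default dt = 1.5 s) released one per 10-μm lane on a line above
the grid, with a ±10° uniform axial jitter representing the imperfect
far-field alignment. Release lanes are symmetric about the obstacle axis
and include the stagnation streamline itself: fibers arriving on it pile
up at the upstream face, and their diverging residence time is what makes
the face box read perpendicular-to-flow. Each rod deposits its axial
angle at 5 points along its length at every time step for up to 2700 s
(the polymerization window during which flow is applied), so box averages
are residence-time weighted — a steady rain of polymerizing fibers is
equally likely to freeze at any moment, making residence time the natural
sampling measure. Box statistics use doubled-angle vector averaging;
coherence is the resultant length (the rear-surface box, where
arriving-tangential and departing-radial material mix, is honestly
low-coherence).

Resolution caveat: integrated rod strain tips orientations only where the
cumulative strain is large, so the perpendicular/tangential material
occupies a shell a few tens of μm thick against the 103-μm boxes. The
advected box field therefore shows the correct pattern at the
surface-adjacent boxes but carries a much weaker migration barrier than
the measured gels, whose aligned zones are thicker (fiber length, network
connectivity and fiber–fiber interactions are outside this model).
`flow_pattern_field` states the same pattern as a geometric idealization
at exactly the grid's resolution element: a tangential annulus one box
(103 μm) wide around the spheroid — perpendicular-to-flow at the upstream
pole by construction — a radial lobe in the downstream 45° sector (the
sector convention of the front analysis), and flow-aligned background.
This zoned field is what the invasion-calibration runs use.

`OrientationGrid` is total over the plane (nearest box outside the field
of view, nearest sampled box for empty boxes, flagged), so cells inside
the spheroid always see a defined α. The canonical test fields (uniform,
radial, tangential, isotropic) carry exact analytic evaluators so that,
e.g., motion on the radial field is exactly radial at the cell's own
position rather than at the box center.

## Invasion model

Cells are points on an unbounded plane; no proliferation, no volume
exclusion, no cell–cell interaction. Each of N = 100 daily steps draws
one of four equiprobable moves: ±k_p along the local fiber axis or ±k_v
perpendicular to it. Step sizes follow the diffusive calibration
k = r/√N from the day-one front distances r_p (default 220 μm/day,
downstream) and r_v (default 0, upstream); under this scaling day-level
statistics are independent of N (tested over N ∈ {25, 100, 400}) and
fronts grow with √t. A perpendicular move with k_v = 0 is a null move
that consumes its time step; the alternative (`redraw_null_moves`)
doubles the effective parallel diffusivity and is off by default. A
`linear` step scaling (k = r/N) is kept as a switch for comparison; it
contradicts the observed √t front growth. Cells are seeded uniformly on
the spheroid circle (radius default 150 μm, the model's stated initial
condition); a filled-disk mode exists for sensitivity analysis. Fiber
orientation is looked up nearest-box (bilinear axial interpolation was
evaluated and changes day-1 fronts by ~20% downward upstream; the boxed
lookup is the documented contract).

## Front quantification

The invasion front in a 45° sector is the mean of the m = 10 largest
values of max(r − R₀, 0) among cells currently in the sector (ties broken
by cell index). The asymmetry index is the downstream/upstream front
ratio at day 1, the calibration day. The perpendicular-step sweep runs
r_v ∈ {0, 60, 120, 220} μm/day with 10 replicate seeds and reports
replicate-averaged tables; `shape_mismatch` (RMS sector difference,
averaged over days) operationalizes "best match in shape". The
time-scaling exponent is the log–log slope of front versus day.

**Cohort-size dependence.** The top-10 front is an extreme order
statistic: its expectation grows with the number of cells feeding the
sector. With 1000 boundary-seeded cells and the day-scale parallel spread
r_p/√2 ≈ 156 μm, the computed day-1 downstream front is ≈ 330 μm and the
upstream front ≈ 105 μm (10 replicates); smaller cohorts give smaller
fronts for the same r_p. Absolute front values should therefore only be
compared between runs with matched cohort sizes; ratios (asymmetry,
day-3/day-1) are much less sensitive.

## Image analysis

Preprocessing: Gaussian blur (σ = 2 px), rolling-ball background
subtraction (radius 25 px; invariant to additive offsets), Otsu
threshold. The exact filter scales for orientation analysis are artifact
choices exposed in `PreprocessParams`. Orientation: 3×3 Sobel gradients;
local fiber orientation = gradient direction + 90°, weighted by squared
gradient magnitude over the foreground; 180 one-degree bins. The aligned
window is realized as the 46 integer bins 68..113 so the uniform baseline
is exactly 46/180 = 25.56% (the closed interval 68°–112° would span 45
bins = 25.0%; the printed 25.56% is taken as normative). The uniform
reference histogram uses equal integer weights so the baseline and a
degree of alignment of 1.0 are floating-point exact.

## Synthetic data

Fiber images are anti-aliased line segments whose axial angle is the
local field angle plus von Mises jitter on the doubled angle (κ = 8 by
default, ≈ 10° spread; κ → 0 gives isotropy), blurred with a Gaussian PSF
(σ = 1 px) and corrupted with Gaussian or Poisson noise. Pixel size
defaults to 1 μm/px for arithmetic transparency (the real microscope
scale is not modeled). Ground truth is returned with every image, and all
generators are bit-reproducible from (spec, seed). The generator captures
the statistical structure the analysis relies on — local axial
orientation with controllable dispersion — not confocal optics,
photobleaching or 3D sectioning; passing round trips show the estimators
recover known orientation structure, not that they are unbiased on real
microscopy. One known estimator effect: squared-gradient weighting
slightly over-weights axis-aligned crisp lines (a +0.1-level degree-of-
alignment bias on isotropic images at PSF σ = 1), shrinking with stronger
blur.

## Numerical choices

Rod and tracer integration: explicit midpoint (2nd order); streamlines:
classical RK4. Overshoot into the obstacle is clipped radially back onto
the surface (rods then slide along it, which is also the mechanism that
accumulates tangential fibers at the interface). Axial means use angle
doubling throughout; the 0°/180° seam is handled by construction.
Simulation sizes in tests and in the acceptance script (10 replicates ×
1000 cells × 100 steps/day) keep every check well under a minute while
holding replicate standard errors on day-1 fronts at the few-μm level.

## Known limitations

- The flow model is 2D depth-averaged; the real aggregate (208 μm) does
  not span the 400-μm channel height, so flow also passes above it.
- Fiber–fiber interactions, network elasticity and matrix remodeling are
  absent; hence the thin aligned shell discussed above.
- The random walk ignores volume exclusion and collective effects, which
  the front statistic is known to be sensitive to through crowding.
- Front distances depend on cohort size via the order statistic; see
  above.
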
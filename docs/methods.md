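# Methods

`densewall` measures circumferential stretch of the ascending aortic wall
from displacement-encoded (DENSE) MR phase images and quantifies its
asymmetry around the vessel circumference. This note documents the model,
the numerical choices, and what the synthetic phantom does and does not
establish about real data.

## Measurement model

DENSE stores tissue displacement in the signal phase. With encoding
frequency `k_e` (cycles/mm) and encoding direction `e`, a voxel whose
tissue moved by `u` between the encoding pre-pulse and the readout carries
phase

    phi = 2 * pi * k_e * (u . e)    (known only modulo 2*pi).

The acquisition is timed so that position is encoded at maximal aortic
expansion (systole, identified on a cine series as the maximum lumen area)
and read out in diastole. The measured `u` therefore carries tissue from
the expanded state to the resting state, and the expanded position of a
diastolic point `p` is `p - u(p)`. Blood that was encoded leaves the slice
before readout, so the lumen contributes almost no signal (black-blood
effect) and the wall dominates the phase even at coarse resolution.

Four acquisitions with balanced encoding directions (a regular tetrahedron
on the unit sphere by default; arbitrary direction sets are accepted)
sense 3-D displacement. One acquisition acts as the reference; net phases
`phi_i - phi_ref` with net directions `e_i - e_ref` give the per-pixel
linear system `(2 pi k_e) D u = phi_net`, solved by least squares. A
direction set whose net rows do not span 3-D is rejected (the unsensed
direction is reported); a minimum-norm solution in the sensed subspace is
available for deliberately planar setups.

## Processing chain

1. **Delineation.** Operator-supplied control points for the inner, outer
   and mid-wall contours are interpolated by periodic cubic splines,
   reparameterized by arc length (uniform speed to ~1e-6 relative; the
   underlying parametric function is kept exactly, only the
   reparameterization is tabulated). Wall pixels are those between inner
   and outer contours whose magnitude is at least `exclusion_fraction`
   (default 0.3) times the median magnitude between the contours; this
   removes partial-volume pixels whose phase is unreliable. The threshold
   is a package default — no published value exists — chosen to strip the
   phantom's partial-volume rim without eroding the one-to-two-pixel-wide
   wall. The mid-wall curve may be supplied explicitly or derived as the
   angular midpoint of inner and outer.

2. **Phase conditioning.** Each wrapped phase image is smoothed by
   normalized convolution on the unit-complex representation,
   `arg(G_sigma * (c e^{i phi}) / (G_sigma * c))`, with certainty
   `c = magnitude^p` (default `p = 1`) zeroed outside the wall mask and a
   Gaussian applicability of `sigma = 1` pixel. Smoothing the complex
   representation respects wraps; weighting by magnitude reflects that
   phase noise scales inversely with signal magnitude. Pixels where the
   denominator falls below 1e-3 of its maximum are flagged invalid rather
   than divided by near-zero.

3. **Unwrapping.** Net phases are unwrapped by weighted least squares:
   wrapped first differences (weight = the smaller certainty of the two
   pixels, zero across the mask boundary) feed the weighted Poisson normal
   equations with Neumann boundary conditions, solved by conjugate
   gradients preconditioned with the unweighted cosine-transform Poisson
   solver. With uniform weights the preconditioner is the exact solver and
   the first iteration terminates. The continuous solution is centred on
   its certainty-weighted median offset and then snapped to congruence:
   every output pixel equals the wrapped input plus the nearest integer
   multiple of 2*pi, so unwrapping only ever chooses branch integers and
   never perturbs the measured phase. Each net-encoding phase image is
   unwrapped separately.

4. **Tracking.** 100 points are seeded at equal arc length on the
   diastolic mid-wall curve, the first at the anterior-axis crossing.
   Displacement at each sub-pixel location is sampled by a
   certainty-weighted local linear fit (moving least squares, Gaussian
   window of 1 px over a 5x5 footprint of valid pixels). The local linear
   model reproduces affine fields exactly, which makes rigid bulk motion —
   large in the ascending aorta — bias-free; a renormalized convolution
   kernel does not have this property on a wall only one to two pixels
   wide, where the footprint always straddles the mask edge.

5. **Stretch.** The systolic point cloud is regularized with a 5-piece
   periodic least-squares cubic B-spline (uniform knots in the point-index
   parameter, each coordinate fitted independently). The diastolic points
   are smoothed with the *same* basis, and the per-segment stretch is the
   ratio of 3-D systolic to in-plane diastolic chord lengths between
   corresponding spline-projected points. Matching the bases is essential:
   a 5-knot cubic basis carries ~0.5% radial ripple on a circle of aortic
   size, which cancels between numerator and denominator when both states
   are filtered identically (the identity deformation then returns stretch
   1.0 to machine precision) but would appear as a spurious ±0.5%
   per-segment signal if only the systolic state were smoothed. Systolic
   distances include the through-plane coordinate; the resting curve is
   defined in the imaging plane. Chords between projected points are used
   (an arc-length variant of the same quantity differs at second order in
   the segment length).

6. **Quadrants.** Segments are assigned to 90-degree sectors centred on
   the anatomical axes of a supine axial slice (anterior = image -y,
   patient right = image -x); a segment exactly on a 45-degree boundary
   goes to the next sector in A->R->P->L order. Reported statistics are
   the overall mean stretch, per-quadrant means, and the relative stretch
   difference `(S_quadrant - S_overall)/S_overall`, whose four values sum
   to zero for equal segment counts.

7. **Statistics.** Cross-sectional area change from a cine contour series
   is `(A_max - A_min)/A_min` (shoelace areas). Cohorts are compared by a
   two-way fixed-effects ANOVA with interaction on per-subject,
   per-quadrant mean stretch (factors: group, quadrant; statsmodels OLS +
   type-II table) with Tukey HSD ranges within each factor, and stretch is
   correlated with area change by Pearson's r. Whether the original
   analysis included the interaction term is not documented; the
   fixed-factor model with interaction is implemented and the per-subject
   quadrant means are treated as independent observations (no repeated-
   measures nesting).

## The phantom

No patient DENSE data is deposited, so validation uses a synthetic annulus
with analytic ground truth. The resting wall is a circular annulus
(mid-wall radius 15 mm, thickness 2.5 mm — aortic walls are of the order
of 2-3 mm) on a 64x64 grid of 2.3 mm pixels with k_e = 0.08 cycles/mm and
8 mm slice thickness, matching published acquisition geometry. The forward
map scales the mid-wall radius by `s(theta) = s0 + sum a_k cos(k theta +
phi_k)` while preserving wall thickness (pure circumferential stretch),
composed with a rigid in-plane rotation, an in-plane translation and a
constant through-plane shift — the expand-and-rotate phenomenology
reported for eccentric flow. The true stretch profile follows in closed
form (`sqrt(s^2 + s'^2)` on the mid-wall; computed by step-halved
numerical differentiation of the deformed curve and cross-checked against
a dense polygonal arc-length oracle).

Rendering uses the analytically exact disk/pixel overlap area, so edge
pixels carry realistic partial-volume magnitude; the lumen magnitude is
5% of the wall's (black blood) and the background zero. Noise is complex
Gaussian added per acquisition to the real and imaginary channels before
magnitude/phase extraction (`snr` = wall magnitude over per-channel noise
standard deviation), reproducing magnitude-dependent phase noise. The
cine series interpolates the lumen contour between rest and full
deformation with a half-cycle raised-cosine weight, the lumen scaled by
`s(theta)` so lumen area tracks the squared stretch exactly.

What the phantom does **not** emulate: stimulated-echo T1 decay of the
wall signal (magnitude is static; no published signal model to copy),
phase-cycling artifacts, respiratory or bulk patient motion,
through-plane curvature of the vessel, partial-volume *phase* mixing
(edge pixels carry the analytic wall phase at reduced magnitude), and
surrounding-tissue signal. Passing recovery tests therefore demonstrates
correctness of the numerical chain under the stated acquisition geometry
and noise model, not robustness to scanner artifacts.

## Defaults and parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k_e` | 0.08 cycles/mm | encoding frequency (published range 0.08-0.11) |
| `sigma_px` | 1 px | Gaussian applicability of normalized averaging |
| `exclusion_fraction` | 0.3 | low-magnitude wall-pixel exclusion threshold |
| `certainty_exponent` | 1 | certainty = magnitude^p |
| `n_points` | 100 | seeded mid-wall points |
| `pieces` | 5 | periodic spline pieces for point regularization |
| phantom `snr` | inf | noise off unless requested; studies use 15-25 |

Problem sizes in the test suite and acceptance script (64x64 grids, 100
points, 20 noisy replicates, 200 ANOVA repetitions, 12-phantom cohorts)
are the package's standard study conditions; each end-to-end phantom run
takes ~0.1 s.

## Numerical notes and limitations

- Noise-free accuracy is limited by the sigma = 1 px complex smoothing of
  a curved phase field: a uniform 6% expansion is recovered as 5.88%
  (bias ~ sigma^2/2 * laplacian(u), ~5 um here). Rigid motion is exact to
  0.03% because all stages are exact on affine fields.
- Least-squares unwrapping assumes the smoothed phase has alias-free
  gradients within the mask (< pi per pixel step); displacements up to
  ~6 mm at k_e = 0.08 satisfy this on the default geometry.
- `quadrant_of` uses a deterministic boundary tie-break; profiles are
  reproducible bit-for-bit for a given seed, and the pipeline manifest
  records the configuration hash, seed and per-file checksums.
- The angular-midpoint mid-wall construction assumes the wall is
  star-shaped about its centroid — true for aortic cross-sections, not
  for arbitrary vessels.
- Single time-pair only: no multi-phase cine DENSE tracking, no strain
  tensor decomposition, no distensibility (pressure data is out of
  scope).
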
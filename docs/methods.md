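# Methods

`optomotor` implements the quantitative chain that links the anatomy of a
miniature compound eye to walking optomotor behavior: reconstruction of
per-ommatidium geometry from digitized 3-D markers, geometric optics of
the corneal lens, scoring of turning responses from rotating-drum
trajectories, the closed-form Reichardt elementary-motion-detector (EMD)
response, and grid least-squares estimation of the EMD delay time
constant. A synthetic-data generator provides marker sets, walking
bouts and tuning curves with exact ground truth, so every stage is
testable without raw micro-CT or video data.

## Eye reconstruction

Input is one marker set per ommatidium — outer and inner lens tips, six
lens-base rim points, one rhabdomere (cone/rhabdomere transition)
marker — plus three ocelli markers. The pipeline:

1. **Head normalization.** A rigid transform maps the ocelli centroid to
   the origin, the ocelli-plane normal (right-handed in marker order) to
   +z and the first ocellus into the +x half-plane. No scaling; all
   derived scalars are invariant under rigid motion of the input cloud
   (tested property).
2. **Lens-base plane.** The six rim markers are projected onto their
   least-squares plane (numpy SVD). This is the orientation in which the
   projected base area is maximal, which makes the "rotate until the
   base area is maximal" step well posed.
3. **Circle fit.** A least-squares circle
   (`skimage.measure.CircleModel`) in that plane gives the lens center
   and diameter `D`. In-plane radial RMS residuals above a tolerance
   (default 0.5 um) set a warning flag on the record rather than
   rejecting it — manual digitization occasionally produces a bad rim
   point, and the analyst should see it, not lose the lens.
4. **Visual axis.** Two constructions are provided. The default is the
   lens-base plane normal, oriented outward. The alternative
   (`axis_method="top"`) is the projection line from the fitted circle
   center through the outer-tip marker. On a symmetric dome they agree
   exactly. With digitization noise they do not: the outer tip sits only
   the lens half-thickness (~1.6 um) above the base plane, so marker
   noise of 0.1 um tilts the top-marker line by several degrees
   (~0.1/1.6 rad per coordinate), which inflates the *mean* neighbor
   angle by over a degree; the plane normal pools six markers spread
   over the full ~8.8 um rim and is an order of magnitude more stable.
   That robustness is why the normal is the default.

**Neighbors.** "Neighboring ommatidia" is defined by the convex-hull
surface triangulation of the 3-D lens centers; hull edges longer than
2.5x the median edge length are pruned (the hull of a partial eye cap
closes across the opening with edges that are much longer than lattice
edges), and any node isolated by pruning is reconnected to its nearest
center. A symmetrized k-nearest-centers graph (`neighbor_method="knn"`)
is available for fragmentary eyes. The interommatidial angle per edge
is the clamped-arccos angle between unit axes — two vectors always span
a plane, so this equals any "in-plane" evaluation.

**Rhabdomere spacing.** Each ommatidium's `rhabdomere_distance` is the
mean 3-D distance to the rhabdomere tips of its graph neighbors, the
quantity that enters the acceptance-angle ratio.

## Lens optics

For a thin dome lens of diameter `D` whose tip sits `h` above the
principal plane, the surface curvature radius is the sphere through the
rim, `r = (D^2/4 + h^2) / (2h)`; `h = 0` returns an infinite radius
(flat surface) rather than raising, because the lens-maker formula
handles zero curvature naturally. Focal length comes from the thin-lens
lens-maker formula with indices n_air = 1.0, n_lens = 1.45,
n_cone = 1.35 (honeybee values, the standard surrogate for compound-eye
cornea and cone):

    1/l = (n_L - n_A)/r_air - (n_L - n_C)/r_cone

By default the air term takes the **outer** surface radius and the cone
term the inner one — air physically meets the outer cornea. A
`literal_radius_labels` switch swaps the assignment for comparison with
texts that label the radii the other way; it lengthens the focal length
by roughly half. The acceptance angle is the small-angle ratio
`drho = d/l` in degrees.

Eye-level summaries report mean, SD, median and N per quantity, plus
the focal-length/diameter and acceptance/interommatidial ratios both as
ratios of means (the conventional way such eye statistics are reported)
and per ommatidium. Because the optics formulas are nonlinear,
plugging mean `D` and mean `h` into them does not reproduce the mean of
per-ommatidium values; both routes are therefore emitted.

## Behavior scoring

Trajectories are (t, x, y) tracks at nominally 60 Hz of one animal
walking in a 15 mm radius container centered in a 95 mm radius pattern
drum. Two exclusion rules are applied, both always evaluated so the
flagged set is order-independent:

* **wall_following** — radial distance within 0.5 mm (`wall_epsilon`)
  of the container radius for a contiguous span longer than 3 s;
* **short_walk** — cumulative time at speed above 0.5 mm/s
  (`walk_speed_threshold`) below 10 s. Speed is measured as path
  displacement across the 0.25 s smoothing window divided by the window,
  not frame-to-frame differences, so uncorrelated tracking jitter is not
  integrated into phantom walking.

A circling animal's y-position trace is quasi-sinusoidal. After a
centered moving average (default 0.25 s), local maxima with at least
1 mm prominence (`scipy.signal.find_peaks`) mark successive tops of the
walking circle; peak-to-peak spacings are the full-rotation periods and
the response is `R = 360 deg / mean(dt)`, signed by comparing the sense
of the animal's phase progression around its path centroid with the
stimulus direction. The smoothing window and prominence defaults are
free choices for under-specified signal processing and are exposed as
parameters. Periods are aggregated by the mean; an independent
brute-force local-maximum oracle cross-checks the peak detector in the
tests.

Responses are normalized per experiment by the maximum response
magnitude in the group (grouping key configurable; an experiment is one
animal's condition series by default). Normalization preserves sign and
argmax and is idempotent.

**Egocentric correction.** A stripe of wavelength `lambda` (as seen
from the arena center) subtends approximately
`lambda * R_drum / distance` when viewed from `distance` mm — larger
near the pattern (80 mm), smaller far from it (110 mm). The nominal
wavelength remains the analysis default (within a 15 mm container the
deviation is small); near/far apparent values and the mean distance
from center are reported alongside. Drum speed can be verified from a
tracked marker-angle trace at 120 Hz as ten full rotations divided by
the frames they took.

**Onset latency.** Circling onset is detected from the heading turn
rate, computed with centered differences across the smoothing window
(again to avoid integrating jitter). The first span above 45 deg/s
sustained for 0.5 s marks circling; the reported onset is then refined
to where the turn rate crosses the midpoint between the pre-onset level
and the circling plateau — for a centered window that crossing aligns
with the true onset rather than leading it by half a window. On
synthetic bouts with a 1.76 s programmed latency the estimate lands
within 0.25 s at tracking noise up to 0.2 mm.

## EMD model

The steady-state response of the correlation EMD to a drifting grating
factorizes as

    R = (1+x^2)^(-1/2) * sin(arctan x) * sin(2*pi*dphi/lambda) * (1+(drho/lambda)^2)^(-1/2)

with `x = 2*pi*tau*v/lambda`. Angles enter in degrees only through the
dimensionless ratios `dphi/lambda` and `drho/lambda`; the optics term
is implemented exactly in this algebraic form (not the Gaussian
modulation-transfer variant used elsewhere). `sin(arctan x)` is
computed as `x/sqrt(1+x^2)`, identical analytically and stable for
large `|x|`. Structural consequences, all tested: the response is odd
in velocity, bounded by 1 in magnitude, zero at the spatial-aliasing
wavelengths `lambda = 2*dphi/k`, maximal over temporal frequency at
`f_opt = 1/(2*pi*tau)` independent of wavelength (the
wavelength-dependent factors cancel under normalization), and maximal
over wavelength at `lambda_max = 4*dphi`. Sign changes below `2*dphi`
are reported as-is, not clipped.

## Time-constant fit

`grid_fit_tau` evaluates the model at exactly the (wavelength,
velocity) conditions of a measured tuning curve for every `tau` on a
grid (default 10-70 ms in 1.2 ms steps, endpoints inclusive — 51
points; an exclusive-endpoint option gives 50). Model and data curves
are each renormalized to their own maximum magnitude, and the error is
the sum of squared differences over conditions (mean-squared optional;
the choice is recorded in the report). Ties in the argmin break toward
the smaller `tau`. Because the LSE profile is shallow near its minimum,
the fit reports the contiguous band of grid points within a tolerance
(default 0.008) of the minimum, plus the implied
`f_opt = 1/(2*pi*tau_best)`. Fitting is per-wavelength by default;
degenerate (constant) curves are flagged unidentifiable. Gradient or
Bayesian estimation is deliberately out of scope — the explicit grid is
the method.

## Synthetic data

The generators define the conditions the analysis is validated under.
All randomness flows from the single seed in each spec; the same seed
reproduces every number bit-for-bit.

* **Eye.** Visual axes on a sunflower-spiral lattice over a spherical
  cap sized by a hexagonal-packing estimate and then calibrated by
  iteratively rescaling polar angles until the neighbor-graph mean
  interommatidial angle matches the target (default 17.8 deg) to 0.01%;
  per-axis angular jitter spreads the angles with roughly the requested
  SD (4.4 deg default). Only the first two moments of the angle
  distribution are matched — the real eye's regional gradients (smaller
  lenses and angles at the dorsal/ventral margins) are not modeled, so
  passing recovery tests says nothing about spatially structured
  layouts. Lens diameters are drawn N(8.76, 0.76) um; base circles,
  tips at half-thicknesses 1.61/1.28 um and rhabdomere markers at
  9.5 um depth (chosen so neighboring rhabdomere tips sit ~5.8 um
  apart, the measured photoreceptor separation) are constructed exactly
  on the axis, then isotropic Gaussian marker noise is added. The eye
  radius is `D_mean / dphi_target` (~28 um) so lenses tile the cap.
  Noiseless generation followed by full reconstruction reproduces every
  stored ground-truth quantity to numerical precision (tested to
  1e-9).
* **Walk.** 68 s at 60 Hz by default. Before the truncated-normal
  onset latency (1.76 +/- 1.0 s) the animal walks at 5 mm/s with
  heading diffusing at 10 deg/sqrt(s), reflected off the wall — a
  stand-in for the unquantified pre-response behavior, assumed only to
  be low-curvature. From onset it circles at the signed ground-truth
  velocity on a 5 mm radius, tangent-continuous with its current
  heading when that circle fits in the container (otherwise the circle
  is placed through the current position). Optional terminal rest
  fraction (speed ~ 0) and an initial wall-following span glued to the
  container circumference support the exclusion-filter tests. Position
  noise is added everywhere except wall spans, and the path never
  leaves the container.
* **Tuning curves.** Closed-form EMD responses at `tau_true` for each
  (wavelength, velocity) condition plus zero-mean Gaussian noise
  (default SD 0.05), each replicate curve renormalized to its own
  maximum. Defaults use one 60 deg wavelength and seven velocities
  spanning 30-700 deg/s, the protocol's range.

## Numerical choices and degenerate inputs

Arccos arguments are clamped to [-1, 1]. Collinear ocelli or base
markers raise degenerate-input errors; a flat lens surface returns an
infinite radius; a non-positive optical power raises a diverging-lens
error with diagnostics; fewer than two y-peaks yields an empty period
list flagged `no_rotation` rather than an exception; an all-zero
response group is flagged as undefined normalization.

## Problem sizes

Tests and examples run at the study's own scales: 60-ommatidium eyes,
68 s walks at 60 Hz, 51-point tau grids, 20-replicate tuning curves,
and 50-seed recovery sweeps — the full analysis is closed-form or
O(n log n), so nothing needs to be larger.

## Known limitations

Printed per-ommatidium summary statistics (mean radii, focal length,
acceptance angle) cannot be regenerated exactly from other printed
means because the optics formulas are nonlinear and the underlying
per-ommatidium tables are not deposited; the package validates those
chains by synthetic round trips instead. The wavelength-sensitivity
model declines beyond `lambda_max` while measured behavior tends to
saturate; both curves are reported without reconciliation. The EMD
here is the steady-state closed form — no spatio-temporal array
simulation with explicit delay filters, and no wave-optics or
diffraction modeling of the acceptance angle.
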
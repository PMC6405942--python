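# Methods

`mtdyn` quantifies microtubule dynamic instability from two-channel TIRF
time-lapse data: a *seed* channel showing surface-immobilized, stabilized
microtubule fragments, and a *dynamic* channel showing the microtubules
growing and shrinking from the seed ends.  This note records the models,
the estimators, the numerical choices, and what the synthetic validation
data do and do not establish.

## Image model

A filament's intensity footprint is a chain of 2D Gaussians of PSF width
placed at equal arc spacing `ds` along a path, sharing one amplitude `A`,
on a constant background `Bg`:

    F_i = A (G_start,i + G_1,i + ... + G_end,i) + Bg
    G_j,i = exp(-(i_x - mu_x,j)^2 / sx^2 - (i_y - mu_y,j)^2 / sy^2)

Note the convention: the exponent carries `sigma^2`, not `2 sigma^2`; the
PSF width entering it is `sigma = FWHM / (2 sqrt(2 ln 2))` of the measured
PSF (defaults: FWHM 199 nm, pixel size 156 nm, so sigma ≈ 0.54 px).  The
simulator renders filaments with the same functional form, so simulated
data are exact members of the model family up to Poisson noise.

Two path families are used:

* **Line** (seed channel): free parameters are both endpoints, `ds`, `A`,
  `Bg`.  J + 1 Gaussians, J = round(|end − start| / ds), are spread
  *evenly* from start to end, so both tips are chain members, the
  intensity density is uniform up to the very ends, and the endpoint
  gradients are exactly linear (`∂μ_j/∂μ_start = (1 − j/J) I`).  Two
  alternatives were rejected after measurement: differentiating only the
  tip Gaussians (with the chain frozen along a fixed direction) leaves the
  far endpoint with an exponentially small gradient once it is ~1 sigma
  off the ridge, so the fit cannot recover from realistic initialization
  errors; and appending a dedicated tip Gaussian on top of the chain
  doubles the intensity density at the tip and biases fitted endpoints
  ~0.17 px inward.  `ds` acts only through the count J.
* **Cubic** (dynamic channel): path `y = I x^3 + b x^2 + m x + c` with the
  start pinned at the seed end.  `m` is eliminated through the two
  endpoints and `c` through the start point, so the path passes through
  both endpoints for every `(b, I)`; free parameters are the end point,
  `ds`, `A`, `Bg`, `b`, `I`.  The chain steps the path parameter by
  `ds / sqrt(1 + y'(x)^2)`; all derivatives are propagated exactly through
  that placement recursion (for `b = I = 0` they reduce to the line-model
  expressions).  Near-vertical growth is fit in the x↔y-swapped frame.

Coordinates: pixel centers at integer positions, origin top-left, x right,
y down, 0-based.  All outputs use nm for length, s for time, degrees for
angles.

## Chi-squared minimization

The objective is the unweighted sum of squared residuals.  A
Levenberg–Marquardt solver takes analytic Jacobians; the Gauss–Newton
Hessian `H = 2 J^T J` (second-order term dropped) is damped as
`H + mu diag(H)` (Marquardt scaling — more robust than a plain identity
given the mixed parameter scales of pixels and counts), with `mu` divided
by 10 after an accepted step and multiplied by 10 after a rejected one, so
chi-squared never increases along accepted steps.  Defaults: `mu0 = 1e-3`,
stop at relative chi-squared change < 1e-10 or step norm < 1e-4 px or 100
iterations.

Three practical devices make the narrow-PSF objective tractable:

1. **Scale-space cascade.**  The capture radius in the endpoint
   coordinates is about one sigma (≈ 0.5 px).  Each coarse stage blurs the
   *data* with a Gaussian of std `s_b` and fits with the matching widened
   model sigma `sqrt(sigma^2 + 2 s_b^2)`, so the blurred image stays an
   exact member of the model family while the basin widens; `ds` is held
   fixed during blurred stages (it trades off against `A` in a flat
   valley).  Default schedule: blur std 2, 1, 0 px.
2. **Axial endpoint scan.**  The remaining failure mode is an endpoint slid
   along the filament axis where the objective is nearly flat; a greedy 1D
   chi-squared scan per endpoint (default ±3 px in 0.25 px steps) resolves
   it deterministically.  The scan runs on the mildly blurred stage rather
   than the raw image: the raw argmin is biased toward the inward branch,
   whose Poisson fluctuations are larger (variance follows intensity).
3. **Frozen-count polish.**  The integer Gaussian count makes the
   objective piecewise smooth; the final stage freezes `J`, converges the
   smooth problem, re-derives `J` until self-consistent, and compares the
   result against its `J ± 1` neighbours, keeping the lowest chi-squared.
   Fits whose endpoints leave the fit window are rejected as runaways.

With these, a noiseless rendered filament initialized at truth is a fixed
point (chi-squared ≈ 0), and ±2 px endpoint perturbations recover to
better than 0.01 px.

## Subpixel tip refinement (Gaussian mask fit)

Endpoints from the chi-squared fit carry small residual biases — the
cubic model keeps a dedicated tip Gaussian on top of its chain, and noise
asymmetries shift the argmin at low SNR.  Each tip is therefore
refined with an iterative two-Gaussian mask — the tip Gaussian plus one
neighbour displaced `ds` inward, each of std 1.25 sigma — via the
mask-weighted intensity centroid.  (At exactly PSF width the centroid's
restoring signal is weak enough that pixel-noise wells trap the walk and
only ~40% of the fit's tip bias is corrected; widening the weight to
1.25 sigma pools more tip signal per update and was verified on two
independent simulated ensembles to leave the along-axis error mean within
±0.04 px at SNR 3–10, at the cost of a slightly larger error spread.)
Two further corrections make the scheme work on ridges (as opposed to
isolated spots):

* The mask's own centroid sits `ds/2` inward of the tip; that offset is
  subtracted from each update, so the map is neutral in the filament
  interior and driven only by the intensity truncation at the tip.
* The update is run in lockstep on the background-subtracted data and on a
  noiseless *continuous* rendering of the fitted model (dense chain,
  spacing sigma/3, ridge intensity preserved, ending exactly at the fitted
  tip).  Both walks share the residual inward drift, which cancels in
  their difference; the refined tip is `fit_tip + (c_data - c_model)`.
  Calibrating against the continuous rendering rather than the discrete
  fitted chain also cancels the parametrization's tip bias.

Negative background-subtracted values are kept (clipping at zero would add
a positive intensity floor beyond the tip and drag the estimate outward).
Iteration stops when both walks' steps fall below 1e-3 px (the difference
alone is nearly constant during the initial common drift and would stop
too early); if the walks keep jittering under image noise, the trailing
ten iterations are averaged and accepted when their spread is below
0.25 px.  Corrections beyond `2 sigma + ds/2` flag the tip as unrefined —
the mask is a local refinement, and larger corrections mean it latched
onto noise — and the chi-squared endpoint is kept, marked in the output.

## Seed detection

1. **MSER regions.**  Bright extremal regions are the nodes of the image
   max-tree (scikit-image); a node is kept where its relative area growth
   over `delta` gray levels is a local minimum along its branch.  The
   image is smoothed (Gaussian, 1 px) and stretched to 8 bits
   (median→max) first.  Defaults: `delta` 2, area 10 px … 10% of the
   image, max variation 0.5.  Because `delta = 2` sits below the Poisson
   noise scale, candidate nodes whose gray level is under 2× the robust
   background noise (1.4826·MAD, in stretched units) are discarded; nested
   survivors on one branch collapse to the most stable.  Detected regions
   carry their pixel sets and second moments `p, q, r`.
2. **Line initialization.**  The major axis of the region's moment
   ellipse gives slope `m = (r - p + dr)/(2q)`, `dr = sqrt(p^2 + 4q^2 -
   2pr + r^2)`; internally all geometry uses the unit eigenvector, which
   also covers the axis-aligned (`q = 0`) and near-vertical cases.
   Endpoints initialize at the extreme projections of region pixels onto
   the axis; `ds` at sigma; `A`/`Bg` from window statistics.
3. **Fit + refine.**  Line SoG fit in the region's bounding box dilated by
   3 sigma, then mask refinement of both tips.  Candidates shorter than
   5 px or with measured SNR below 1.5 are dropped as noise-born.

On simulated 256² images (8 seeds, separations > 5 px) one-to-one
detection accuracy is 100% at SNR 5–10 and ≈ 95% at SNR 3; median
endpoint errors are 0.2–0.5 px with the along-axis mean within ±0.04 px —
the validation suite reproduces these numbers at the full study scale.

## Tracking

Per frame and per tracked seed end: MSER regions are detected in the
dynamic channel; a ray from the fixed seed end along the previous tip
tangent selects candidate regions; the end-point guess is the far end of
the ray's *first* contiguous intersection with the region, gated at 50% of
the region's robust maximum intensity (95th percentile of region pixels —
the literal maximum doubles where two filaments overlap in a merged region
and would gate out every single-filament pixel).  The cubic SoG model is
fit with the start pinned, warm-started from the previous frame's
polynomial (`b = I = 0` on the first frame, and frozen at zero while the
filament is shorter than 10 px, where the cubic terms are unconstrained);
with several candidate regions, each is fit and the tip nearest the last
known tip wins.  A fit is rejected — the frame becomes a gap — when the
tip direction turns by more than 20° or `b`/`I` jump by more than 10
running standard deviations of the track history.  Gaps are retried next
frame by re-projecting from the seed end (recovery works after arbitrarily
many missed frames as long as the ray still intersects the filament);
tracks close after `max_gap = 5` consecutive gaps.  The accepted tip is
mask-refined and the contour length `∫ sqrt(1 + y'(x)^2) dx` (adaptive
quadrature × pixel size) is reported from seed end to tip.

## Event segmentation and dynamics parameters

Length-versus-time tracks are segmented by iterative RANSAC.  Growth: a
minimal sample (4 points within a local window, spanning ≥ 5 frames) fits
a cubic ridge-regularized toward a line (penalty 1e3 on the quadratic and
cubic coefficients in unit-normalized time/length); inliers are points
within `epsilon` of the curve; the longest quasi-consecutive inlier run
(internal gaps ≤ 2 frames) with positive slope and a total rise above
2 epsilon wins; its points are removed and the search repeats.  `epsilon`
defaults to 3× the per-point localization noise estimated from second
differences (1.4826·MAD/√6).  Shrinkage is found among the remaining
points with a 2-point linear model constrained to fast decline (slope
below −2× the track's fitted growth speed).  Events shorter than 3 frames
are noise; adjacent same-kind events whose linear fits mutually predict
each other's near endpoints within 2 epsilon merge.  Every event is
finalized by a plain linear fit to its inliers, which provides the
reported slope.

Parameter estimators (pooled over tracks):

* `vg`, `vs`: mean (± sd) of growth / shrink event slopes.
* `fc` = (shrink events observed at the end of a resolved growth event) /
  (total duration of those growth events).  A growth phase whose
  terminating shrinkage was too brief to resolve contributes neither an
  event nor exposure, keeping the ratio consistent; with no shrinkage at
  all, `fc = 0` (and `NaN` when nothing was observed).
* `fr` = rescues / total duration of shrink events with an observed
  outcome.  A shrink that returns to the seed baseline (within epsilon) is
  a *total catastrophe*; the subsequent regrowth is re-nucleation from the
  seed and deliberately does **not** count as a rescue, though it is
  reported in the summary counts.  (Counting it — as a literal reading of
  "all growth events per time shrinking" would — overestimates `fr`
  whenever total catastrophes occur.)
* Polarity: with both seed ends tracked, the end with the larger mean
  growth slope is the plus end; ties break on total length gained.

On 100 simulated telegraph trajectories (vg 30 nm/s, vs 300 nm/s, fc
0.01 s⁻¹, fr 0.05 s⁻¹, 0.5 s sampling, 10 nm localization noise) the
acceptance suite verifies slope biases < 5% and both frequencies within
two standard errors.

### Two-state length distribution

`length_distribution` integrates the advection equations of the two-state
model — growing density advected at `+vg`, shrinking at `−vs`, exchange at
rates `fc`/`fr`, shrinkage flux through zero re-entering growth at the
seed — with a first-order upwind scheme (CFL 0.5).  In the bounded regime
(`vg fr < vs fc`) the time-averaged distribution is exponential with decay
`a = fc/vg − fr/vs`; the integration runs to `max(40/(a vg), 20/fc)` so
the slow tail relaxes, and the recovered decay matches `a` to ≈ 4%
(limited by upwind diffusion).  The unbounded regime raises an error for
the stationary query and supports finite-time queries only.

## Synthetic data: what it does and does not emulate

The generator reproduces the imaging physics that limits localization:
PSF-width ridges on a constant background, per-pixel Poisson counts
calibrated so the measured ridge SNR (mean/std of pixel intensities along
a line scan after background subtraction; on zero background the ridge
mean is SNR²) hits the target, filaments on lines and cubics, two-state
telegraph length dynamics with seed clamping and re-nucleation, and
crossing geometries.  It does **not** model camera EM gain or read noise,
photobleaching, finite fluorophore labeling density, focus drift, or
filament lateral motion — passing tests therefore demonstrate correctness
of the estimators under shot-noise-limited imaging, not robustness to
every experimental artifact.  Default conditions: 512×512 px at 156
nm/px, PSF FWHM 199 nm, background 20 counts, ridge SNR 3–10, growth
0.4–3 µm/min-scale speeds with shrinkage an order of magnitude faster.

Validation problem sizes (chosen so the full suite runs comfortably on a
single CPU): seed-detection accuracy on 20 × 15 seeds at 512²; endpoint
localization on ≥ 100 seeds per SNR at 256²; tracking on ~50 movies of 30
frames at 128²; 25 crossing movies (50 tracked ends); 100 telegraph
trajectories of 1300 points.

## Known limitations

* Shrinkage events shorter than 3 frames are unresolvable by construction;
  the frequency estimators stay consistent by discarding the matching
  growth exposure, but per-track event counts undercount at coarse frame
  intervals.  Relatedly, catastrophe–rescue dips shallower than the inlier
  tolerance epsilon are bridged into a single growth event, which dilutes
  the apparent growth speed; resolving them needs deeper excursions
  (vs >> vg) or finer temporal sampling.
* After a total catastrophe the filament is invisible until regrowth
  exceeds the detection limit; if that takes longer than ``max_gap``
  frames the track closes and the regrowth is not re-acquired (re-running
  detection on later frames would start fresh tracks).
* The 95th-percentile intensity reference assumes overlap regions are a
  small fraction of a merged region; many simultaneous collisions in one
  region would lower the gate.
* Both-end tracking assumes the seed detection's two endpoints are the two
  nucleation sites; seeds shorter than ~5 px are filtered out and never
  tracked.
* The LM objective is unweighted least squares; at very low counts a
  Poisson likelihood would localize slightly better.
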
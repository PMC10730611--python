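# Methods

## Hard-rod tactoid model

A tactoid is treated as a uniaxial nematic droplet elongated along its
director, with free energy

    F = gamma * A + K * V / R^2,

the first term the interfacial cost, the second the one-constant Frank
elastic cost of the gently curved (bipolar-like) director field, with the
curvature scale set by the droplet length R.  Twist and saddle-splay are
ignored and splay and bend share a single constant K.  The droplet area and
volume are approximated by their leading elongated-limit scalings A = R*r
and V = R*r^2; these exact proxies are used everywhere in the theory module
(energy, closed form, numeric minimiser) so the three agree to rounding.
Morphometry, by contrast, imputes volumes to measured 2D ellipses with the
prolate-spheroid rule V = (pi/6)*major*minor^2 — a deliberate difference:
the theory proxies are scaling devices valid up to prefactors, while the
spheroid rule is a concrete 2D-to-3D assumption about real droplets.

Minimising F at fixed V (volume eliminated by r = sqrt(V/R), then 1-D
minimisation over log R) gives

    R = (4K/gamma)^(2/5) V^(1/5),    R/r = (4K/gamma)^(3/5) V^(-1/5).

All hidden proportionality constants are set to 1: only exponents and
between-species ratios are meaningful, and every prediction the package
makes is such a ratio.  When parameters place the minimiser outside the
elongated regime (R < r) the shape is returned flagged
`outside_validity` instead of raising, since the scaling relation is only
derived for r << R.

Material constants come from the rod geometry at the homogeneous–bipolar
transition, K = rho*b/a^2 and gamma = 1/(a*b) (length b, width a, packing
fraction rho).  The rod width a cancels from every in-scope prediction
(the two species compared have equal widths), which also insulates the
results from the ambiguity of absolute width values.  The Young–Laplace
interior contact angle cos(theta) = (gamma_bd - gamma_ba)/gamma is reported
in degrees; |cos| > 1 raises an error naming the complete-wetting or
complete-dewetting side.

## Scaling-law fitting

Aspect ratios and volumes span decades and their scatter is multiplicative,
so fits are done in log space: log(R/r) = log C + m log V + eps.  With the
exponent fixed at m = -1/5 the estimator is the sample mean of
log(R/r) - m log V (maximum likelihood under log-normal noise), with
SE = sd(residuals)/sqrt(n); with m free it is OLS (statsmodels).  Prefactor
SEs are delta-method (C * se(log C)); ratios of two prefactors carry
SE = ratio * sqrt(se_logA^2 + se_logB^2).  A case-resampling percentile
bootstrap (default 1000 replicates, >= 100 enforced) is provided because
the appropriate "+/-" estimator for published prefactors is not in general
knowable; no claim is made to reproduce any particular published
uncertainty.  Aspect ratios below 1 are rejected, not inverted, so
major/minor ordering bugs in input tables surface immediately.

## Packing fractions

Filaments are parallel hard cylinders of radius r_f spanning a cubic box of
edge E; occupancy is n*pi*r_f^2/E^2.  In lattice mode the count is
(round(E/s))^2 — nearest-integer per edge, which is what reproduces the
worked tally for E = 89.72 nm, s = 6 nm (14.95 -> 15 per edge, 225 total);
floor would give 196.  No overlap correction is applied, matching how such
tallies are computed in practice; instead `overlapping` flags
configurations that hard cylinders could not realise (2*r_f > s, or
occupancy > 1), e.g. the 6.4 nm-diameter / 6 nm-spacing case whose naive
89.9% occupancy is geometrically impossible and should be read as an upper
bound.

## FRAP

Normalisation is the affine map sending the pre-bleach mean to 100% and the
first post-bleach frame to 0%, with times re-zeroed at the bleach; it is
idempotent and makes the downstream fit invariant to affine transforms of
the raw intensities.  The recovery model I(t) = A(1 - exp(-t/T)) is fitted
by Levenberg–Marquardt-style least squares (scipy `curve_fit`, trust-region
with bounds) on the post-bleach points only, on the 0–1 scale.
Initialisation is deterministic: A0 from the final plateau, T0 the first
time the trace reaches half the plateau.  A is bounded in (0, 1.5]: fits
slightly above 1 are reported but flagged invalid rather than clipped, so a
trace that over-recovers is visible as such.  Half-life is T*ln 2 by
definition; the immobile fraction is 1 - A.  Averaging requires a common
time grid (1e-6 s tolerance) and propagates the per-point SD.

## Morphometry

Segmentation is threshold-initialised morphological Chan–Vese active
contours (scikit-image), 50 iterations by default — the same region-based
active-contour family used in the semi-automated MATLAB workflows this
replaces.  Automatic mode initialises from an Otsu threshold and first
requires the Otsu split to explain at least 75% of the intensity variance
(the between-class variance fraction is ~0.64 for pure Gaussian noise and
>0.9 for a genuine bright foreground), so noise-only channels yield zero
objects instead of speckle.  Seeded mode takes click-like points or masks,
dilated by 3 px by default, mirroring the practice of reusing dilated cell
masks as seeds for the tactoid channel.  Objects below 0.2 um^2 are
discarded as sub-diffraction specks.

Ellipse axes and orientation come from second-order image moments
(regionprops).  Orientations are axial, degrees in [0, 180), measured
counterclockwise on screen from the +x axis (origin top-left, y down);
pairwise differences wrap into [0, 90].  Association uses the mask distance
transform: a cell belongs to the tactoid whose mask overlaps it or lies
within `max_gap_um` (default 0.3 um), nearest winning ties — an explicit
operationalisation of a visual criterion.  The encapsulation score is the
fraction of cell-boundary pixels inside the tactoid mask.  Size excess is
the difference of fitted ellipse majors.  Uptake readout is the
background-subtracted mean of an intensity channel over each cell mask.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **Populations** — volumes log-uniform on [1, 50] um^3, aspect ratios
  C*V^(-1/5)*exp(eps) with eps ~ N(0, 0.1^2), n = 150 by default
  (log-normal noise is the minimal multiplicative model; the volume range
  covers the decades over which the scaling is observed by light
  microscopy).  Axes are back-derived through the spheroid rule.
* **FRAP traces** — 5 pre-bleach frames at 100%, post-bleach sampling at
  1.62 s over 46 s (floor(46/1.62)+1 = 29 frames), additive Gaussian noise
  of SD 2 percentage points; defaults plant a Pf4-like 45.6% immobile
  fraction with T = 8 s.
* **Scenes** — capsule-shaped cells 3 x 0.8 um (typical rod bacteria) at
  0.1 um/px, placed by rejection sampling without overlap; a planted
  fraction (default 0.7) carries a co-centred ellipse tactoid at
  orientation offset N(0, 9 deg); Gaussian PSF of 1 px, Poisson photon
  noise plus Gaussian read noise of SD 2 grey levels.  The planted tactoid
  major axis is the cell's *moment-ellipse* major (analytically ~3.28 um
  for a 3 x 0.8 um capsule) plus the planted size excess, because the
  measurement defines size excess as a difference of moment-ellipse majors;
  planting against the nominal rod length would bias the round trip by the
  capsule/ellipse moment mismatch.
* **Filament boxes** — square lattice at the stated spacing, or parallel
  non-overlapping cylinders rejection-sampled in the cross-section.

What the generators do **not** emulate: uneven illumination, cell
clumping and division septa, out-of-focus light, tactoid internal texture,
drift, detector hot pixels, and realistic optics beyond a Gaussian PSF.
Passing round-trip tests therefore demonstrates correctness of the
estimators and conventions under the stated noise models, not robustness
to every artefact of real micrographs.

## Numerical choices and degenerate inputs

Shape minimisation brackets log R within +-20 of the analytic optimum and
converges to ~1e-10 (well inside the 1e-6 agreement the tests require over
K/gamma in [1e-2, 1e2], V in [1e-2, 1e4]).  Zero-noise bootstrap intervals
degenerate to a point, as they should.  Flat FRAP traces raise a
degenerate-normalisation error rather than dividing by ~0.  Constant images
segment to zero objects.  Tables are validated before use: missing columns
and non-numeric cells are named with their location.

Problem sizes in the validation suite (150-record populations, 200-replicate
bootstrap-coverage runs with 200 resamples each, 25–100 synthetic scenes or
ellipse images per property) were chosen to give stable statistics for the
stated tolerances.

## Known limitations

* The theory yields ratios only; absolute K, gamma, C are not predicted.
* The spheroid volume rule and the association gap are modelling choices;
  both are exposed as parameters/documented assumptions.
* Segmentation is 2D, single-frame, and assumes bright objects on a dark
  background in both channels; brightfield contrast inversion must be
  handled upstream.
* The FRAP model is a single-exponential reaction-limited form; diffusion-
  limited recovery and bleach-spot-size corrections are out of scope.
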
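# Methods

## Scope and design

`optoscreen` models a consumer display as a patterned optogenetic light
source and closes the loop display → light field → behaviour → statistics
entirely in software. The physical display, camera and animals are replaced
by a photometric model, a rasteriser and an agent-based simulator; the
analysis code is the same code a user would point at manually tracked CSV
tables from a real experiment.

## Display photometry

**Spectral overlap.** Emission and action spectra are sampled curves,
linearly interpolated onto the union of their wavelength grids and taken as
zero outside their support. The action spectrum is rescaled to peak 1 before
integration, which makes the overlap a pure spectral-match fraction in
[0, 1], independent of the absolute scale of either curve. Integration is
trapezoidal; agreement with a 0.1 nm reference quadrature is better than
1e-3 for nm-sampled curves.

**Transfer curve.** Consumer panels are strongly nonlinear in drive value.
Default is the display-industry gamma power law `(v/255)^2.2`, overridable
per channel by a measured monotone lookup table pinned to `0 → 0` and
`255 → 1`.

**Lateral spread.** Flux emitted at polar angle θ is weighted
`I(θ) sin θ dθ` and lands at lateral radius `t tan θ` at the top of the
cover glass (optionally refracted: `sin θ_glass = sin θ_air / n`). The
containment radius is the radius at the requested quantile of the angular
flux CDF, computed by cumulative trapezoid on a 1e5-point grid; for a
Lambertian profile this matches the closed form `t tan(arcsin √c)` to
better than 1e-6 relative. Refraction is off by default: the bundled
figures are geometric estimates and the real measured angular profile of
any given panel is what should drive quantitative predictions. The
`AngularProfile.lambertian()` constructor samples cos θ at 0.01° so that
linear interpolation of the profile never limits quadrature accuracy.

**Rise/fall times.** Measured from the commanded ON/OFF instant to the
first crossing of 90% (rise) / 10% (fall) of the plateau, with the plateau
estimated from the last quarter of the ON window and crossings linearly
interpolated between samples. The classical 10–90% convention is available
as an option.

**Honor 8 preset.** Scalar values (1.8/2.1/2.1 µW/mm² per channel, 0.68 mm
glass, 60 Hz, 41 µm × 12 µm sub-pixels, 5.3e-3 µW/mm² black residual) are
published measurements; the sub-pixel emission spectra and opsin action
spectra were never published as data, so the preset uses synthetic Gaussian
bands at field-typical peak wavelengths (red 610 nm, green 535 nm, blue
455 nm; CsChrimson 590 nm, ChR2XXL 460 nm, GtACR1 515 nm, GtACR2 470 nm).
Every number that depends on these curves (overlap fractions, opsin-weighted
drives) is a model number, not a reproduction of a measurement.

## Stimulus model

Coordinates are millimetres, origin at the arena's top-left, x rightward,
y downward; rasters are row-major with pixel centres at half-integer
multiples of `mm_per_px`. A pixel is lit iff its centre lies in the
analytic pattern region — no anti-aliasing — so lit areas are exactly
computable and resolution-consistent (halving the pixel size moves the
ring's lit-area estimate by < 2%).

Black steps render exactly zero; the measured black residual of an LCD
panel is kept as display metadata only. The sync marker (a 2 mm white disc
shown whenever the display is non-black, used to align video with stimulus
onsets) is off by default and configurable, since it sits outside the
experimental area in the physical setup.

The irradiance map multiplies each pixel's per-channel transfer output by
the channel's peak irradiance. The optional blur convolves each channel
with the radial kernel induced by the angular profile and glass thickness
(areal density `C'(r) / 2πr` of the lateral flux CDF, sampled per pixel,
truncated at the 99.5% containment radius and renormalised to sum exactly
to 1, so flux is conserved up to raster-boundary leakage).

## Track metrics

Periods are half-open `[start, end)`; a sample exactly on a boundary
belongs to the later period. A speed value describes an inter-sample
interval and counts toward a period only if the whole interval lies inside
it, so piecewise-constant behaviour aligned to period boundaries is
recovered exactly and no baseline movement leaks into stimulation means.
The optional terminal window (`window_s`) implements the analysis rule for
slow-closing opsins: only the last seconds of each period count.

Normalisation is per animal (stimulation mean / immediately preceding dark
mean), then averaged across animals — group summaries are mean ± s.e.m.
over animals, not over samples. A dark baseline below ε = 0.01 mm/s (or
mm) flags the ratio invalid instead of dividing by near-zero; invalid
ratios are excluded from group means with a count.

The prisoner index weights each inter-sample interval by whether the head
was inside the safe region at the interval's start; for a ring stimulus
the safe region is the interior of the inner circle, translated with the
ring. The positional Gaussian fit uses moment estimates (sample mean/sd),
not histogram least squares; its 95% interval is mean ± 1.96 sd. Two-sample
t tests default to Welch.

## The simulator

The locomotion model is deliberately minimal and entirely this package's
own construction: a run-and-turn walker (constant crawl speed, von Mises
heading noise with concentration κ = 8 per 0.5 s step, Poisson
reorientations at 0.1 Hz) whose interaction with light is point-sampled at
the head from the analytic light field of the active stimulus step. The
analytic point query shares its containment code with the rasteriser, so
simulation and rendering can never disagree; blur is not applied to the
sensed drive.

Response modes: `avoid` resamples the heading (up to 20 draws, then
random) until a one-body-length probe step lowers the sensed drive;
`stop` scales speed by `max(0, 1 − d/d_sat)`; `contract` shortens the
emitted head–tail distance by up to 30%; `roll` raises a rolling flag and
multiplies speed by 1.5 while the drive exceeds threshold; `none` ignores
light. Avoidance is **anticipatory**: the trigger fires when either the
head or a one-body-length probe along the current heading senses
supra-threshold light. Confined larvae are observed to turn when
*approaching* a lit border — larval photo-sensing is anterior-weighted —
and a purely reactive trigger would let sampled head positions dwell in
the lit annulus for ~1 s per boundary encounter, which contradicts the
observed perfect ring confinement. Under an all-black protocol every mode
consumes the random stream identically, so all modes reduce exactly to
`none` in darkness.

Defaults: baseline speed 0.5 mm/s and body length 4 mm (typical third
instar crawling scales), dt = 0.5 s, activation threshold 0.41 µW/mm²
(published minimum evoking a response), saturation drive 2.0 µW/mm²
(≈ one full-drive sub-pixel channel, the scale at which responses were
robust). Arena walls reflect, mimicking a physical chamber rim. All
randomness derives from one seed via `SeedSequence` child streams, one per
agent, so output is bit-identical across runs and independent of cohort
size ordering.

**Canonical experiments.** The ring experiment uses the published geometry
(17/47 mm annulus, 0.17 mm/s in +x, 21.5 min, 1 s sampling) on a 260 × 60
mm virtual arena — longer than any real phone, because at 0.17 mm/s the
ring centre travels 219 mm, which no physical display could accommodate;
a long arena keeps the protocol exactly as stated without wall
interaction. The maze is a 20 mm dark vertical channel flanked by 7 mm and
37 mm lit bands (64 × 40 mm chamber, 5 s sampling); the real chamber's
dimensions are unpublished, so the expected occupancy of this synthetic
chamber (0.31) differs from the published 0.22. Avoid cohorts start inside
the safe region (as the animals were placed); control cohorts start
uniformly in the arena.

## What a green test establishes — and what it does not

The simulator is a stated world: its agents have exactly the sensing and
kinematics described above, not fitted larval parameters. Agreement of the
simulated ring/maze statistics with the published cohort values shows that
the *analysis pipeline* measures confinement and guidance correctly and
that the invented behavioural model is sufficient for those phenomena; it
is not a parameter-level reproduction of larval locomotion. Synthetic
tracks lack posture, peristalsis, habituation, tracking error and the
minutes-long photocycle of slow opsins (represented only by the terminal
analysis window). The control cohorts' statistics depend on the synthetic
chamber geometry and placement rule and are not comparable to the
published control values.

## Numerical choices

* Overlap quadrature: trapezoid on the union grid; tested to 1e-3 against
  a 0.1 nm oracle.
* Spread quantile: 1e5-point cumulative trapezoid; 1e-6 relative against
  the Lambertian closed form.
* Blur kernel: truncated at 99.5% containment, renormalised; kernel sum
  exactly 1 within 1e-6.
* Period boundaries: half-open, interval-containment assignment (see
  above); ties at a boundary go to the later period.
* Zero-variance t tests: one-sample with mean = µ returns (0, n−1, 1);
  with mean ≠ µ returns (±inf, n−1, 0).
* Reflection at walls flips the heading component; at 0.25 mm per step a
  single bounce suffices.
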
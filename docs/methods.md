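# Methods

This note documents the models behind `speedkin`, the conventions and
defaults that matter, what the synthetic data do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinate conventions

Image coordinates are nanometres from the centre of pixel (0, 0); `x`
runs along columns, `y` along rows.  The NE middle plane is a
second-degree polynomial `x(y) = c0 + c1·y + c2·y²`, i.e. the membrane
runs roughly parallel to the image y axis (the recommended acquisition
geometry: a pore on the equator of the nucleus sits parallel to y and
perpendicular to the optical axis).  Pore-frame coordinates are

- **axial**: signed perpendicular distance from the NE curve, negative on
  the cytoplasmic side, positive on the nucleoplasmic side.  Which image
  side is cytoplasm cannot be inferred from an image; it is an explicit
  flag (`cytoplasm_side`, default `'left'` = smaller x) carried by
  `NEModel`.
- **lateral**: signed arclength along the curve from the pore's
  projection.

The perpendicular foot point on the quadratic is found exactly (the
stationarity condition is a cubic in y, solved by `numpy.roots`), not by
a small-angle approximation — NE curvature in a 1 µm window is small, but
exactness is cheap and removes a bias term from every downstream number.

## Camera and optics model

Counts are generated as `adu = offset + (electrons + read noise) /
electrons_per_adu` with `electrons ~ Gamma(shape=Poisson(QE·photons),
scale=em_gain)`.  The Gamma stage reproduces the factor-two excess noise
of an electron-multiplying register (output variance `2·g²·N`) without
simulating the per-stage cascade; at `em_gain = 1` the register is
bypassed (conventional CCD, `F = 1`).  Defaults: 107 nm pixels, 2 ms
exposure, gain 300, sensitivity 45 e⁻/ADU, offset 100 ADU, 50 e⁻ read
noise — a photon then produces ~6.7 ADU and a 3000-photon spot stays
well inside the 16-bit range.

Spots are rendered as the analytic integral of a Gaussian over each
pixel area (`erf` differences), so sub-pixel positions are exact and the
fitted width of a rendered spot is the pixelation-broadened
`√(s² + a²/12)` — exactly the width the precision formula expects.  The
PSF standard deviation defaults to s₀ = 150 nm.  A Gaussian illumination
profile (FWHM 1000 nm, the size of the single-pore illumination field)
attenuates emitters away from the targeted pore; the sub-diffraction
axial confinement of inclined illumination is not modelled beyond this
lateral attenuation.

## Localization precision

For a fitted spot with N detected photons and background SD b (photons
per pixel),

    σ² = F · [ 16·s_a²/(9N) + 8π·b²·s_a⁴/(a²·N²) ],   s_a² = s² + a²/12,

with `F = 2` for an EMCCD and `s² = s₀² + D·Δt/3` for an emitter
diffusing with coefficient D during the exposure.  The pixelation term
`a²/12` is applied in both occurrences of the PSF width, the standard
form of the least-squares localization variance.  Per-localization
precision uses the *fitted* width as s (which already contains the
pixelation broadening; the resulting ~2% overestimate is conservative).
σ is a per-axis standard deviation; the scatter of measured 2D positions
around truth — the number comparable to quoted tracking precisions — is
`√2·σ`, about 7.6 nm at the default N = 3000, b = 2 (per-axis σ = 5.4 nm).
The 30 nm default precision cutoff is the usual first-pass quality filter.

Background SD is estimated from the fit-window border pixels (median/MAD,
converted to photon units by the camera gain).  Fitting is unweighted
least squares with an analytic Jacobian (`scipy.optimize.least_squares`,
tolerances 1e-8, ≤200 iterations); maximum-likelihood fitting of EMCCD
counts would gain ~10–20% precision but the closed form above describes
the least-squares estimator, which keeps the Monte-Carlo/formula
comparison clean.

## Kinetic scheme of the simulator

The generative model for one import attempt (the event phenomenology is
observed; the scheme itself is this package's model):

1. **Approach** — 2D Brownian motion (per-axis step SD `√(2DΔt)`,
   default D = 0.5 µm²/s, chosen as a plausible near-membrane value for a
   ~25 nm particle; it is a configuration parameter, not a claim) from
   axial −150 nm, reflected at −400 nm (axial) and ±300 nm (lateral),
   until first entry into the ±100 nm band.  Approaches exceeding 400
   frames are abandoned (rare; recorded as non-interacting).
2. **Dwell** — an `Exp(dwell_mean)` sojourn, discretised as
   `ceil(T/Δt)` frames (the ceiling of an exponential is exactly
   geometric, which the discretization-aware estimator inverts), with the
   walk reflected into the band.
3. **Branch** — with probability `success_prob` the particle is released
   just beyond +100 nm and diffuses (reflected at the band edge) until it
   crosses +200 nm; otherwise the same on the cytoplasmic side.  The
   release is a jump of up to ~2 band widths in one frame — the
   single-frame pore transit the tracker must be able to follow.

Events are separated by 4 empty frames so a single particle is in the
field at any time, matching the intended acquisition regime.  One master
seed spawns independent child streams for trajectory, emission and camera
noise, making every output byte-reproducible.

What the simulator does **not** emulate: pore-interior substructure and
spatially varying mobility, NE drift and vibration over the acquisition,
fluorophore blinking during transits, multiple simultaneous particles,
axial (z) defocus.  Passing tests therefore validate the estimators
against the stated generative model, not against every complication of
live-cell data.

## Tracking

Greedy nearest-neighbour linking (smallest distance first, ties by lower
particle id) with gap closing; single-pore data are designed for ≤1
particle near the pore, so global assignment adds nothing.  Two radius
defaults are provided: `default_max_link_nm = 3·√(4DΔt)` (~190 nm), the
usual diffusive gate, and `pore_max_link_nm = 2·band + 2·√(2DΔt)`
(~290 nm) used by the single-pore pipeline — the gate must admit the
fastest physical motion of interest, a one-frame crossing of the whole
interaction band, which the purely diffusive radius would cut and thereby
selectively destroy short-dwell successful events (biasing efficiency
low).  Default gap allowance is 1 frame; with chopped (1:n on–off)
illumination the gap allowance should equal the off period.

## Event classification and kinetics

A trajectory in the pore frame is **successful** if its first point is
< −100 nm, its last point > +100 nm, and ≥1 point lies in |axial| ≤ 100
nm; **abortive** if first and last are both < −100 nm with ≥1 in-band
point; otherwise **non-interacting** (including trajectories starting on
the nucleoplasmic side: export is out of scope).  Endpoint rules are
strict inequalities, band membership is inclusive, and only the literal
first and last points decide — no smoothing.  Transport time is the
in-band frame count times the exposure.

Efficiency is `p = n_s/(n_s+n_a)` with binomial s.d. `√(p(1−p)/n)`.  The
mean lifetime τ comes from a least-squares fit of `A·exp(−t/τ)` to the
transport-time histogram (bin width defaults to the exposure time, the
natural resolution of frame-quantised times); `fit_transport_time_mle`
is the maximum-likelihood alternative, and with `frame_ms` set it inverts
the frame discretization (geometric MLE `q̂ = (m̄−1)/m̄`,
`τ = −Δt/ln q̂`), removing the ~half-frame upward bias of a naive sample
mean.

## NE and pore reference

`fit_ne` fits each image row's intensity profile with a 1D Gaussian and
the row peaks with a quadratic; rows with amplitude below 3× the image
noise are excluded, and fewer than 5 valid rows is an error.  On
noiseless input the recovery is sub-2 nm; the residual is a property of
the row-profile reading of a sloped line (neighbouring emitters leak
asymmetrically into a row), not noise.

`fit_npc` fits an elliptical Gaussian and removes the pixelation
broadening from both widths before forming the ratio `σ_y/σ_x` —
without the correction a truly 1.78-elongated spot reads ~1.75 and the
perpendicularity decision is biased.  The accepted band is [1.74, 1.82],
endpoints inclusive.  The reference-pore image is modelled as a long
(~1 s) low-power acquisition integrating ~10⁵ photons, which makes the
band decision reliable per image.  Registration error between two
channels is reported as the RMS of residual displacement vectors after
removing the mean offset (the offset is returned for correction).

## Photobleaching step counting

Recursive binary segmentation with the Gaussian mean-shift likelihood
ratio `G = n·ln(SS₀/(SS₁+SS₂))` (unknown common variance, hence affine
invariance).  The acceptance threshold is the (1−α) quantile of the null
max-G statistic, simulated on white noise at a fixed grid of segment
lengths (10…1280, 5000 replicates, fixed internal seed) and interpolated
in ln n — short segments get a correspondingly lower gate, which is what
makes closely spaced steps detectable.  A backward pruning pass re-tests
every changepoint against its two neighbouring segments and removes the
weakest until all survive either the local likelihood ratio or a
two-sample z-test at 3.3σ using a global noise SD (robust first-difference
estimate); the local LR alone has no power when a neighbour segment is a
single frame, and the z-test is what distinguishes a true one-frame level
(full step down on both sides) from the half-step orphan a misplaced
split leaves behind.  Upward level changes are attributed to blinking and
excluded from the count unless `allow_up=True`.  α is a per-segment-test
level; with k true steps about 2k+1 segments are tested, so an exact
count analysis should use α ≈ 10⁻³ (the package tests do), while the CLI
default of 0.01 favours sensitivity.  Unit (single-fluorophore) intensity
is the mean downward step size when ≥3 steps were found, else it must be
supplied from a separate calibration.

Trace defaults emulate a two-minute acquisition at 50 ms frames (2400
samples) with 8 bleach events spread over about a minute (mean spacing
150 frames).  Bleach times are discretised to whole frames and coincident
steps pushed one frame apart — at the per-frame readout two bleaches in
one frame are a single larger drop, and the generator's truth tables must
stay consistent with what is observable.

## Problem sizes and determinism

The shipped validation uses 500 spots for the precision comparison, 500
import attempts for efficiency recovery, 5000 dwells for the lifetime
estimators, 200 traces for step-count accuracy and 230 pairs for the
registration error — sizes at which the Monte-Carlo error of each check
is several times smaller than its tolerance.  All randomness flows from
`numpy.random.SeedSequence`: one seed, independent child streams, byte-
identical outputs on repetition.

## Known limitations

- 2D only: no astigmatic/axial localization, no z-dependence of the PSF.
- Single-emitter fitting: overlapping particles are not deconvolved; the
  detector keeps at most one candidate per diffraction-limited
  neighbourhood.
- The EM-register model matches mean and variance (F = 2) but not the
  full count distribution tail.
- The exponential-dwell, single-band kinetic scheme is the simplest model
  consistent with the analysis it feeds; real pore passage has structured
  sub-steps that a richer simulator could expose.
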
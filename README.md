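# speedkin

Single-pore nucleocytoplasmic transport analysis for high-speed
single-molecule fluorescence microscopy — from raw image stacks to import
kinetics and fluorophore stoichiometry, with a full synthetic-movie
simulator so the entire chain can be exercised and validated without a
microscope.

## The problem

Viral particles and other cargo cross the nuclear envelope (NE) through
nuclear pore complexes (NPCs) in milliseconds.  Measuring how often an
individual particle that engages a single pore actually makes it into the
nucleus — and how long it dwells in the pore — requires localizing a
moving fluorophore to a few nanometres at 2 ms frame rates, anchoring
those localizations to a pore-centred coordinate frame, and classifying
each approach as a successful or an abortive import event.  `speedkin`
implements that workflow:

- **simulate** — synthetic 16-bit movies of a particle diffusing into a
  ±100 nm pore interaction band (Brownian approach, exponential dwell,
  Bernoulli import branch), wide-field NE images, single-pore reference
  spots, and stepwise photobleaching traces, all with ground truth.
- **localize** — spot detection and least-squares 2D Gaussian fitting
  with a per-localization precision

  σ = √( F·[ 16 s_a²/(9N) + 8π b² s_a⁴/(a²N²) ] ),  s_a² = s² + a²/12,

  where N is the detected photon count, b the background SD in photons
  per pixel, a the pixel size, s the PSF width (motion-broadened by
  s² = s₀² + DΔt/3 for a diffusing emitter) and F the camera excess-noise
  factor (2 for an EMCCD).
- **reference** — NE middle-plane localization (row-wise Gaussian peaks
  fitted with a second-degree polynomial), elliptical single-pore
  centroid with a perpendicularity filter (width ratio within
  1.74–1.82), dual-channel registration error, and the exact
  perpendicular projection into (axial, lateral) pore coordinates.
- **track** — deterministic greedy nearest-neighbour trajectory linking
  with gap closing, and 2D localization histograms.
- **kinetics** — event classification (first/last point beyond ±100 nm,
  at least one in-band localization), transport efficiency
  p = successes/(successes+abortive) with binomial s.d. √(p(1−p)/n), and
  the mean interaction lifetime τ from an exponential fit to the
  transport-time histogram (with a discretization-aware maximum-likelihood
  alternative).
- **stoichiometry** — photobleaching step counting by recursive
  likelihood-ratio segmentation with Monte-Carlo-calibrated thresholds,
  and copy-number estimation from intensity ratios.

## Worked example

```python
import numpy as np
import speedkin as sk
from speedkin.track import pore_max_link_nm

# a single-pore movie: 100 import attempts at 17% success probability
scene = sk.SimScene(n_events=100, success_prob=0.17, rng_seed=8)
camera, optics = sk.CameraModel(), sk.OpticsModel()
stack, truth = sk.simulate_transport_movie(scene, camera, optics)

# reference frame from NE and single-pore images
ne_stack, _ = sk.simulate_ne_image(sk.SimScene(rng_seed=9), camera, optics)
ne = sk.fit_ne(ne_stack, camera)
ne.valid_y_range = (-500.0, 32 * 107.0 + 500.0)
npc_stack, _ = sk.simulate_npc_image(sk.SimScene(rng_seed=10), camera,
                                     optics, width_ratio=1.78)
npc = sk.fit_npc(npc_stack, camera)

# localize, link, transform, classify
locs = sk.localize_stack(stack, optics=optics, moving=True, D_um2_s=0.5,
                         max_precision_nm=30.0)
trajs = sk.transform_trajectories(
    sk.link_trajectories(locs, max_link_nm=pore_max_link_nm()), ne, npc)
events = sk.classify_events(trajs, exposure_ms=camera.exposure_ms)
stats = sk.transport_efficiency(events)
times = np.array([e.transport_time_ms for e in events
                  if e.event_class in ("successful", "abortive")])
tau, tau_se = sk.fit_transport_time_mle(times, frame_ms=camera.exposure_ms)

print(f"NE residual RMS: {ne.residual_rms_nm:.2f} nm; "
      f"NPC width ratio: {npc.width_ratio:.3f} "
      f"(perpendicular: {npc.perpendicular_ok})")
print(f"{len(locs)} localizations, median precision "
      f"{np.median([l.precision_nm for l in locs]):.1f} nm")
print(f"import efficiency: {100*stats.efficiency_p:.1f} +/- "
      f"{100*stats.efficiency_sd:.1f}% ({stats.n_success} successful / "
      f"{stats.n_success + stats.n_abort} interacting)")
print(f"mean interaction time: {tau:.1f} +/- {tau_se:.1f} ms")
```

Output:

```
NE residual RMS: 2.61 nm; NPC width ratio: 1.761 (perpendicular: True)
3901 localizations, median precision 6.0 nm
import efficiency: 17.2 +/- 3.8% (17 successful / 99 interacting)
mean interaction time: 7.3 +/- 0.7 ms
```

The efficiency recovers the generating 17% success probability within its
binomial error; the interaction time is the mean of the exponential dwell
(6 ms here) as seen through 2 ms frames; the median per-localization
precision of ~6 nm is what ~3000 photons per frame buy at this pixel size
and background.

The same pipeline is available from the shell:

```sh
speedkin simulate transport --config cfg.json --out run/ --seed 1
speedkin localize --stack run/transport.tif --camera cfg.json --out run/locs.csv
speedkin reference --ne run/ne.tif --npc run/npc.tif --camera cfg.json --out run/
speedkin track --locs run/locs.csv --ref run/ --out run/trajs.csv
speedkin kinetics --trajs run/trajs.csv --exposure-ms 2 --out run/stats.json
speedkin stoich --trace run/bleach_trace.csv --alpha 0.01
```

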
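# Methods

This note documents the models, numerical choices and limitations behind
the package. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## The measurement being emulated

A combined PARS / autofluorescence microscope acquires five optical
quantities per laser pulse while two stages raster the sample: nuclear UV
absorption (PARS), UV back-scattering, and collagen, NAD(P)H and FAD
autofluorescence. The fast stage oscillates sinusoidally,
`x(t) = (D/2)·sin(2πft)` with peak-to-peak travel `D` (2–10 mm on the
instrument), while the slow stage moves at constant velocity `v`, so pulse
positions form a dense sinusoidal ribbon rather than a raster grid. The
digitizer streams eight channels at a common rate (50 MS/s by default,
20-ns interval): the two quadrature encoder bits and the trigger as binary
signals, the rest as analog values conditioned by the front-end
electronics. Because a 20-ns sample interval cannot resolve the nanosecond
optical transients, the instrument conditions each analog channel before
digitization — the PARS burst is integrated over a modulation window
downstream, and the scattering/autofluorescence channels pass through
sample-and-hold peak detectors that are reset after every pulse. The
simulator reproduces exactly this contract and nothing deeper: it is an
electronics-level emulation, not an optics simulation.

## Simulator model and defaults

- **Phantoms** are five nonnegative 2-D maps (one per contrast source) on
  a common texel grid, sampled bilinearly at pulse positions. Patterns:
  `uniform`, `edge` (half-plane step in every map, for resolution work),
  `gradient` (a step in the ground-truth ORR `fad/(nadh+fad)` at constant
  total autofluorescence — the spatial signature of an uncoupler
  perturbation), `cells` (cytoplasm disks carrying scattering + NAD(P)H +
  FAD with nuclear-absorption disks inside, on a smooth collagen
  background), `checkerboard`.
- **Optical blur**: an optional Gaussian point-spread FWHM per channel,
  applied to the maps before sampling. The diffraction-limited value used
  in the resolution study is `0.51·λ/NA`.
- **Encoder**: position counts `round(x/Δ)` with pitch `Δ = 0.05 µm/count`
  by default — well below the finest 0.25-µm pixel spacing used in
  reconstruction; the count series is emitted on the 2-bit Gray cycle
  00→01→11→10. The simulator refuses configurations whose count rate
  exceeds one count per sample, since a real encoder stream would alias.
- **Triggers** are ideal one-sample pulses on the PRF comb (optional
  Gaussian timing jitter, off by default). PRF is validated against the
  trigger generator's 10 kHz – 2 MHz range.
- **PARS burst**: an exponentially damped half-cycle sinusoid of
  `pars_window` samples (default 16, decay constant window/3). Only its
  windowed sample sum is contractual — it equals the map value times
  `pars_gain`; the shape itself is a placeholder for the real modulation
  transient, which the source system does not specify.
- **Peak detectors**: each held channel carries a fast rise/decay transient
  per pulse whose peak equals the map value; the output tracks the running
  maximum from trigger to reset (reset fixed at `trigger + pars_window + 1`
  samples; held channels are read one sample before reset).
- **Noise**: additive Gaussian read-out noise on the analog channels only,
  with σ expressed as a fraction of that channel's full scale (default 1%).
  It is applied after peak-hold, i.e. modeled as digitizer/read-out noise;
  noise inside the analog hold loop would upward-bias every held sample and
  is deliberately out of scope.
- Analog channels are stored as float32 (the digitizer's 14-bit dynamic
  range is not modeled); "machine precision" claims about the noise-free
  chain therefore mean single precision.

## Trajectory and extraction

Fast positions are decoded by accumulating ±1 Gray-cycle transitions and
multiplying by the encoder pitch; a both-bits-flip transition is physically
unobservable and raises (an opt-in glitch-tolerance flag treats isolated
ones as no movement). The origin is the first sample: images are registered
to reconstructed coordinates, so only relative accuracy matters, and the
decoded position is guaranteed within one count of truth. Slow positions
are `v·i·Δt` from timestamps. Decoding is chunk-invariant: splitting the
stream and stitching (carrying one overlap sample) equals a single pass.

Per pulse, the PARS value is the plain sample sum over the modulation
window (no Δt factor — units are arbitrary and normalized downstream),
minus `window × mean(4 pre-trigger samples)` as an AC-coupling emulation
(disable-able); held channels are read at `trigger + hold_readout_offset`.
Pulses whose window would run off the record are dropped and counted.

## Gridding

Events are interpolated on a shared Delaunay triangulation. The default is
true Sibson natural-neighbor interpolation, implemented via Watson's
cavity construction: for a query q, the triangles whose circumcircles
contain q form the Bowyer–Watson cavity; the area q's inserted Voronoi
cell steals from neighbor v is a convex polygon whose vertices are the
circumcenters of cavity triangles incident to v plus the circumcenters of
(q, a, b) over the cavity boundary edges at v. Weights are stolen areas
normalized by their sum. All geometry is evaluated in q-relative
coordinates; the affine-exactness test holds to 1e-9 relative (measured
~1e-15). Degenerate queries — on the hull boundary, or with collapsed
polygons from cocircular ties — fall back to barycentric interpolation on
the containing simplex, which is also linear-precise; the per-image
fallback count is recorded in the stack metadata. Exactly duplicated event
positions are averaged first; events are sorted before triangulation so
the output is invariant under row permutation. Pixels outside the convex
hull are NaN and excluded from all downstream statistics.

Grid spacing defaults to 0.25 µm (fast) × 0.25 µm (slow) and may be
asymmetric, mirroring the instrument's asymmetric stage stepping; automatic
grids shrink the event bounding box by one pixel per side so that almost
all pixels are inside the hull.

## ORR and statistics

ORR is computed per pixel after gridding (not per pulse), as
`fad/(nadh + fad)`, masked where the denominator is not positive or a
source pixel is invalid. Intensities are physical, so negative noise
excursions are floored at zero first; the map is therefore always in
[0, 1] and invariant to common positive rescaling of both channels. No
cross-channel calibration is applied by default (none is defined for the
simulated system); an optional per-channel gain dict is provided.

Patch statistics tile the grid from its origin into non-overlapping
squares (49 µm default, ≥ 2 pixels per side); a patch needs ≥ 50% valid
pixels, others are dropped and counted. Group comparison uses the
two-sample, two-tailed Welch unequal-variances *t* test
(`t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b)`, Welch–Satterthwaite df), with
normality checked by an Anderson–Darling test decided against the 5%
critical value with the standard sample-size adjustment. Both are
delegated to scipy; the test suite verifies them against the explicit
formulas and a hand-computed 4 + 4 example. No multiple-comparison
correction is applied, matching the analysis protocol being reproduced.

## Rendering

"Removing" outliers above the 98th percentile is implemented as clipping
to the threshold (removal to zero would punch holes in dense channels);
the threshold uses the linear-interpolation percentile over valid pixels.
Note this makes repeated clipping only approximately idempotent: the
re-computed percentile of an already-clipped image sits marginally below
the first threshold, touching only the top band. Channels are then min-max
normalized (a positive constant channel maps to full scale, zero to zero),
which makes composites invariant to per-channel positive rescaling. The
fused composite assigns ORR/scattering/collagen to R/G/B and alpha-blends
the normalized PARS on top along a linear yellow (255,255,0) → white ramp
(the ramp is a design choice; only its endpoints are specified by the
colour convention). Invalid pixels are black. The virtual-H&E rendering is
(R,G,B) = 255 − (PARS, reflectance, 0); its background and invalid pixels
are white.

## Resolution characterization

`fit_esf` fits the four-parameter erf model by Levenberg–Marquardt
(σ bounded positive, initialized at span/10; baseline = min, amplitude =
range, centre = half-rise position). Falling edges are handled by
reflection. `measure_resolution` averages 5 adjacent profile lines by
default (configurable) before fitting and converts σ to FWHM in closed
form — the derivative of the erf fit is Gaussian, so no numerical
differentiation is involved.

The end-to-end resolution study scans a blurred edge phantom with a 20-µm
fast-axis throw, ~0.025-µm pulse spacing, 0.02-µm encoder pitch and
0.02-µm phantom texels, reconstructs at 0.25-µm fast pixels, and fits
across the edge averaging all 21 reconstructed rows (noise in the averaged
profile, not fit bias, dominates the seed-to-seed scatter of the estimate). The sub-PSF pulse spacing matters:
scattered-data interpolation acts as a small low-pass whose variance adds
to the PSF's (~h²/6 for spacing h), so sampling near the pixel pitch would
inflate a 0.27-µm FWHM by tens of percent, while at 0.025-µm spacing the
residual inflation is ~1–2%, within the 3% qualification band. The same
applies to the encoder pitch and texel size. Recovery is verified for
ground-truth FWHMs of 0.3, 0.5 and 1.0 µm (noise-free) and for the
diffraction-limited 266-nm / NA 0.5 configuration at 1% noise.

## Desk-scale study geometries

Simulated studies use fast-axis throws of 20–240 µm and sampling rates of
1–4 MS/s rather than the instrument's millimetre throws at 50 MS/s, chosen
so that every dimensionless regime that matters — counts per sample well
below 1, pulses per fast period, pulse spacing versus pixel pitch, patches
per region — matches the instrument's, while records stay in the
megasample range. The default-configuration stream-geometry checks (8
channels, 50 MS/s, 1 ms) run at the instrument's true rate. The two-region
ORR study uses a 260 × 480 µm gradient phantom, 3.5-µm pixels and 49-µm
patches aligned so the step falls on a patch boundary, giving 16 patches
per region.

## What passing tests do and do not show

The phantoms exercise the full signal path but idealize the physics: no
fluence or depth effects, no spectral crosstalk between autofluorescence
channels, no PMT shot noise or saturation, no stage vibration or encoder
glitches (glitch handling exists but the simulator never emits them), and
the emulated "metabolic perturbation" is a literal step in ground-truth
ORR. Agreement therefore validates the reconstruction and analysis chain —
decoding, extraction, interpolation, ratio, statistics — not the
instrument's contrast mechanisms. The printed linearity R² values of the
physical detector chain depend on bench measurements and are represented
here only by the reusable `linear_fit_r2` operation. CycleGAN stain-style
transfer is out of scope; the pseudocolor virtual-H&E output is the
representation such models consume.

## Determinism

A seed fixes everything: phantom, noise, triangulation (events are sorted,
qhull is deterministic for identical input bytes), and serialization (HDF5
written without timestamps, OME-TIFF without UUIDs, CSV with %.17g floats
so positions round-trip bit-exactly — Delaunay diagonals on quantized
positions flip under 1-ulp perturbations otherwise). Two runs of the same
config produce byte-identical artifacts, which the manifest checksums
make cheap to verify.
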
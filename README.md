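# metalase

Simulation and reconstruction pipeline for combined **photoacoustic remote
sensing (PARS)** and **autofluorescence** metabolic microscopy — the class of
label-free instruments that produce virtual H&E histology and optical
redox-ratio maps from a single scan of unstained tissue or live cells.

The physical instrument scans a sample with a sinusoidally oscillating
voice-coil stage (fast axis) and a constant-velocity stage (slow axis) while
a pulsed 266-nm laser fires at 10–2000 kHz. Eight digitizer channels are
streamed continuously: two AquadB quadrature encoder bits, a trigger, the
PARS (nuclear absorption) channel, UV back-scattering, and three peak-held
autofluorescence channels — collagen, NAD(P)H and FAD. This package
implements everything downstream of (and including a faithful simulator
for) that stream:

- **`acquisition_sim`** — synthetic phantoms (cells, edge targets, ORR
  gradients, …) and a deterministic simulator of the full eight-channel
  record: sinusoidal trajectory, Gray-coded quadrature encoding, trigger
  comb, PARS modulation bursts, analog sample-and-hold peak detectors,
  Gaussian read-out noise.
- **`trajectory`** — AquadB decoding (fast axis) and timestamp-based slow
  positions per sample.
- **`signal_extraction`** — one event per laser pulse: PARS integral over
  the modulation window, peak-held channel read-outs, stage position.
- **`reconstruction`** — Delaunay-based scattered-data gridding of events
  onto Cartesian pixels. Sibson **natural-neighbor** interpolation is the
  default (implemented in-package via Watson's cavity construction, exactly
  linear-precise); barycentric linear interpolation is available as a
  fallback. Output is a multichannel float OME-TIFF with NaN outside the
  convex hull.
- **`metabolic`** — the optical redox ratio

  ```
  ORR = I_FAD / (I_NAD(P)H + I_FAD)  ∈ [0, 1]
  ```

  mapped per pixel, plus the patch workflow: non-overlapping square patches,
  mean ORR per patch, two-region comparison with a two-sample two-tailed
  Welch unequal-variances *t* test and an Anderson–Darling normality check.
- **`rendering`** — the fused composite (R = ORR, G = UV scattering,
  B = collagen, nuclear PARS overlaid on a yellow→white ramp) and the
  pseudocolor virtual-H&E image (PARS → red, reflectance → green, blue
  zeroed, complemented), both after 98th-percentile outlier clipping.
- **`characterization`** — resolution via an error-function edge-spread fit
  `I(x) = b + a/2·(1 + erf((x − x0)/(σ√2)))`, with
  `FWHM = 2√(2 ln 2)·σ` of the implied Gaussian PSF, and OLS linearity
  (slope/intercept/R²) for detector-response curves.
- **`cli` / `config`** — a `metalase` command with `simulate`,
  `reconstruct`, `orr`, `render`, `characterize`, `stats` and `run`
  subcommands driven by validated YAML configs; every run is byte-for-byte
  reproducible for a fixed seed and writes a checksum manifest.

## Worked example

End-to-end on a simulated 200 × 200 µm cell-culture phantom:

```sh
metalase run --config examples/demo.yaml --out demo_out
```

writes `raw.h5`, `events.csv`, `stack.ome.tif`, `orr.ome.tif`,
`metalase.png`, `virtual_he.png` and `report.json` (plus `manifest.json`
with SHA-256 checksums). The report for the shipped config reads, in part:

```
"n_events": 18000,
"orr":     {"mean": 0.4553, "valid_fraction": 0.8016},
"af_nadh": {"mean": 0.1067, "p98": 0.6452},
"af_fad":  {"mean": 0.0711, "p98": 0.4299}
```

18,000 laser pulses were placed on the sinusoidal trajectory and gridded at
1-µm pixels; the mean ORR of ~0.455 reflects the phantom's cytoplasm maps
(NAD(P)H 0.6, FAD 0.4 per cell before jitter, i.e. ground truth 0.4)
pulled up by low-signal background pixels.

The two canned studies reproduce the instrument's qualification
measurements at desk scale:

```python
>>> from metalase.workflows import (diffraction_limited_fwhm,
...                                 edge_resolution_study, gradient_orr_study)
>>> w0 = diffraction_limited_fwhm(0.266, 0.5)   # 266 nm at NA 0.5
>>> round(w0, 5)
0.27132
>>> res = edge_resolution_study(w0, noise_sd=0.01, seed=1)
>>> round(res.report.fwhm_um, 4)                # measured through the chain
0.2797
>>> g = gradient_orr_study(orr_low=0.4, orr_high=0.5)
>>> round(g.measured_step, 4), round(g.welch.t, 1), g.welch.p < 1e-3
(0.099, 235.1, True)
```

The first blurs an edge phantom with a diffraction-limited Gaussian PSF,
simulates the scan, reconstructs the PARS image and fits the ESF: the
recovered FWHM (0.280 µm here) matches the blur within ~3%, the residual being
the known broadening from finite pulse spacing and encoder quantization.
The second pushes a 0.1 ORR step through the whole chain and recovers it
to 1% with an overwhelming Welch statistic over 16 + 16 patches of
49 × 49 µm.

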
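# End-to-end demo: simulated cell-culture phantom, 200 x 200 um field of
# view, reconstructed at 1-um pixels.
#   metalase run --config examples/demo.yaml --out demo_out
schema_version: 1
seed: 11
phantom:
  pattern: cells
  extent_um: [200.0, 200.0]
  resolution_um: 0.5
  seed: 3
  params:
    n_cells: 12
    cyto_radius: 14.0
scan:
  fast_scan_distance: 0.18   # mm peak-to-peak fast-axis throw
  fast_frequency: 25.0       # Hz
  slow_velocity: 0.1         # mm/s
  prf: 1.0e4                 # Hz
  duration: 1.8              # s -> 180 um slow-axis travel
  sample_rate: 1.0e6         # S/s (desk-scale; instrument streams 5e7)
  encoder_resolution: 0.05   # um/count
  noise_sd: 0.01
grid:
  spacing_fast_um: 1.0
  spacing_slow_um: 1.0
  method: natural_neighbor
render:
  percentile: 98.0
stats:
  patch_size_um: 49.0
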
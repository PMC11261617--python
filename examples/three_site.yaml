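seed: 11
n_molecules: 80
design:
  n_sites: 3
  frame_time: 0.1
  duration: 240.0
  species:
    - {label: donor, concentration: 30.0, dwell_time: 1.0}
    - {label: acceptor, concentration: 25.0, dwell_time: 10.0}
truth:
  site_coords: [[0.0, 0.0, 0.0], [4.799, 0.0, 0.0], [3.110, 5.167, 0.0]]
  forster_radius: 5.4
  linker_length: 0.0
noise: {total_intensity: 1000.0, channel_sd: 40.0, baseline_sd: 20.0}
forster: {forster_radius: 5.4, linker_length: 0.0}
detection: {min_frames: 5}
bootstrap: {B: 200}
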
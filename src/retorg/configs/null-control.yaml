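# Light-stable control: identical acquisition, but the retina does not change
# (all kinetic drops and shortenings zero).  No measure should reach
# statistical significance at any timestamp.
scenario: null_control
n_subjects: 14
seed: 0
outdir: retorg-null-control

protocol:
  alines_per_bscan: 600
  bscans_per_volume: 600
  repeats: 4
  lateral_field_mm: [1.2, 1.2]
  axial_pixels: 512
  axial_pitch_um: 1.25
  frame_rate_hz: 16.0
  recording_frames: 4800
  volume_timestamps_min: [0, 5, 10, 15, 20, 25, 30]
  speckle_looks: 4.0
  jitter_amplitude_um: 1.0

kinetics:
  lights_off_s: 30.0
  t_sat_min: 30.0
  ise_drop: 0.0
  elm_rpe_shortening_um: 0.0
  onl_shortening_um: 0.0
  iz_contrast_loss: 0.0
  shape: linear_ramp
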
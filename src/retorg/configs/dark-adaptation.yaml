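# Full dark-adaptation scenario at acquisition scale:
# 14 eyes, seven volumes (light baseline + every 5 min up to 30 min in dark),
# 4 x 600 x 600 A-scans over 1.2 x 1.2 mm, plus a 4800-frame / 16 fps
# high-speed recording with lights off at 30 s.
scenario: dark_adaptation
n_subjects: 14
seed: 0
outdir: retorg-dark-adaptation

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
  ise_drop: 0.25
  elm_rpe_shortening_um: 4.07
  onl_shortening_um: 1.76
  iz_contrast_loss: 0.5
  shape: linear_ramp
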
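"""High-speed recording -> spatiotemporal M-scan -> transition kinetics.

Simulates a 100-s fixed-plane recording at 16 fps with lights off at 30 s,
builds the M-scan (1-s columns, ELM-aligned, ONL-normalized) and summarizes
the post-lights-off trends with line fits and Pearson correlations.
"""

import numpy as np

import retorg

model = retorg.mouse_retina_model()
kin = retorg.KineticsParams()
protocol = retorg.AcquisitionProtocol(
    alines_per_bscan=208, axial_pixels=384, recording_frames=1600, seed=2
)

rec = retorg.render_highspeed(model, kin, protocol, np.random.default_rng(2))
ms = retorg.build_mscan(rec, n_alines=200)
tk = retorg.transition_kinetics(ms)

print(f"recording: {rec.n_frames} frames at {rec.frame_rate_hz:g} fps "
      f"({rec.frame_period_ms:.1f} ms per frame)")
print(f"M-scan: {ms.n_columns} columns of {ms.column_period_s:g} s, "
      f"lights off at column {ms.lights_off_col}")
print()
print(f"displacement slope: {tk.displacement_slope_um_per_min:+.3f} um/min "
      f"(generator: {-kin.elm_rpe_shortening_um / kin.t_sat_min:+.3f})")
print(f"r(time, ISe intensity)    = {tk.r_time_ise:+.3f}")
print(f"r(time, displacement)     = {tk.r_time_displacement:+.3f}")
print(f"r(ISe, displacement)      = {tk.r_ise_displacement:+.3f}")
print()
print("Time correlates negatively with both the ISe intensity and the")
print("ELM-RPE displacement, and the two responses correlate positively")
print("with each other - the structural and intensity signals move together.")
print("Over this short 100-s demo snippet the per-column noise keeps |r|")
print("moderate; on the full 5-min recording (4800 frames, as in the test")
print("suite) all three correlations exceed |r| = 0.9.")
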
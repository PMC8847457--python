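"""Repeated-measures inference across the dark-adaptation timestamps.

Builds a subject x timestamp table of ELM-RPE thicknesses from fast
profile-level phantom simulations (6 eyes, 7 timestamps), runs the one-way
repeated-measures ANOVA and the Bonferroni-corrected paired comparisons
against the light-adapted baseline.
"""

import numpy as np

import retorg
from retorg.preprocess import DepthProfile, upsample_profile

model = retorg.mouse_retina_model(curvature_um_per_mm2=0.0)
kin = retorg.KineticsParams()
protocol = retorg.AcquisitionProtocol(alines_per_bscan=128, axial_pixels=320)
times = protocol.volume_timestamps_min

rng = np.random.default_rng(4)
vals = np.empty((6, len(times)))
for j, t in enumerate(times):
    clean = retorg.render_aline(retorg.kinetics_at(model, kin, t), 0.0,
                                protocol, noiseless=True)
    for i in range(6):
        noisy = (clean * rng.gamma(4.0, 0.25, (128, clean.size))).mean(axis=0)
        prof = DepthProfile(upsample_profile(noisy), protocol.axial_pitch_um / 4)
        vals[i, j] = retorg.measure_profile(prof).thickness.elm_rpe_um

table = retorg.RepeatedMeasuresTable(vals, times, "elm_rpe", "um")
aov = retorg.rm_anova(table)
post = retorg.bonferroni_vs_baseline(table)

print(f"ELM-RPE means (um): {np.round(aov.means, 2)}")
print(f"RM-ANOVA: F({aov.df_effect}, {aov.df_error}) = {aov.f_statistic:.1f}, "
      f"p = {aov.p_value:.2e} (GG epsilon {aov.gg_epsilon:.2f})")
print(f"Bonferroni-adjusted p vs baseline (factor {post.bonferroni_factor}):")
for t, p in zip(post.timestamps, post.adjusted_p):
    print(f"  {t:4.0f} min: {p:.2e}")
print(f"earliest significant timestamp: {post.earliest_significant} min")
print()
print("The linear-ramp kinetics make even the first dark timestamp (5 min)")
print("significantly thinner than the light-adapted baseline.")
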
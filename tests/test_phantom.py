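"""Phantom generator: resolution formula, kinetics model, rendering."""

import math

import numpy as np
import pytest

import retorg
from retorg.errors import InvalidParameterError, RenderError
from retorg.phantom import LAYER_ORDER, Layer, _staircase_profile

from conftest import noiseless_profile


class TestAxialResolution:
    @pytest.mark.parametrize(
        "wavelength_nm, bandwidth_nm, expected_um",
        [(810, 100, 2.9), (1310, 100, 7.6)],
    )
    def test_coherence_length(self, wavelength_nm, bandwidth_nm, expected_um):
        # (2 ln2 / pi) * lambda^2 / dlambda, quoted to one decimal
        assert retorg.axial_resolution(wavelength_nm, bandwidth_nm) == pytest.approx(
            expected_um, abs=0.05
        )

    def test_monotone_decreasing_in_bandwidth(self):
        res = [retorg.axial_resolution(810, bw) for bw in (50, 100, 200, 1e6)]
        assert all(b < a for a, b in zip(res, res[1:]))
        assert res[-1] < 0.01  # bandwidth -> infinity gives resolution -> 0

    @pytest.mark.parametrize("args", [(0, 100), (810, 0), (-810, 100), (810, -1)])
    def test_rejects_non_positive_inputs(self, args):
        with pytest.raises(InvalidParameterError):
            retorg.axial_resolution(*args)


class TestRetinaLayerModel:
    def test_default_landmarks(self, model):
        assert model.inner_retina_um == pytest.approx(79.42)
        assert model.onl_um == pytest.approx(58.08)
        assert model.elm_rpe_um == pytest.approx(48.73)
        assert model.cone_tip_offset_um == pytest.approx(13.4)
        assert model.rod_tip_offset_um == pytest.approx(20.9)
        assert model.cone_tip_offset_um < model.rod_tip_offset_um

    def test_layers_contiguous_and_ordered(self, model):
        assert tuple(l.name for l in model.layers) == LAYER_ORDER
        for a, b in zip(model.layers, model.layers[1:]):
            assert a.outer_um == pytest.approx(b.inner_um)

    def test_rejects_onl_brighter_than_bands(self, model):
        with pytest.raises(InvalidParameterError, match="ONL"):
            model.with_reflectance(ONL=5.0)

    def test_rejects_noncontiguous_layers(self, model):
        layers = list(model.layers)
        layers[3] = Layer(layers[3].name, layers[3].inner_um,
                          layers[3].outer_um + 1.0, layers[3].reflectance)
        with pytest.raises(InvalidParameterError, match="contiguous"):
            retorg.RetinaLayerModel(layers=tuple(layers))


class TestKinetics:
    def test_pre_lights_off_identity(self, model, kinetics):
        snap = retorg.kinetics_at(model, kinetics, -1.0)
        assert snap is model

    def test_linear_midpoint_halves_the_shortening(self, model, kinetics):
        snap = retorg.kinetics_at(model, kinetics, kinetics.t_sat_min / 2)
        assert model.elm_rpe_um - snap.elm_rpe_um == pytest.approx(4.07 / 2)

    def test_saturation_clamp(self, model, kinetics):
        s1 = retorg.kinetics_at(model, kinetics, kinetics.t_sat_min)
        s2 = retorg.kinetics_at(model, kinetics, 2 * kinetics.t_sat_min)
        for a, b in zip(s1.layers, s2.layers):
            assert a == b

    def test_saturated_changes_match_parameters(self, model, kinetics):
        snap = retorg.kinetics_at(model, kinetics, 30.0)
        assert model.elm_rpe_um - snap.elm_rpe_um == pytest.approx(4.07)
        assert model.onl_um - snap.onl_um == pytest.approx(1.76)
        assert snap["ISe"].reflectance == pytest.approx(4.0 * 0.75)

    @pytest.mark.parametrize("t", [0.0, 2.5, 10.0, 30.0, 60.0])
    def test_snapshots_keep_layer_ordering_and_inner_retina(self, model, kinetics, t):
        snap = retorg.kinetics_at(model, kinetics, t)
        for a, b in zip(snap.layers, snap.layers[1:]):
            assert a.outer_um == pytest.approx(b.inner_um)
            assert a.thickness_um > 0
        for name in ("NFL", "GCL", "IPL", "INL", "OPL"):
            assert snap[name] == model[name]

    def test_null_kinetics_is_static(self, model):
        null = retorg.KineticsParams.null()
        snap = retorg.kinetics_at(model, null, 30.0)
        assert snap.layers == model.layers

    def test_exponential_shape_saturates_at_t_sat(self, model):
        kin = retorg.KineticsParams(shape="exponential")
        assert kin.ramp(kin.t_sat_min) == pytest.approx(1.0)
        assert 0.5 < kin.ramp(kin.t_sat_min / 2) < 1.0  # above the linear ramp

    @pytest.mark.parametrize("bad", [{"ise_drop": 1.5}, {"elm_rpe_shortening_um": -1},
                                     {"t_sat_min": 0}, {"shape": "step"}])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            retorg.KineticsParams(**bad)


class TestRenderAline:
    def test_noiseless_elm_peak_at_true_depth(self, flat_model, small_protocol):
        prof = retorg.render_aline(flat_model, 0.0, small_protocol, noiseless=True)
        lo = int((flat_model.elm_depth_um - 6) / 1.25)
        hi = int((flat_model.elm_depth_um + 6) / 1.25)
        peak_um = (lo + np.argmax(prof[lo:hi])) * 1.25
        assert abs(peak_um - flat_model.elm_depth_um) <= 1.25 / 2 + 1e-9

    def test_speckle_is_unit_mean(self, flat_model, small_protocol):
        # Monte-Carlo over 10^4 draws: E[speckled] = noiseless at every depth;
        # the per-depth z bound accounts for testing all 384 depths at once
        clean = retorg.render_aline(flat_model, 0.0, small_protocol, noiseless=True)
        rng = np.random.default_rng(0)
        n = 10_000
        draws = clean * rng.gamma(4.0, 0.25, size=(n, clean.size))
        se = draws.std(axis=0, ddof=1) / math.sqrt(n)
        z = np.abs(draws.mean(axis=0) - clean) / se
        assert np.mean(z <= 3.0) > 0.99
        assert z.max() <= 4.5

    def test_determinism(self, flat_model, small_protocol):
        a = retorg.render_aline(flat_model, 0.0, small_protocol,
                                np.random.default_rng(9))
        b = retorg.render_aline(flat_model, 0.0, small_protocol,
                                np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_out_of_field_position_rejected(self, flat_model, small_protocol):
        with pytest.raises(InvalidParameterError):
            retorg.render_aline(flat_model, 0.9, small_protocol, noiseless=True)

    def test_layers_exceeding_window_raise_named_error(self, model, kinetics):
        proto = retorg.AcquisitionProtocol(axial_pixels=128)  # 160 um window
        with pytest.raises(RenderError, match="RPE|OS|choroid|ONL|I"):
            retorg.render_aline(model, 0.0, proto, noiseless=True)

    @pytest.mark.parametrize("separation_um, n_peaks", [(2.0, 1), (6.0, 2)])
    def test_psf_merges_subresolution_double_bands(self, flat_model,
                                                   separation_um, n_peaks):
        # two near-delta bright bands closer than the 2.9-um PSF FWHM merge
        # into one maximum; at >= 2x FWHM they stay distinct
        cone_c = flat_model.cone_tip_depth_um
        rod_c = cone_c + separation_um
        half = 0.25
        edits = {
            "OS": (flat_model["OS"].inner_um, cone_c - half),
            "IZ_cone": (cone_c - half, cone_c + half),
            "OS_inter": (cone_c + half, rod_c - half),
            "IZ_rod": (rod_c - half, rod_c + half),
            "pre_RPE": (rod_c + half, flat_model["pre_RPE"].outer_um),
        }
        layers = tuple(
            Layer(l.name, *edits[l.name], l.reflectance) if l.name in edits else l
            for l in flat_model.layers
        )
        m = retorg.RetinaLayerModel(layers=layers, curvature_um_per_mm2=0.0)
        z = np.arange(0, 320, 0.05)
        prof = _staircase_profile(m, z)
        lo = int((m["OS"].inner_um + 1.0) / 0.05)
        hi = int((rod_c + 2.0) / 0.05)
        seg = prof[lo:hi]
        local_max = np.sum((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:]))
        assert local_max == n_peaks


class TestRenderVolume:
    def test_shape_follows_protocol(self, small_volume, small_protocol):
        assert small_volume.data.shape == (
            small_protocol.repeats,
            small_protocol.bscans_per_volume,
            small_protocol.alines_per_bscan,
            small_protocol.axial_pixels,
        )

    def test_default_protocol_shape_is_paper_raster(self):
        proto = retorg.AcquisitionProtocol()
        assert (proto.repeats, proto.bscans_per_volume, proto.alines_per_bscan) \
            == (4, 600, 600)

    def test_seeded_rerender_is_bit_identical(self, model, kinetics, small_protocol):
        v1 = retorg.render_volume(model, kinetics, small_protocol, 5.0,
                                  np.random.default_rng(3))
        v2 = retorg.render_volume(model, kinetics, small_protocol, 5.0,
                                  np.random.default_rng(3))
        assert np.array_equal(v1.data, v2.data)

    def test_null_kinetics_volume_static_in_expectation(self, flat_model):
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=16, bscans_per_volume=8, axial_pixels=256, repeats=4
        )
        null = retorg.KineticsParams.null()
        v0 = retorg.render_volume(flat_model, null, proto, 0.0, np.random.default_rng(1))
        v30 = retorg.render_volume(flat_model, null, proto, 30.0, np.random.default_rng(2))
        m0 = v0.data.mean(axis=(0, 1, 2))
        m30 = v30.data.mean(axis=(0, 1, 2))
        n = proto.repeats * 8 * 16
        se = v0.data.std(axis=(0, 1, 2)) / math.sqrt(n)
        z = np.abs(m0 - m30) / (math.sqrt(2.0) * se + 1e-9)
        assert np.mean(z <= 3.0) > 0.99  # multiplicity over 256 depths
        assert z.max() <= 5.0


class TestRenderHighspeed:
    def test_frame_count_and_period(self, flat_model):
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=8, axial_pixels=256, recording_frames=64,
            speckle_looks=math.inf, jitter_amplitude_um=0.0,
        )
        kin = retorg.KineticsParams(lights_off_s=2.0)
        rec = retorg.render_highspeed(flat_model, kin, proto)
        assert rec.n_frames == 64
        assert rec.frame_period_ms == pytest.approx(62.5)

    def test_first_30s_drawn_from_baseline_only(self, flat_model, kinetics):
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=8, axial_pixels=256, recording_frames=640,
            speckle_looks=math.inf, jitter_amplitude_um=0.0,
        )
        rec = retorg.render_highspeed(flat_model, kinetics, proto)
        pre = rec.data[: int(30 * 16)]
        assert np.allclose(pre, pre[0])  # identical until lights off
        assert not np.allclose(rec.data[-1], pre[0])  # kinetics then engage

    def test_zero_jitter_keeps_elm_fixed(self, flat_model):
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=8, axial_pixels=256, recording_frames=96,
            speckle_looks=math.inf, jitter_amplitude_um=0.0,
        )
        rec = retorg.render_highspeed(
            flat_model, retorg.KineticsParams.null(lights_off_s=2.0), proto
        )
        peaks = rec.data[:, 4, :].argmax(axis=1)
        assert np.all(peaks == peaks[0])


class TestSpeckleAveraging:
    def test_variance_scales_inversely_with_frames_averaged(self):
        # averaging N independent speckle frames divides the pixel variance by N
        rng = np.random.default_rng(5)
        single = rng.gamma(4.0, 0.25, size=(4000,))
        averaged = rng.gamma(4.0, 0.25, size=(4000, 8)).mean(axis=1)
        ratio = single.var(ddof=1) / averaged.var(ddof=1)
        assert ratio == pytest.approx(8.0, rel=0.25)


class TestNoiselessBandStructure:
    def test_staircase_has_the_five_outer_band_maxima(self, flat_model, small_protocol):
        """ELM, ISe, cone tip, rod tip and RPE are distinct maxima with hypo
        plateaus between them."""
        prof = noiseless_profile(flat_model, small_protocol)
        meas = retorg.measure_profile(prof)
        assert meas.double_peak.resolved
        depths = [meas.bands["ELM"], meas.bands["ISe"],
                  meas.double_peak.cone_tip_um, meas.double_peak.rod_tip_um,
                  meas.bands["RPE"]]
        assert all(b > a for a, b in zip(depths, depths[1:]))


class TestGroundTruth:
    def test_sidecar_roundtrip(self, model, kinetics, tmp_path):
        import json

        path = tmp_path / "truth.json"
        retorg.write_ground_truth(path, model, kinetics, [0.0, 30.0])
        payload = json.loads(path.read_text())
        t0 = payload["truth"]["0.0"]
        t30 = payload["truth"]["30.0"]
        assert t0["thicknesses_um"]["elm_rpe"] == pytest.approx(48.73)
        assert t30["thicknesses_um"]["elm_rpe"] == pytest.approx(48.73 - 4.07)
        assert t0["tip_offsets_um"]["cone"] == pytest.approx(13.4)
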
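"""ELM detection, flattening and the representative-profile reduction."""

import inspect

import numpy as np
import pytest

import retorg
from retorg.errors import DetectionError, InvalidParameterError, NormalizationError, ProtocolError
from retorg.preprocess import (
    DepthProfile,
    detect_elm,
    flatten,
    normalize_onl,
    representative_profile,
    upsample_profile,
)


def true_trace_px(model, protocol, n_alines):
    x = protocol.lateral_positions_mm(n_alines, protocol.lateral_field_mm[0])
    return (model.elm_depth_um + model.curvature_um_per_mm2 * x**2) / protocol.axial_pitch_um


class TestDetectElm:
    def test_flat_noiseless_trace_is_constant_at_truth(self, flat_model, small_protocol):
        b = retorg.render_bscan(flat_model, small_protocol, noiseless=True)
        tr = detect_elm(b, small_protocol.axial_pitch_um)
        truth = flat_model.elm_depth_um / small_protocol.axial_pitch_um
        assert np.all(np.abs(tr.positions_px - truth) <= 0.5)
        assert np.ptp(tr.positions_px) < 0.2

    def test_curved_noiseless_trace_matches_quadratic(self, model, small_protocol):
        b = retorg.render_bscan(model, small_protocol, noiseless=True)
        tr = detect_elm(b, small_protocol.axial_pitch_um)
        truth = true_trace_px(model, small_protocol, small_protocol.alines_per_bscan)
        assert np.all(np.abs(tr.positions_px - truth) <= 0.5)

    def test_single_frame_speckle_accuracy(self, model):
        # single-frame speckle at the study noise level: >= 99% of
        # A-lines localized within one pixel (fixed-seed simulation)
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=256, axial_pixels=384, seed=0
        )
        b = retorg.render_bscan(model, proto, np.random.default_rng(0))
        tr = detect_elm(b, proto.axial_pitch_um)
        truth = true_trace_px(model, proto, 256)
        assert np.mean(np.abs(tr.positions_px - truth) <= 1.0) >= 0.99

    def test_structureless_image_fails_loudly(self):
        rng = np.random.default_rng(2)
        noise = rng.gamma(4.0, 0.25, size=(32, 384))
        with pytest.raises(DetectionError, match="confident"):
            detect_elm(noise, 1.25)


class TestFlatten:
    def test_identity_on_flat_input(self, flat_model, small_protocol):
        b = retorg.render_bscan(flat_model, small_protocol, noiseless=True)
        tr = detect_elm(b, small_protocol.axial_pitch_um)
        flat = flatten(b, tr, reference_px=float(np.median(tr.positions_px)))
        assert np.allclose(flat, b, atol=1e-6)

    def test_curved_phantom_flattens_to_one_pixel(self, model, small_protocol):
        b = retorg.render_bscan(model, small_protocol, noiseless=True)
        tr = detect_elm(b, small_protocol.axial_pitch_um)
        flat = flatten(b, tr)
        tr2 = detect_elm(flat, small_protocol.axial_pitch_um)
        assert np.ptp(tr2.positions_px) <= 1.0

    def test_shift_then_flatten_recovers_original(self, flat_model, small_protocol):
        b = retorg.render_bscan(flat_model, small_protocol, noiseless=True)
        k = 7
        shifted = np.roll(b, k, axis=1)
        shifted[:, :k] = 0.0
        tr = detect_elm(shifted, small_protocol.axial_pitch_um)
        ref = flat_model.elm_depth_um / small_protocol.axial_pitch_um
        back = flatten(shifted, tr, reference_px=ref)
        inner = slice(2 * k, b.shape[1] - 2 * k)
        assert np.allclose(back[:, inner], b[:, inner], atol=0.02)

    def test_reference_outside_window_rejected(self, flat_model, small_protocol):
        b = retorg.render_bscan(flat_model, small_protocol, noiseless=True)
        tr = detect_elm(b, small_protocol.axial_pitch_um)
        with pytest.raises(InvalidParameterError, match="reference"):
            flatten(b, tr, reference_px=1e4)


class TestRepresentativeProfile:
    def test_uniform_volume_reduces_to_upsampled_aline(self, flat_model):
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=64, bscans_per_volume=48, axial_pixels=384
        )
        aline = retorg.render_aline(flat_model, 0.0, proto, noiseless=True)
        data = np.broadcast_to(
            aline.astype(np.float32), (2, 48, 64, aline.size)
        ).copy()
        vol = retorg.OCTVolume(data=data, axial_pitch_um=1.25, lateral_pitch_um=2.0)
        prof = representative_profile(vol, n_bscans=40, n_alines=50)
        assert prof.intensity.size == 4 * aline.size
        assert np.allclose(prof.intensity, upsample_profile(aline), atol=1e-5)

    def test_insufficient_bscans_error_reports_requirements(self, small_volume):
        with pytest.raises(ProtocolError, match="150"):
            representative_profile(small_volume)  # defaults need 150 x 200

    def test_default_windows_aggregate_120k_ascans(self):
        sig = inspect.signature(representative_profile)
        n = (retorg.AcquisitionProtocol().repeats
             * sig.parameters["n_bscans"].default
             * sig.parameters["n_alines"].default)
        assert n == 120_000

    def test_profile_commutes_with_global_gain(self, small_volume):
        prof1 = representative_profile(small_volume, n_bscans=40, n_alines=50)
        gained = retorg.OCTVolume(
            data=small_volume.data * 3.0,
            axial_pitch_um=small_volume.axial_pitch_um,
            lateral_pitch_um=small_volume.lateral_pitch_um,
        )
        prof2 = representative_profile(gained, n_bscans=40, n_alines=50)
        assert np.allclose(prof2.intensity, 3.0 * prof1.intensity, rtol=1e-6)

    def test_averaging_reduces_speckle(self, flat_model):
        proto = retorg.AcquisitionProtocol(
            alines_per_bscan=64, bscans_per_volume=48, axial_pixels=384, seed=4
        )
        vol = retorg.render_volume(
            flat_model, retorg.KineticsParams.null(), proto, 0.0,
            np.random.default_rng(4),
        )
        prof = representative_profile(vol, n_bscans=40, n_alines=50)
        clean = upsample_profile(
            retorg.render_aline(flat_model, 0.0, proto, noiseless=True)
        )
        # restrict to reflectance plateaus: on band edges the residual is
        # dominated by sub-pixel alignment, not speckle
        grad = np.abs(np.gradient(clean))
        sel = (clean > 0.2) & (grad < 0.01 * clean)
        rel_resid = np.std((prof.intensity[sel] - clean[sel]) / clean[sel])
        single_rel = 0.5  # 4-look speckle has relative SD 1/sqrt(4)
        n_ascans = proto.repeats * 40 * 50
        predicted = single_rel / np.sqrt(n_ascans)
        # within a factor 2 of the independent-A-scan prediction
        assert predicted / 2 < rel_resid < 2 * predicted


class TestNormalizeOnl:
    def test_divides_by_onl_mean(self, baseline_profile, flat_model):
        span = (flat_model.elm_depth_um - 50, flat_model.elm_depth_um - 10)
        norm = normalize_onl(baseline_profile, span)
        lo, hi = span
        q = (hi - lo) / 4
        sel = (norm.depth_um >= lo + q) & (norm.depth_um <= hi - q)
        assert norm.intensity[sel].mean() == pytest.approx(1.0)
        assert norm.normalized == "onl"

    def test_gain_invariance(self, baseline_profile, flat_model):
        span = (flat_model.elm_depth_um - 50, flat_model.elm_depth_um - 10)
        doubled = DepthProfile(baseline_profile.intensity * 2.0,
                               baseline_profile.pitch_um)
        a = normalize_onl(baseline_profile, span)
        b = normalize_onl(doubled, span)
        assert np.allclose(a.intensity, b.intensity)

    def test_scalar_halving(self):
        prof = DepthProfile(np.full(400, 2.0), 0.3125)
        norm = normalize_onl(prof, (10.0, 50.0))
        assert np.allclose(norm.intensity, 1.0)

    def test_zero_onl_rejected(self):
        prof = DepthProfile(np.zeros(400), 0.3125)
        with pytest.raises(NormalizationError):
            normalize_onl(prof, (10.0, 50.0))


class TestUpsample:
    def test_length_and_node_values(self):
        vals = np.array([0.0, 1.0, 4.0, 9.0])
        up = upsample_profile(vals, 4)
        assert up.size == 16
        assert np.allclose(up[::4], vals)
        assert up[2] == pytest.approx(0.5)  # linear between nodes
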
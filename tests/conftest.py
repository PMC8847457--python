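"""Shared fixtures: reduced-raster phantoms that keep the study-condition
kinetics, noise and optics while shrinking the lateral scan so the suite
runs quickly."""

import numpy as np
import pytest

import retorg
from retorg.preprocess import DepthProfile, upsample_profile


@pytest.fixture(scope="session")
def model():
    return retorg.mouse_retina_model()


@pytest.fixture(scope="session")
def flat_model():
    return retorg.mouse_retina_model(curvature_um_per_mm2=0.0)


@pytest.fixture(scope="session")
def kinetics():
    return retorg.KineticsParams()


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced lateral raster (4 x 48 x 64 A-scans, 384-px axial window) with
    study-condition noise and optics."""
    return retorg.AcquisitionProtocol(
        alines_per_bscan=64, bscans_per_volume=48, axial_pixels=384, seed=0
    )


def noiseless_profile(m, protocol, t_min=0.0, kin=None):
    """Noiseless on-axis representative profile of a kinetics snapshot."""
    snap = retorg.kinetics_at(m, kin or retorg.KineticsParams(), t_min)
    aline = retorg.render_aline(snap, 0.0, protocol, noiseless=True)
    return DepthProfile(
        upsample_profile(aline), protocol.axial_pitch_um / 4, timestamp_min=t_min
    )


@pytest.fixture(scope="session")
def baseline_profile(flat_model, small_protocol):
    return noiseless_profile(flat_model, small_protocol)


@pytest.fixture(scope="session")
def baseline_measurement(baseline_profile):
    return retorg.measure_profile(baseline_profile)


@pytest.fixture(scope="session")
def small_volume(model, kinetics, small_protocol):
    return retorg.render_volume(
        model, kinetics, small_protocol, 0.0, np.random.default_rng(1)
    )


@pytest.fixture(scope="session")
def study_transition_kinetics(model, kinetics):
    """Transition kinetics of one full-length high-speed phantom recording
    (4800 frames, 16 fps, lights off at 30 s) with study-condition noise;
    the lateral raster is reduced to the 200 averaged A-lines plus margin."""
    from retorg.mscan import build_mscan, transition_kinetics

    proto = retorg.AcquisitionProtocol(
        alines_per_bscan=208, axial_pixels=384, recording_frames=4800, seed=3
    )
    rec = retorg.render_highspeed(model, kinetics, proto, np.random.default_rng(3))
    ms = build_mscan(rec, n_alines=200)
    return transition_kinetics(ms)
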
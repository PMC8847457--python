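"""B-scan flattening and reduction to a representative depth profile.

Quantification operates on one representative A-line per volume: repeats are
averaged, every B-scan is flattened by realigning its A-lines on the external
limiting membrane (ELM) peak, the central 150 B-scans are averaged, then the
central 200 A-lines, and the result is upsampled 4x by linear interpolation.
Intensity profiles are normalized to the mean outer-nuclear-layer (ONL)
intensity before relative band-intensity measurement.

ELM detection is template-based: each A-line is cross-correlated (normalized)
against an outer-retina template, the best lag proposes an ELM position, the
nearest local maximum is refined to sub-pixel precision with a parabolic fit,
and a lateral median filter rejects outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import DetectionError, InvalidParameterError, NormalizationError, ProtocolError
from .io import OCTVolume

__all__ = [
    "ELMTrace",
    "DepthProfile",
    "ELMTemplate",
    "elm_template",
    "detect_elm",
    "flatten",
    "representative_profile",
    "normalize_onl",
    "default_onl_span",
    "upsample_profile",
]

UPSAMPLE_FACTOR = 4


@dataclass
class ELMTrace:
    """Per-A-line sub-pixel ELM axial position (pixels) with confidence."""

    positions_px: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.positions_px.shape != self.confidence.shape:
            raise InvalidParameterError("trace and confidence shapes differ")

    @property
    def reference_px(self) -> float:
        """Default flattening reference: the median trace depth."""
        return float(np.median(self.positions_px))


@dataclass
class DepthProfile:
    """A flattened, upsampled representative A-line.

    ``pitch_um`` is the axial sample pitch of the (upsampled) grid;
    ``normalized`` is ``"raw"`` or ``"onl"``.
    """

    intensity: np.ndarray
    pitch_um: float
    normalized: str = "raw"
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise InvalidParameterError("profile intensity must be 1-D")
        if self.pitch_um <= 0:
            raise InvalidParameterError("pitch must be positive")
        if (self.intensity < 0).any():
            raise InvalidParameterError("profile intensities must be non-negative")

    @property
    def depth_um(self) -> np.ndarray:
        return np.arange(self.intensity.size) * self.pitch_um

    def at_um(self, depth_um: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of the profile at arbitrary depths."""
        return np.interp(depth_um, self.depth_um, self.intensity)


@dataclass(frozen=True)
class ELMTemplate:
    """Outer-retina intensity template with the ELM index it encodes."""

    values: np.ndarray
    elm_index_px: float
    pitch_um: float


_TEMPLATE_CACHE: dict = {}


def elm_template(
    axial_pitch_um: float = 1.25,
    model=None,
    *,
    inner_margin_um: float = 25.0,
    outer_margin_um: float = 45.0,
) -> ELMTemplate:
    """Build the default outer-retina template from a canonical noiseless
    phantom profile (ONL tail through the RPE band).

    The template is anatomy-generic: the cross-correlation stage only needs
    the characteristic ELM/ISe/RPE pattern, and the subsequent local-maximum
    refinement snaps onto the data's own ELM peak.
    """
    from . import phantom  # local import to avoid a cycle

    key = None
    if model is None:
        key = (axial_pitch_um, inner_margin_um, outer_margin_um)
        if key in _TEMPLATE_CACHE:
            return _TEMPLATE_CACHE[key]
        model = phantom.mouse_retina_model(curvature_um_per_mm2=0.0)
    n_px = int(np.ceil((model.rpe_basal_um + 30.0) / axial_pitch_um))
    z = np.arange(n_px) * axial_pitch_um
    prof = phantom._staircase_profile(model, z)
    lo = int(np.floor((model.elm_depth_um - inner_margin_um) / axial_pitch_um))
    hi = int(np.ceil((model.elm_depth_um + outer_margin_um) / axial_pitch_um))
    lo = max(lo, 0)
    tpl = ELMTemplate(
        values=prof[lo:hi],
        elm_index_px=model.elm_depth_um / axial_pitch_um - lo,
        pitch_um=axial_pitch_um,
    )
    if key is not None:
        _TEMPLATE_CACHE[key] = tpl
    return tpl


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample vertex of the parabola through (i-1, i, i+1).

    Returns (position, height); clamps the shift to half a sample so the
    refinement can never leave the discrete maximum's cell.
    """
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not a strict local max in the quadratic sense
        return float(i), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return i + delta, float(height)


def _ncc(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of each row of ``image`` (n, depth)
    against ``template`` (m,); returns (n, depth - m + 1) scores in [-1, 1]."""
    t = template - template.mean()
    t_norm = np.linalg.norm(t)
    if t_norm == 0:
        raise InvalidParameterError("template has zero variance")
    t = t / t_norm
    m = t.size
    raw = signal.fftconvolve(image, t[::-1][None, :], mode="valid", axes=1)
    ones = np.ones(m)
    s1 = signal.fftconvolve(image, ones[None, :], mode="valid", axes=1)
    s2 = signal.fftconvolve(image**2, ones[None, :], mode="valid", axes=1)
    var = np.maximum(s2 - s1**2 / m, 0.0)
    denom = np.sqrt(var)
    # windows with negligible structure (flat background) carry no match
    # information; their near-0/0 scores must not clip to +-1
    floor = 1e-3 * np.sqrt(m) * float(image.std())
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > max(floor, 1e-12), raw / denom, 0.0)
    return np.clip(ncc, -1.0, 1.0)


def detect_elm(
    bscan: np.ndarray,
    axial_pitch_um: float = 1.25,
    template: ELMTemplate | None = None,
    *,
    median_window: int = 15,
    smooth_sigma_px: float = 1.0,
    max_jump_px: float = 4.0,
    confidence_threshold: float = 0.5,
    min_confident_fraction: float = 0.5,
) -> ELMTrace:
    """Locate the ELM peak on every A-line of a B-scan.

    Parameters
    ----------
    bscan:
        (A-lines, depth) linear-intensity image.
    template:
        Outer-retina template; built from the canonical phantom when omitted.
    median_window:
        Lateral median-filter window (A-lines) for outlier rejection.
    max_jump_px:
        Positions further than this from the median-filtered trace are
        replaced by it and their confidence zeroed.

    Raises
    ------
    DetectionError
        If fewer than ``min_confident_fraction`` of A-lines reach
        ``confidence_threshold`` normalized correlation.
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2 or bscan.size == 0:
        raise InvalidParameterError("bscan must be a non-empty 2-D array")
    if template is None:
        template = elm_template(axial_pitch_um)
    smooth = ndimage.gaussian_filter1d(bscan, smooth_sigma_px, axis=1)
    scores = _ncc(smooth, template.values)
    best_lag = np.argmax(scores, axis=1)
    confidence = scores[np.arange(scores.shape[0]), best_lag]

    # parabolic sub-pixel refinement of the correlation maximum; the score
    # aggregates the whole template, so it is far less speckle-sensitive than
    # the raw intensity peak
    positions = np.empty(bscan.shape[0])
    for i in range(bscan.shape[0]):
        pos, _ = _parabolic_refine(scores[i], int(best_lag[i]))
        positions[i] = pos + template.elm_index_px

    if positions.size >= 3:
        w = min(median_window, positions.size if positions.size % 2 else positions.size - 1)
        w = max(w - (w + 1) % 2, 3)  # odd window
        med = ndimage.median_filter(positions, size=w, mode="nearest")
        outlier = np.abs(positions - med) > max_jump_px
        positions[outlier] = med[outlier]
        confidence = np.where(outlier, 0.0, confidence)

    frac = float(np.mean(confidence >= confidence_threshold))
    if frac < min_confident_fraction:
        raise DetectionError(
            f"only {frac:.0%} of A-lines yielded a confident ELM peak "
            f"(threshold {min_confident_fraction:.0%})"
        )
    return ELMTrace(positions_px=positions, confidence=confidence)


def flatten(
    bscan: np.ndarray,
    trace: ELMTrace,
    reference_px: float | None = None,
) -> np.ndarray:
    """Shift each A-line axially (sub-pixel, linear interpolation) so its ELM
    sits at ``reference_px`` (default: the median trace depth).

    Samples shifted in from outside the axial window are zero.
    """
    bscan = np.asarray(bscan, dtype=float)
    if trace.positions_px.size != bscan.shape[0]:
        raise InvalidParameterError("trace length does not match the B-scan")
    if reference_px is None:
        reference_px = trace.reference_px
    if not 0 <= reference_px <= bscan.shape[1] - 1:
        raise InvalidParameterError(
            f"reference depth {reference_px} px outside the axial window"
        )
    # output[i, z] = input[i, z - (ref - pos_i)]
    shifts = reference_px - trace.positions_px
    rows = np.arange(bscan.shape[0])[:, None]
    cols = np.arange(bscan.shape[1])[None, :] - shifts[:, None]
    return ndimage.map_coordinates(
        bscan, [np.broadcast_to(rows, cols.shape), cols],
        order=1, mode="constant", cval=0.0,
    )


def upsample_profile(values: np.ndarray, factor: int = UPSAMPLE_FACTOR) -> np.ndarray:
    """Linear-interpolation upsampling to ``factor`` x the sampling density.

    Output length is ``factor * len(values)``; the last ``factor - 1`` samples
    extrapolate by edge-holding, matching ``np.interp`` clamping.
    """
    n = values.size
    return np.interp(np.arange(factor * n) / factor, np.arange(n), values)


def representative_profile(
    volume: OCTVolume,
    *,
    n_bscans: int = 150,
    n_alines: int = 200,
    center_offset: tuple[int, int] = (0, 0),
    template: ELMTemplate | None = None,
    upsample: int = UPSAMPLE_FACTOR,
    **detect_kwargs,
) -> DepthProfile:
    """Reduce a volume to one representative, flattened, upsampled A-line.

    Pipeline: average the co-located repeats, flatten every central B-scan on
    its ELM trace (all to a volume-common reference depth), average the
    ``n_bscans`` central B-scans, average the ``n_alines`` central A-lines,
    and upsample by linear interpolation.  With the default windows a profile
    aggregates 4 x 150 x 200 = 120,000 raw A-scans.  ``center_offset`` moves
    the averaged region (in B-scan / A-line indices) to emulate
    landmark-based region selection.
    """
    if volume.n_bscans < n_bscans or volume.n_alines < n_alines:
        raise ProtocolError(
            f"representative profile needs >= {n_bscans} B-scans and "
            f">= {n_alines} A-lines; volume has {volume.n_bscans} and "
            f"{volume.n_alines}"
        )
    if template is None:
        template = elm_template(volume.axial_pitch_um)
    avg = volume.data.mean(axis=0)  # (bscan, aline, depth)

    b0 = (volume.n_bscans - n_bscans) // 2 + center_offset[0]
    a0 = (volume.n_alines - n_alines) // 2 + center_offset[1]
    if not (0 <= b0 and b0 + n_bscans <= volume.n_bscans
            and 0 <= a0 and a0 + n_alines <= volume.n_alines):
        raise ProtocolError("center_offset pushes the averaged region outside the volume")

    traces = [
        detect_elm(avg[b], volume.axial_pitch_um, template, **detect_kwargs)
        for b in range(b0, b0 + n_bscans)
    ]
    reference = float(np.median(np.concatenate([t.positions_px for t in traces])))
    acc = np.zeros(volume.n_depth)
    for t, b in zip(traces, range(b0, b0 + n_bscans)):
        flat = flatten(avg[b], t, reference_px=reference)
        acc += flat[a0:a0 + n_alines].mean(axis=0)
    mean_aline = acc / n_bscans
    return DepthProfile(
        intensity=np.maximum(upsample_profile(mean_aline, upsample), 0.0),
        pitch_um=volume.axial_pitch_um / upsample,
        normalized="raw",
        timestamp_min=volume.timestamp_min,
    )


def default_onl_span(elm_depth_um: float) -> tuple[float, float]:
    """ONL reference span used for normalization: 50 to 10 um inner of the
    ELM peak, safely inside the ONL for a mouse retina."""
    return (elm_depth_um - 50.0, elm_depth_um - 10.0)


def normalize_onl(
    profile: DepthProfile,
    onl_span_um: tuple[float, float],
    *,
    use_minimum: bool = False,
) -> DepthProfile:
    """Normalize a profile by its ONL intensity.

    The reference is the mean intensity over the central 50% of
    ``onl_span_um`` (or the minimum over that region with ``use_minimum``);
    after normalization the mean over that region is exactly 1.
    """
    lo, hi = onl_span_um
    if not (0 <= lo < hi <= profile.depth_um[-1] + profile.pitch_um):
        raise NormalizationError(
            f"ONL span ({lo}, {hi}) um outside the profile extent"
        )
    quarter = (hi - lo) / 4.0
    sel = (profile.depth_um >= lo + quarter) & (profile.depth_um <= hi - quarter)
    if not sel.any():
        raise NormalizationError("ONL span contains no profile samples")
    region = profile.intensity[sel]
    ref = float(region.min()) if use_minimum else float(region.mean())
    if ref <= 0:
        raise NormalizationError(f"non-positive ONL reference intensity ({ref})")
    return DepthProfile(
        intensity=profile.intensity / ref,
        pitch_um=profile.pitch_um,
        normalized="onl",
        timestamp_min=profile.timestamp_min,
    )
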
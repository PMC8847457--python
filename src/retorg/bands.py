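"""1-D segmentation of the representative depth profile.

Locates the hyper-reflective band peaks (NFL, IPL, OPL, ELM, ISe, RPE), the
double outer-segment-tip peaks between the ISe and RPE, and the layer
boundaries that induce the four thickness measures (inner retina, outer
retina, ONL, ELM-RPE complex).

Peaks are found on a lightly smoothed profile with a relative prominence
threshold, assigned anatomically through ordered search windows anchored at
the ELM, and refined to sub-pixel precision with a parabolic fit.  Boundary
depths use relative (half-prominence / fractional-height) criteria so they
are invariant to a global intensity gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import InvalidParameterError, SegmentationError
from .preprocess import DepthProfile, _parabolic_refine, default_onl_span, normalize_onl

__all__ = [
    "BandSet",
    "DoublePeak",
    "BoundarySet",
    "BandWindows",
    "locate_bands",
    "detect_double_peaks",
    "locate_boundaries",
    "auto_normalize",
]

MANDATORY_BANDS = ("ELM", "ISe", "RPE")


@dataclass
class BandSet:
    """Sub-pixel band-peak depths (um from the profile origin) and their
    ONL-normalized heights.  Inner-retinal bands may be absent (None) on
    cropped profiles; ELM, ISe and RPE are always present."""

    depths_um: dict
    heights: dict

    def __post_init__(self) -> None:
        for name in MANDATORY_BANDS:
            if self.depths_um.get(name) is None:
                raise SegmentationError(f"mandatory band {name} missing")
        present = [(n, d) for n, d in self.depths_um.items() if d is not None]
        order = ["NFL", "IPL", "OPL", "ELM", "ISe", "RPE"]
        seq = [d for n in order for (m, d) in present if m == n]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise SegmentationError(f"band depth ordering violated: {self.depths_um}")

    def __getitem__(self, name: str) -> float:
        d = self.depths_um.get(name)
        if d is None:
            raise KeyError(name)
        return d


@dataclass
class DoublePeak:
    """The two interdigitation-zone tip peaks along the photoreceptor OS.

    ``resolved`` is True only when two distinct maxima were found; a single
    maximum is reported as the rod tip.
    """

    cone_tip_um: float | None
    rod_tip_um: float | None
    cone_prominence: float | None
    rod_prominence: float | None
    resolved: bool


@dataclass
class BoundarySet:
    """Layer boundaries (um, sub-pixel), strictly increasing."""

    inner_surface_um: float
    opl_onl_um: float
    elm_um: float
    rpe_basal_um: float

    def __post_init__(self) -> None:
        seq = (self.inner_surface_um, self.opl_onl_um, self.elm_um, self.rpe_basal_um)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise SegmentationError(f"boundaries not strictly increasing: {seq}")


@dataclass(frozen=True)
class BandWindows:
    """Anatomical search windows, um relative to the ELM peak (mouse defaults)."""

    ise: tuple[float, float] = (2.5, 15.0)
    rpe: tuple[float, float] = (36.0, 65.0)
    opl: tuple[float, float] = (-80.0, -45.0)
    ipl: tuple[float, float] = (-125.0, -85.0)
    nfl: tuple[float, float] = (-150.0, -120.0)
    elm_from_ise: tuple[float, float] = (-15.0, -2.5)


def _smooth(profile: DepthProfile, sigma_um: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(profile.intensity, sigma_um / profile.pitch_um)


def _anchor_elm_um(profile: DepthProfile, min_confidence: float = 0.4) -> float:
    """ELM anchor on a 1-D profile via the template-correlation detector.

    Template matching keys on the whole outer-retina pattern, so the anchor
    survives reflectance changes that make individual bands atypical (e.g. a
    dimmed ISe)."""
    from .preprocess import detect_elm, elm_template

    tpl = elm_template(profile.pitch_um)
    trace = detect_elm(
        profile.intensity[None, :], profile.pitch_um, tpl,
        min_confident_fraction=0.0,
    )
    if trace.confidence[0] < min_confidence:
        raise SegmentationError(
            "no ELM band: outer-retina template does not match the profile "
            f"(correlation {trace.confidence[0]:.2f})"
        )
    return float(trace.positions_px[0]) * profile.pitch_um


def _pick(peaks_um, prominences, window, mode="prominent"):
    lo, hi = window
    cands = [(p, pr) for p, pr in zip(peaks_um, prominences) if lo <= p <= hi]
    if not cands:
        return None, None
    if mode == "innermost":
        return min(cands, key=lambda c: c[0])
    return max(cands, key=lambda c: c[1])


def locate_bands(
    profile: DepthProfile,
    *,
    smooth_sigma_um: float = 1.25,
    prominence_fraction: float = 0.1,
    windows: BandWindows = BandWindows(),
) -> BandSet:
    """Locate the hyper-reflective band peaks on an ONL-normalized profile.

    The profile is smoothed with a Gaussian of ``smooth_sigma_um`` (one
    original axial pixel by default); local maxima with prominence below
    ``prominence_fraction`` of the ISe-candidate height are discarded.  The
    ELM anchor comes from the template-correlation ELM detector applied to
    the 1-D profile; the remaining bands are assigned in ordered windows
    relative to it.  Peak depths and heights are parabolically refined
    (never by more than one sample).
    """
    if profile.normalized != "onl":
        raise InvalidParameterError("locate_bands requires an ONL-normalized profile")
    y = _smooth(profile, smooth_sigma_um)
    anchor = _anchor_elm_um(profile)
    ise_lo = int((anchor + windows.ise[0]) / profile.pitch_um)
    ise_hi = int((anchor + windows.ise[1]) / profile.pitch_um) + 1
    ise_cand_height = float(y[ise_lo:ise_hi].max())
    idx, props = signal.find_peaks(y, prominence=prominence_fraction * ise_cand_height)
    if idx.size == 0:
        raise SegmentationError("no ELM band: profile has no prominent local maxima")
    peaks_um = idx * profile.pitch_um
    proms = props["prominences"]

    elm, _ = _pick(peaks_um, proms, (anchor - 3.0, anchor + 3.0))
    if elm is None:
        raise SegmentationError("no ELM band peak near the template anchor")

    assigned: dict[str, float | None] = {}
    for name, window, mode in (
        ("ISe", windows.ise, "prominent"),
        ("RPE", windows.rpe, "prominent"),
        ("OPL", windows.opl, "prominent"),
        ("IPL", windows.ipl, "prominent"),
        ("NFL", windows.nfl, "innermost"),
    ):
        pos, _ = _pick(peaks_um, proms, (elm + window[0], elm + window[1]), mode)
        assigned[name] = pos
    assigned["ELM"] = elm
    for name in MANDATORY_BANDS:
        if assigned[name] is None:
            raise SegmentationError(f"mandatory band {name} not found")

    depths, heights = {}, {}
    for name, pos in assigned.items():
        if pos is None:
            depths[name] = None
            heights[name] = None
            continue
        i = int(round(pos / profile.pitch_um))
        sub, h = _parabolic_refine(y, i)
        depths[name] = sub * profile.pitch_um
        heights[name] = h
    return BandSet(depths_um=depths, heights=heights)


def detect_double_peaks(
    profile: DepthProfile,
    bands: BandSet,
    *,
    guard_um: float = 2.0,
    prominence_threshold: float = 0.1,
    smooth_sigma_um: float = 1.25,
) -> DoublePeak:
    """Search the open interval between the ISe and RPE peaks for the double
    outer-segment-tip maxima.

    Two maxima above the prominence threshold resolve the cone tip (shallower)
    and rod tip (deeper); a single maximum is reported as the rod tip with
    ``resolved=False``; absence is encoded, not an error.
    """
    y = _smooth(profile, smooth_sigma_um)
    lo = bands["ISe"] + guard_um
    hi = bands["RPE"] - guard_um
    sel_lo = int(np.ceil(lo / profile.pitch_um))
    sel_hi = int(np.floor(hi / profile.pitch_um))
    if sel_hi - sel_lo < 3:
        return DoublePeak(None, None, None, None, False)
    idx, props = signal.find_peaks(y[sel_lo:sel_hi + 1], prominence=prominence_threshold)
    if idx.size == 0:
        return DoublePeak(None, None, None, None, False)
    order = np.argsort(props["prominences"])[::-1][:2]
    chosen = sorted(
        ((sel_lo + idx[k], props["prominences"][k]) for k in order),
        key=lambda c: c[0],
    )
    refined = []
    for i, prom in chosen:
        pos, _ = _parabolic_refine(y, i)
        refined.append((pos * profile.pitch_um, float(prom)))
    if len(refined) == 2:
        (cd, cp), (rd, rp) = refined
        return DoublePeak(cd, rd, cp, rp, True)
    (rd, rp), = refined
    return DoublePeak(None, rd, None, rp, False)


def _falling_crossing(y: np.ndarray, start: int, stop: int, level: float,
                      pitch_um: float, what: str) -> float:
    """First sub-pixel depth in [start, stop) where ``y`` falls below ``level``."""
    for i in range(start, min(stop, y.size - 1)):
        if y[i] >= level > y[i + 1]:
            frac = (y[i] - level) / (y[i] - y[i + 1])
            return (i + frac) * pitch_um
    raise SegmentationError(f"no {what} flank crossing found in the search window")


def _rising_crossing(y: np.ndarray, level: float, pitch_um: float, what: str) -> float:
    for i in range(y.size - 1):
        if y[i] < level <= y[i + 1]:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return (i + frac) * pitch_um
    raise SegmentationError(f"no {what} rise found")


def locate_boundaries(
    profile: DepthProfile,
    bands: BandSet,
    *,
    smooth_sigma_um: float = 1.25,
    rpe_search_um: float = 25.0,
) -> BoundarySet:
    """Derive the four layer boundaries from the band peaks.

    * inner surface: first depth where the smoothed profile rises above 50%
      of the NFL peak height;
    * OPL/ONL: half-prominence crossing on the outer flank of the OPL peak
      (midpoint of the OPL peak and the ONL trough before the ELM);
    * ELM: the ELM band peak itself;
    * basal RPE: half-prominence crossing on the outer flank of the RPE peak
      (midpoint of the RPE peak and the outer trough toward the choroid).

    All criteria are relative, so a global intensity gain leaves every
    boundary unchanged.
    """
    y = _smooth(profile, smooth_sigma_um)
    pitch = profile.pitch_um
    for need in ("NFL", "OPL"):
        if bands.depths_um.get(need) is None:
            raise SegmentationError(f"boundary location requires the {need} band")

    nfl_h = bands.heights["NFL"]
    inner = _rising_crossing(y, 0.5 * nfl_h, pitch, "inner-surface")

    opl_i = int(round(bands["OPL"] / pitch))
    elm_i = int(round(bands["ELM"] / pitch))
    trough = float(y[opl_i:elm_i].min())
    level = 0.5 * (bands.heights["OPL"] + trough)
    opl_onl = _falling_crossing(y, opl_i, elm_i, level, pitch, "OPL/ONL")

    rpe_i = int(round(bands["RPE"] / pitch))
    stop = min(rpe_i + int(rpe_search_um / pitch), y.size)
    trough_r = float(y[rpe_i:stop].min())
    level_r = 0.5 * (bands.heights["RPE"] + trough_r)
    rpe_basal = _falling_crossing(y, rpe_i, stop, level_r, pitch, "basal RPE")

    return BoundarySet(
        inner_surface_um=inner,
        opl_onl_um=opl_onl,
        elm_um=bands["ELM"],
        rpe_basal_um=rpe_basal,
    )


def auto_normalize(profile: DepthProfile) -> DepthProfile:
    """Normalize a raw profile by its ONL intensity without prior knowledge.

    A coarse template-correlation pass anchors the ELM; the ONL span is then
    taken 50-10 um inner of it.  Normalization is a scalar division, so band
    positions are unaffected.
    """
    if profile.normalized == "onl":
        return profile
    return normalize_onl(profile, default_onl_span(_anchor_elm_um(profile)))
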
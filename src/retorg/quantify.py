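"""Thickness, relative-intensity, displacement and peak-distance measures.

Sign convention: displacements are relative to the light-adapted baseline and
negative values mean shortening (movement toward the ELM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bands import BandSet, BoundarySet, DoublePeak, auto_normalize, detect_double_peaks, locate_bands, locate_boundaries
from .errors import ProtocolError, SegmentationError, UndefinedFractionError
from .preprocess import DepthProfile

__all__ = [
    "ThicknessSet",
    "IntensitySet",
    "ProfileMeasurement",
    "KineticsSeries",
    "thickness_metrics",
    "relative_intensities",
    "displacement_series",
    "shortening_fraction",
    "peak_distances",
    "measure_profile",
]

INTENSITY_BANDS = ("IPL", "OPL", "ISe", "RPE")


@dataclass
class ThicknessSet:
    """The four thickness measures (um) at one timestamp.

    Shared boundary operators make them additive by construction:
    ONL + ELM-RPE = outer retina exactly.
    """

    inner_retina_um: float
    outer_retina_um: float
    onl_um: float
    elm_rpe_um: float
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.inner_retina_um, self.outer_retina_um, self.onl_um, self.elm_rpe_um)
        if any(v <= 0 for v in vals):
            raise SegmentationError(f"non-positive thickness in {vals}")
        if abs(self.onl_um + self.elm_rpe_um - self.outer_retina_um) > 0.1:
            raise SegmentationError(
                "thickness additivity violated: ONL + ELM-RPE != outer retina"
            )


@dataclass
class IntensitySet:
    """ONL-normalized peak intensities of the hyper-reflective bands."""

    ipl: float | None
    opl: float | None
    ise: float
    rpe: float
    timestamp_min: float = 0.0


def thickness_metrics(boundaries: BoundarySet, timestamp_min: float = 0.0) -> ThicknessSet:
    """Thicknesses induced by the shared boundary set.

    inner = OPL/ONL - inner surface; outer = basal RPE - OPL/ONL;
    ONL = ELM - OPL/ONL; ELM-RPE = basal RPE - ELM.
    """
    return ThicknessSet(
        inner_retina_um=boundaries.opl_onl_um - boundaries.inner_surface_um,
        outer_retina_um=boundaries.rpe_basal_um - boundaries.opl_onl_um,
        onl_um=boundaries.elm_um - boundaries.opl_onl_um,
        elm_rpe_um=boundaries.rpe_basal_um - boundaries.elm_um,
        timestamp_min=timestamp_min,
    )


def relative_intensities(
    profile: DepthProfile, bands: BandSet, timestamp_min: float | None = None
) -> IntensitySet:
    """Sub-pixel-refined peak heights of the IPL, OPL, ISe and RPE bands on an
    ONL-normalized profile (band-mean quantification is deliberately not the
    default; peak height matches the at-the-arrow reading of the bands)."""
    if profile.normalized != "onl":
        raise SegmentationError("relative intensities require an ONL-normalized profile")
    return IntensitySet(
        ipl=bands.heights.get("IPL"),
        opl=bands.heights.get("OPL"),
        ise=bands.heights["ISe"],
        rpe=bands.heights["RPE"],
        timestamp_min=profile.timestamp_min if timestamp_min is None else timestamp_min,
    )


def displacement_series(
    thicknesses: list[ThicknessSet], baseline_min: float = 0.0
) -> dict[float, float]:
    """Per-timestamp ELM-RPE displacement (um) relative to baseline.

    displacement(t) = ELM-RPE(t) - ELM-RPE(baseline); negative = shortening.
    """
    by_t = {t.timestamp_min: t for t in thicknesses}
    if baseline_min not in by_t:
        raise ProtocolError(
            f"baseline timestamp {baseline_min} min missing from series "
            f"(have {sorted(by_t)})"
        )
    base = by_t[baseline_min].elm_rpe_um
    return {t: ts.elm_rpe_um - base for t, ts in sorted(by_t.items())}


def shortening_fraction(
    elm_rpe_displacement_um: float, total_outer_displacement_um: float
) -> float:
    """Percent of the outer-retinal displacement carried by the ELM-RPE
    complex: 100 * (ELM-RPE displacement / total outer displacement)."""
    if total_outer_displacement_um == 0:
        raise UndefinedFractionError("total outer displacement is zero")
    return 100.0 * elm_rpe_displacement_um / total_outer_displacement_um


def peak_distances(
    double_peak: DoublePeak, bands: BandSet
) -> tuple[float | None, float | None]:
    """ISe-to-tip peak distances (cone, rod) in um; absent tips give None."""
    ise = bands["ISe"]
    cone = None if double_peak.cone_tip_um is None else double_peak.cone_tip_um - ise
    rod = None if double_peak.rod_tip_um is None else double_peak.rod_tip_um - ise
    return cone, rod


@dataclass
class ProfileMeasurement:
    """Everything measured on one representative profile."""

    bands: BandSet
    boundaries: BoundarySet
    thickness: ThicknessSet
    intensity: IntensitySet
    double_peak: DoublePeak
    cone_distance_um: float | None
    rod_distance_um: float | None
    timestamp_min: float


def measure_profile(profile: DepthProfile, **band_kwargs) -> ProfileMeasurement:
    """Run the full 1-D quantification on a (raw or normalized) profile."""
    norm = auto_normalize(profile)
    bands = locate_bands(norm, **band_kwargs)
    boundaries = locate_boundaries(norm, bands)
    thick = thickness_metrics(boundaries, timestamp_min=profile.timestamp_min)
    inten = relative_intensities(norm, bands)
    dp = detect_double_peaks(norm, bands)
    cone, rod = peak_distances(dp, bands)
    return ProfileMeasurement(
        bands=bands,
        boundaries=boundaries,
        thickness=thick,
        intensity=inten,
        double_peak=dp,
        cone_distance_um=cone,
        rod_distance_um=rod,
        timestamp_min=profile.timestamp_min,
    )


@dataclass
class KineticsSeries:
    """Per-timestamp measurements for one subject (eye)."""

    subject: str
    measurements: list[ProfileMeasurement]

    def to_frame(self) -> pd.DataFrame:
        """One row per timestamp with all thicknesses, intensities and the
        ELM-RPE displacement relative to the earliest timestamp."""
        thicknesses = [m.thickness for m in self.measurements]
        baseline = min(t.timestamp_min for t in thicknesses)
        disp = displacement_series(thicknesses, baseline_min=baseline)
        rows = []
        for m in self.measurements:
            rows.append({
                "subject": self.subject,
                "timestamp_min": m.timestamp_min,
                "inner_retina_um": m.thickness.inner_retina_um,
                "outer_retina_um": m.thickness.outer_retina_um,
                "onl_um": m.thickness.onl_um,
                "elm_rpe_um": m.thickness.elm_rpe_um,
                "elm_rpe_displacement_um": disp[m.timestamp_min],
                "ipl_intensity": m.intensity.ipl,
                "opl_intensity": m.intensity.opl,
                "ise_intensity": m.intensity.ise,
                "rpe_intensity": m.intensity.rpe,
                "cone_distance_um": m.cone_distance_um,
                "rod_distance_um": m.rod_distance_um,
                "double_peak_resolved": m.double_peak.resolved,
            })
        return pd.DataFrame(rows).sort_values("timestamp_min").reset_index(drop=True)
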
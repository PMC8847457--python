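"""Spatiotemporal M-scan construction and transition kinetics.

A high-speed fixed-plane recording (4800 frames at 16 fps by default) is
reduced to an M-scan: every 16 frames are averaged into one column (1 s),
each averaged frame is flattened on its ELM trace, the central A-lines are
averaged, upsampled 4x, and all columns are aligned so the ELM peak sits at a
common row.  Each column is then normalized by its own ONL intensity.

Transition kinetics re-locate the ISe peak and the basal RPE in every column
(windows seeded by the baseline band set), express the ELM-RPE distance as a
displacement relative to the pre-lights-off mean, and summarize the
post-lights-off trend with least-squares line fits and Pearson correlations
(time vs ISe intensity, time vs displacement, ISe vs displacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .bands import BandSet, locate_bands, _smooth, _falling_crossing
from .errors import AggregationError, InvalidParameterError, KineticsError, ProtocolError
from .io import HighSpeedRecording
from .preprocess import (
    DepthProfile,
    ELMTemplate,
    UPSAMPLE_FACTOR,
    _parabolic_refine,
    default_onl_span,
    detect_elm,
    elm_template,
    flatten,
    upsample_profile,
)

__all__ = ["MScan", "TransitionKinetics", "build_mscan", "transition_kinetics", "aggregate_mscans"]


@dataclass
class MScan:
    """Depth x time matrix of ONL-normalized intensity.

    Each column is one block-averaged, flattened, laterally averaged A-line on
    the 4x-upsampled axial grid, with the ELM at row ``elm_row``.
    """

    data: np.ndarray
    column_period_s: float
    lights_off_col: int
    pitch_um: float
    elm_row: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("M-scan data must be 2-D (depth, columns)")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def column_profile(self, j: int) -> DepthProfile:
        return DepthProfile(
            intensity=np.maximum(self.data[:, j], 0.0),
            pitch_um=self.pitch_um,
            normalized="onl",
            timestamp_min=(j + 0.5) * self.column_period_s / 60.0,
        )

    def column_times_s(self) -> np.ndarray:
        """Column-centre acquisition times in seconds."""
        return (np.arange(self.n_columns) + 0.5) * self.column_period_s


def _column_elm(col: np.ndarray, pitch_um: float) -> float:
    """ELM peak (samples) on one high-SNR column: the most prominent local
    maximum 2.5-15 um inner of the global maximum (the ISe)."""
    y = ndimage.gaussian_filter1d(col, 1.25 / pitch_um)
    idx, props = signal.find_peaks(y, prominence=0.05 * float(y.max()))
    if idx.size == 0:
        raise KineticsError("column has no prominent maxima")
    ise = idx[np.argmax(y[idx])]
    lo = ise - 15.0 / pitch_um
    hi = ise - 2.5 / pitch_um
    cands = [(i, p) for i, p in zip(idx, props["prominences"]) if lo <= i <= hi]
    if not cands:
        raise KineticsError("column ELM anchor not found")
    best = max(cands, key=lambda c: c[1])[0]
    pos, _ = _parabolic_refine(y, int(best))
    return pos


def build_mscan(
    recording: HighSpeedRecording,
    *,
    block_size: int = 16,
    n_alines: int = 200,
    upsample: int = UPSAMPLE_FACTOR,
    template: ELMTemplate | None = None,
    **detect_kwargs,
) -> MScan:
    """Build the spatiotemporal M-scan from a high-speed recording.

    ``floor(frames / block_size)`` columns are produced; a trailing partial
    block is dropped with a warning.  With the default 4800-frame, 16 fps
    protocol this yields 300 one-second columns and the 30 s lights-off falls
    at column index 30.
    """
    if recording.n_frames < block_size:
        raise ProtocolError(
            f"recording has {recording.n_frames} frames, need >= {block_size}"
        )
    n_cols = recording.n_frames // block_size
    dropped = recording.n_frames - n_cols * block_size
    if dropped:
        warnings.warn(
            f"dropping trailing partial block of {dropped} frames", stacklevel=2
        )
    if recording.data.shape[1] < n_alines:
        raise ProtocolError(
            f"recording has {recording.data.shape[1]} A-lines, need >= {n_alines}"
        )
    if template is None:
        template = elm_template(recording.axial_pitch_um)
    a0 = (recording.data.shape[1] - n_alines) // 2
    pitch_up = recording.axial_pitch_um / upsample

    cols = np.empty((recording.data.shape[2] * upsample, n_cols))
    for j in range(n_cols):
        frame = recording.data[j * block_size:(j + 1) * block_size].mean(axis=0)
        trace = detect_elm(frame, recording.axial_pitch_um, template, **detect_kwargs)
        flat = flatten(frame, trace)
        aline = flat[a0:a0 + n_alines].mean(axis=0)
        cols[:, j] = upsample_profile(aline, upsample)

    # align all columns to a common ELM row, then normalize by the ONL
    elms = np.array([_column_elm(cols[:, j], pitch_up) for j in range(n_cols)])
    ref = float(np.median(elms))
    rows = np.arange(cols.shape[0])
    for j in range(n_cols):
        cols[:, j] = np.interp(rows + (elms[j] - ref), rows, cols[:, j],
                               left=0.0, right=0.0)
        lo, hi = default_onl_span(ref * pitch_up)
        quarter = (hi - lo) / 4.0
        sel = slice(int((lo + quarter) / pitch_up), int((hi - quarter) / pitch_up) + 1)
        cols[:, j] /= cols[sel, j].mean()

    period = block_size / recording.frame_rate_hz
    return MScan(
        data=cols,
        column_period_s=period,
        lights_off_col=int(round(recording.lights_off_s / period)),
        pitch_um=pitch_up,
        elm_row=ref,
    )


@dataclass
class TransitionKinetics:
    """Per-column kinetics and their post-lights-off trend summaries."""

    time_s: np.ndarray
    ise_intensity: np.ndarray
    elm_rpe_um: np.ndarray
    displacement_um: np.ndarray
    lights_off_col: int
    ise_slope_per_min: float
    ise_intercept: float
    displacement_slope_um_per_min: float
    displacement_intercept_um: float
    r_time_ise: float
    p_time_ise: float
    r_time_displacement: float
    p_time_displacement: float
    r_ise_displacement: float
    p_ise_displacement: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(self.time_s.size),
            "time_s": self.time_s,
            "ise_intensity": self.ise_intensity,
            "elm_rpe_um": self.elm_rpe_um,
            "displacement_um": self.displacement_um,
        })


def transition_kinetics(
    mscan: MScan,
    baseline_bands: BandSet | None = None,
    *,
    ise_window_um: float = 4.0,
    rpe_window_um: float = 6.0,
    smooth_sigma_um: float = 2.5,
    max_lost_fraction: float = 0.2,
) -> TransitionKinetics:
    """Extract ISe-intensity and ELM-RPE displacement kinetics from an M-scan.

    Band positions are re-located per column inside windows seeded by the
    baseline band set (the mean of the pre-lights-off columns when not
    supplied), which keeps the tracking robust to residual axial drift.
    Per-column profiles are smoothed with ``smooth_sigma_um`` (wider than the
    volume-profile default because a single column averages ~40x fewer
    A-scans than a volume profile).
    Trend statistics (Pearson and least-squares fits, time in minutes since
    lights off) are computed over post-lights-off columns only; the
    pre-period defines the displacement reference.
    """
    n_post = mscan.n_columns - mscan.lights_off_col
    if n_post < 2:
        raise ProtocolError("need at least 2 post-lights-off columns")
    if baseline_bands is None:
        pre = mscan.data[:, :max(mscan.lights_off_col, 1)].mean(axis=1)
        base_profile = DepthProfile(np.maximum(pre, 0.0), mscan.pitch_um, "onl")
        baseline_bands = locate_bands(base_profile)

    pitch = mscan.pitch_um
    ise0 = baseline_bands["ISe"]
    rpe0 = baseline_bands["RPE"]
    elm0 = baseline_bands["ELM"]

    ise_int = np.full(mscan.n_columns, np.nan)
    elm_rpe = np.full(mscan.n_columns, np.nan)
    for j in range(mscan.n_columns):
        y = _smooth(mscan.column_profile(j), smooth_sigma_um)
        try:
            # ELM: parabolic peak at the aligned reference row
            e_lo = int((elm0 - 2.0) / pitch)
            e_hi = int((elm0 + 2.0) / pitch) + 1
            ei = e_lo + int(np.argmax(y[e_lo:e_hi]))
            elm_pos, _ = _parabolic_refine(y, ei)

            i_lo = int((ise0 - ise_window_um) / pitch)
            i_hi = int((ise0 + ise_window_um) / pitch) + 1
            ii = i_lo + int(np.argmax(y[i_lo:i_hi]))
            ise_pos, ise_h = _parabolic_refine(y, ii)

            r_lo = int((rpe0 - rpe_window_um) / pitch)
            r_hi = int((rpe0 + rpe_window_um) / pitch) + 1
            ri = r_lo + int(np.argmax(y[r_lo:r_hi]))
            trough = float(y[ri:ri + int(25.0 / pitch)].min())
            level = 0.5 * (float(y[ri]) + trough)
            basal = _falling_crossing(y, ri, ri + int(25.0 / pitch), level, pitch,
                                      "basal RPE")
        except Exception:
            continue
        ise_int[j] = ise_h
        elm_rpe[j] = basal - elm_pos * pitch

    lost = np.isnan(ise_int).mean()
    if lost > max_lost_fraction:
        raise KineticsError(
            f"band tracking failed in {lost:.0%} of columns (> {max_lost_fraction:.0%})"
        )

    off = mscan.lights_off_col
    pre_mean = np.nanmean(elm_rpe[:off]) if off > 0 else elm_rpe[~np.isnan(elm_rpe)][0]
    disp = elm_rpe - pre_mean

    t_s = mscan.column_times_s()
    post = np.arange(off, mscan.n_columns)
    ok = post[~np.isnan(ise_int[post]) & ~np.isnan(disp[post])]
    t_min = (t_s[ok] - off * mscan.column_period_s) / 60.0
    r1, p1 = stats.pearsonr(t_min, ise_int[ok])
    r2, p2 = stats.pearsonr(t_min, disp[ok])
    r3, p3 = stats.pearsonr(ise_int[ok], disp[ok])
    ise_fit = np.polyfit(t_min, ise_int[ok], 1)
    disp_fit = np.polyfit(t_min, disp[ok], 1)

    return TransitionKinetics(
        time_s=t_s,
        ise_intensity=ise_int,
        elm_rpe_um=elm_rpe,
        displacement_um=disp,
        lights_off_col=off,
        ise_slope_per_min=float(ise_fit[0]),
        ise_intercept=float(ise_fit[1]),
        displacement_slope_um_per_min=float(disp_fit[0]),
        displacement_intercept_um=float(disp_fit[1]),
        r_time_ise=float(r1), p_time_ise=float(p1),
        r_time_displacement=float(r2), p_time_displacement=float(p2),
        r_ise_displacement=float(r3), p_ise_displacement=float(p3),
    )


def aggregate_mscans(mscans: list[MScan]) -> MScan:
    """Element-wise mean of M-scans after common ELM alignment.

    All inputs must share the grid shape, column period, axial pitch and
    lights-off column; each M-scan is shifted axially so its ELM row matches
    the first one's before averaging.
    """
    if not mscans:
        raise AggregationError("no M-scans to aggregate")
    first = mscans[0]
    acc = np.zeros_like(first.data)
    rows = np.arange(first.data.shape[0])
    for m in mscans:
        if (m.data.shape != first.data.shape
                or m.column_period_s != first.column_period_s
                or m.lights_off_col != first.lights_off_col
                or m.pitch_um != first.pitch_um):
            raise AggregationError("M-scan grids do not match")
        shift = m.elm_row - first.elm_row
        if shift == 0.0:
            acc += m.data
        else:
            for j in range(m.n_columns):
                acc[:, j] += np.interp(rows + shift, rows, m.data[:, j],
                                       left=0.0, right=0.0)
    return MScan(
        data=acc / len(mscans),
        column_period_s=first.column_period_s,
        lights_off_col=first.lights_off_col,
        pitch_um=first.pitch_um,
        elm_row=first.elm_row,
    )
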
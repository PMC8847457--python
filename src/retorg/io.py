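"""On-disk format for OCT volumes and high-speed recordings.

Data are stored as multi-page 32-bit float TIFF stacks plus a JSON metadata
sidecar (``<stem>.tiff`` / ``<stem>.meta.json``).  Volume pages are
repeat-major (page ``r * n_bscans + b`` is B-scan ``b`` of repeat ``r``);
recording pages are frames.  Each page is written as a depth x A-line image so
standard viewers display B-scans in the usual orientation.  Reads validate the
array shape against the sidecar and reject NaNs and negative intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, InvalidParameterError

__all__ = [
    "OCTVolume",
    "HighSpeedRecording",
    "write_volume",
    "read_volume",
    "write_recording",
    "read_recording",
]

_FORMAT_VERSION = 1


def _validate_intensities(data: np.ndarray, what: str) -> None:
    if np.isnan(data).any():
        raise FormatError(f"{what} contains NaN intensities")
    if (data < 0).any():
        raise FormatError(f"{what} contains negative intensities")


@dataclass
class OCTVolume:
    """A (possibly simulated) volumetric acquisition.

    ``data`` has shape (repeat, B-scan, A-line, depth) in non-negative linear
    intensity units.
    """

    data: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float
    timestamp_min: float = 0.0
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise InvalidParameterError(
                f"volume data must be 4-D (repeat, bscan, aline, depth), got "
                f"shape {self.data.shape}"
            )
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise InvalidParameterError("pixel pitches must be positive")
        _validate_intensities(self.data, "volume")

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    @property
    def n_bscans(self) -> int:
        return self.data.shape[1]

    @property
    def n_alines(self) -> int:
        return self.data.shape[2]

    @property
    def n_depth(self) -> int:
        return self.data.shape[3]


@dataclass
class HighSpeedRecording:
    """Fixed-plane B-scan recording: ``data`` is (frame, A-line, depth)."""

    data: np.ndarray
    frame_rate_hz: float
    lights_off_s: float = 30.0
    axial_pitch_um: float = 1.25
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise InvalidParameterError(
                f"recording data must be 3-D (frame, aline, depth), got shape "
                f"{self.data.shape}"
            )
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame rate must be positive")
        if not 0.0 <= self.lights_off_s <= self.duration_s:
            raise InvalidParameterError(
                f"lights-off time {self.lights_off_s} s outside the recording "
                f"duration [0, {self.duration_s}] s"
            )
        _validate_intensities(self.data, "recording")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.frame_rate_hz

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in (".tiff", ".tif") else p
    return stem.with_suffix(".tiff"), stem.with_name(stem.name + ".meta.json")


def write_volume(volume: OCTVolume, path: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tiff`` + ``<stem>.meta.json``; returns both paths.

    TIFF pages are repeat-major B-scans, each stored depth x A-line.
    """
    tiff_path, meta_path = _paths(path)
    r, b, a, d = volume.data.shape
    pages = volume.data.reshape(r * b, a, d).transpose(0, 2, 1)
    tifffile.imwrite(tiff_path, np.ascontiguousarray(pages, dtype=np.float32))
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": "oct_volume",
        "shape": [r, b, a, d],
        "page_order": "repeat-major",
        "axial_pitch_um": volume.axial_pitch_um,
        "lateral_pitch_um": volume.lateral_pitch_um,
        "timestamp_min": volume.timestamp_min,
        "seed": volume.seed,
        "provenance": volume.provenance,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return tiff_path, meta_path


def _read_pages(path: str | Path, kind: str) -> tuple[np.ndarray, dict]:
    tiff_path, meta_path = _paths(path)
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("kind") != kind:
        raise FormatError(f"{meta_path} declares kind {meta.get('kind')!r}, expected {kind!r}")
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    return pages, meta


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`, validating its shape."""
    pages, meta = _read_pages(path, "oct_volume")
    r, b, a, d = meta["shape"]
    if pages.shape != (r * b, d, a):
        raise FormatError(
            f"TIFF holds {pages.shape[0]} pages of {pages.shape[1:]}, sidecar "
            f"declares {r} x {b} B-scans of depth {d} x {a} A-lines"
        )
    data = pages.transpose(0, 2, 1).reshape(r, b, a, d)
    return OCTVolume(
        data=data,
        axial_pitch_um=meta["axial_pitch_um"],
        lateral_pitch_um=meta["lateral_pitch_um"],
        timestamp_min=meta["timestamp_min"],
        seed=meta.get("seed"),
        provenance=meta.get("provenance", ""),
    )


def write_recording(rec: HighSpeedRecording, path: str | Path) -> tuple[Path, Path]:
    """Write a high-speed recording; TIFF pages are frames (depth x A-line)."""
    tiff_path, meta_path = _paths(path)
    pages = rec.data.transpose(0, 2, 1)
    tifffile.imwrite(tiff_path, np.ascontiguousarray(pages, dtype=np.float32))
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": "highspeed_recording",
        "shape": list(rec.data.shape),
        "frame_rate_hz": rec.frame_rate_hz,
        "lights_off_s": rec.lights_off_s,
        "axial_pitch_um": rec.axial_pitch_um,
        "seed": rec.seed,
        "provenance": rec.provenance,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return tiff_path, meta_path


def read_recording(path: str | Path) -> HighSpeedRecording:
    pages, meta = _read_pages(path, "highspeed_recording")
    f, a, d = meta["shape"]
    if pages.shape != (f, d, a):
        raise FormatError(
            f"TIFF holds {pages.shape[0]} pages of {pages.shape[1:]}, sidecar "
            f"declares {f} frames of depth {d} x {a} A-lines"
        )
    return HighSpeedRecording(
        data=pages.transpose(0, 2, 1),
        frame_rate_hz=meta["frame_rate_hz"],
        lights_off_s=meta["lights_off_s"],
        axial_pitch_um=meta["axial_pitch_um"],
        seed=meta.get("seed"),
        provenance=meta.get("provenance", ""),
    )
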
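"""Core data containers and readers/writers for THG acquisitions.

The acquisition pipeline saves each scanned frame as an 8-bit grayscale
bitmap; frames are assembled into z-stacks and time-lapse 4D stacks and
carried through the analysis as :class:`VolumeStack` objects together with
their physical geometry (field of view, pixel grid, axial step, frame
period).  TIFF is used as the interchange format for processed stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "AcquisitionGeometry",
    "VolumeStack",
    "ProbabilityMap",
    "DimensionError",
    "FormatError",
    "read_bmp_sequence",
    "write_bmp_sequence",
    "normalize_histogram",
    "write_tiff_stack",
    "read_tiff_stack",
]

#: the scanning stage cannot step finer than this along z
MIN_STAGE_STEP_UM = 0.2


class DimensionError(ValueError):
    """Raised when image dimensions are inconsistent."""


class FormatError(ValueError):
    """Raised when a file is not in the expected pixel format."""


def _pair(value) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    y, x = value
    return (float(y), float(x))


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical geometry of a raster-scanned THG acquisition.

    Parameters
    ----------
    fov_um:
        Lateral field of view in micrometres, scalar or ``(y, x)``.
    grid_px:
        Lateral pixel counts, scalar or ``(ny, nx)``.
    z_step_um:
        Axial spacing between planes of a z-stack (µm).
    frame_period_s:
        Seconds per scanned frame.
    """

    fov_um: tuple[float, float]
    grid_px: tuple[int, int]
    z_step_um: float
    frame_period_s: float = 1.8

    def __post_init__(self):
        object.__setattr__(self, "fov_um", _pair(self.fov_um))
        gy, gx = _pair(self.grid_px)
        object.__setattr__(self, "grid_px", (int(gy), int(gx)))
        if min(self.fov_um) <= 0 or min(self.grid_px) <= 0:
            raise ValueError("fov_um and grid_px must be strictly positive")
        if self.z_step_um <= 0 or self.frame_period_s <= 0:
            raise ValueError("z_step_um and frame_period_s must be strictly positive")
        if self.z_step_um < MIN_STAGE_STEP_UM:
            warnings.warn(
                f"z_step_um={self.z_step_um} is below the stage minimum of "
                f"{MIN_STAGE_STEP_UM} µm",
                stacklevel=2,
            )

    @property
    def pixel_size_um(self) -> tuple[float, float]:
        """Lateral sampling (µm/px) per axis, derived as fov / grid."""
        return (self.fov_um[0] / self.grid_px[0], self.fov_um[1] / self.grid_px[1])

    @property
    def voxel_volume_um3(self) -> float:
        py, px = self.pixel_size_um
        return py * px * self.z_step_um

    def imaged_volume_mm3(self, n_z: int) -> float:
        """Volume of an ``n_z``-plane stack in mm³ (fov_y × fov_x × n_z·Δz)."""
        if n_z < 1:
            raise ValueError("n_z must be >= 1")
        vol_um3 = self.fov_um[0] * self.fov_um[1] * n_z * self.z_step_um
        return vol_um3 * 1e-9

    def to_dict(self) -> dict:
        return {
            "fov_um": list(self.fov_um),
            "grid_px": list(self.grid_px),
            "z_step_um": self.z_step_um,
            "frame_period_s": self.frame_period_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            fov_um=tuple(d["fov_um"]),
            grid_px=tuple(d["grid_px"]),
            z_step_um=d["z_step_um"],
            frame_period_s=d.get("frame_period_s", 1.8),
        )


@dataclass
class VolumeStack:
    """4D intensity data ordered (t, z, y, x) with physical geometry.

    Intensities are either 8-bit unsigned integers (raw acquisitions) or
    floating point in [0, 1] (processed data).  ``timestamps_min`` gives the
    acquisition time of each timepoint in minutes and must be strictly
    increasing.
    """

    voxels: np.ndarray
    geometry: AcquisitionGeometry
    timestamps_min: np.ndarray = field(default=None)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise DimensionError(
                f"voxels must be 4D (t, z, y, x); got shape {self.voxels.shape}"
            )
        if self.timestamps_min is None:
            self.timestamps_min = np.arange(self.voxels.shape[0], dtype=float)
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if len(self.timestamps_min) != self.voxels.shape[0]:
            raise DimensionError("one timestamp per timepoint required")
        if len(self.timestamps_min) > 1 and np.any(np.diff(self.timestamps_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.is_8bit:
            pass
        elif np.issubdtype(self.voxels.dtype, np.floating):
            vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
            if vmin < -1e-9 or vmax > 1 + 1e-9:
                raise ValueError(
                    f"float intensities must lie in [0, 1]; got [{vmin}, {vmax}]"
                )
        else:
            raise FormatError(f"unsupported dtype {self.voxels.dtype}")

    @property
    def is_8bit(self) -> bool:
        return self.voxels.dtype == np.uint8

    @property
    def n_t(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    def with_voxels(self, voxels: np.ndarray) -> "VolumeStack":
        """Copy of this stack with new voxel data on the same grid."""
        return VolumeStack(voxels, self.geometry, self.timestamps_min.copy())


@dataclass
class ProbabilityMap:
    """Per-voxel class probability on the grid of one (z, y, x) volume."""

    values: np.ndarray
    class_name: str = "non-myelin"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError("probability map must be 3D (z, y, x)")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# BMP frame sequences


def read_bmp_sequence(
    paths: Sequence,
    geometry: AcquisitionGeometry,
    layout: str = "z",
    timestamps_min=None,
) -> VolumeStack:
    """Read an ordered sequence of 8-bit grayscale BMP frames into a stack.

    ``layout`` places the file index on the axial axis (``"z"``, a single
    z-stack) or the time axis (``"t"``, a single-plane time lapse).
    Intensities are preserved bit-exactly.
    """
    if layout not in ("z", "t"):
        raise ValueError("layout must be 'z' or 't'")
    frames = []
    for p in paths:
        img = iio.imread(Path(p))
        if img.ndim != 2:
            raise FormatError(f"{p}: expected 8-bit grayscale, got shape {img.shape}")
        if img.dtype != np.uint8:
            raise FormatError(f"{p}: expected uint8 pixels, got {img.dtype}")
        if frames and img.shape != frames[0].shape:
            raise DimensionError(
                f"{p}: frame shape {img.shape} differs from {frames[0].shape}"
            )
        frames.append(img)
    if not frames:
        raise ValueError("empty file list")
    data = np.stack(frames)
    if layout == "z":
        data = data[np.newaxis]  # (1, n, y, x)
    else:
        data = data[:, np.newaxis]  # (n, 1, y, x)
    return VolumeStack(data, geometry, timestamps_min)


def write_bmp_sequence(stack: VolumeStack, directory, prefix: str = "frame") -> list:
    """Write every (t, z) plane of an 8-bit stack as a grayscale BMP.

    Returns the written paths ordered t-major, matching raster acquisition
    order.
    """
    if not stack.is_8bit:
        raise FormatError("BMP output requires an 8-bit stack")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(stack.n_t):
        for z in range(stack.n_z):
            p = directory / f"{prefix}_t{t:04d}_z{z:04d}.bmp"
            iio.imwrite(p, stack.voxels[t, z])
            paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Histogram normalization


def normalize_histogram(stack: VolumeStack) -> VolumeStack:
    """Per-frame linear stretch of [min, max] onto the full 8-bit range.

    Each 2D frame is rescaled independently, mirroring the automatic
    normalization applied to raw bitmaps before TIFF conversion.  Rounding is
    half-to-even; a constant frame maps to 0.
    """
    if not stack.is_8bit:
        raise FormatError("histogram normalization expects 8-bit input")
    out = np.empty_like(stack.voxels)
    for t in range(stack.n_t):
        for z in range(stack.n_z):
            frame = stack.voxels[t, z].astype(np.float64)
            lo, hi = frame.min(), frame.max()
            if hi == lo:
                out[t, z] = 0
            else:
                out[t, z] = np.rint((frame - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return stack.with_voxels(out)


# ---------------------------------------------------------------------------
# TIFF stacks

_TIFF_META_KEY = "thgswell"


def write_tiff_stack(stack: VolumeStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF (one page per (t, z) plane).

    Geometry and timestamps are embedded as JSON in the image description so
    the round trip through :func:`read_tiff_stack` is lossless.
    """
    meta = {
        "axes": "TZYX",
        "shape": list(stack.voxels.shape),
        "geometry": stack.geometry.to_dict(),
        "timestamps_min": [float(v) for v in stack.timestamps_min],
    }
    data = stack.voxels
    if not stack.is_8bit:
        data = data.astype(np.float32)
    pages = data.reshape(-1, *data.shape[2:])
    tifffile.imwrite(
        Path(path),
        pages,
        photometric="minisblack",
        metadata={_TIFF_META_KEY: meta},
    )


def read_tiff_stack(path) -> VolumeStack:
    """Read a TIFF written by :func:`write_tiff_stack` back into a stack."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            shaped = tif.shaped_metadata
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    try:
        meta = shaped[0][_TIFF_META_KEY]
    except (IndexError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing stack metadata") from exc
    shape = tuple(meta["shape"])
    voxels = np.asarray(data).reshape(shape)
    if voxels.dtype != np.uint8:
        voxels = voxels.astype(np.float64)
    geometry = AcquisitionGeometry.from_dict(meta["geometry"])
    return VolumeStack(voxels, geometry, np.asarray(meta["timestamps_min"]))
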
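"""Pre-detection image chain for THG time-lapse stacks.

Order of operations mirrors the acquisition workflow: drift registration of
the time lapse, selection of analysis timepoints, intensity inversion (so
non-myelin structures become bright), per-slice median filtering (radius
2 px), and contrast-limited adaptive histogram equalization (CLAHE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .io import VolumeStack

__all__ = [
    "RegistrationResult",
    "register_timelapse",
    "select_timepoints",
    "invert",
    "median_filter_2px",
    "clahe",
    "DEFAULT_TIMEPOINT_TARGETS_MIN",
]

logger = logging.getLogger(__name__)

#: analysis timepoints (minutes): late baseline, post first and second
#: sodium step, end of acquisition
DEFAULT_TIMEPOINT_TARGETS_MIN = (30.0, 90.0, 150.0, 160.0)


@dataclass
class RegistrationResult:
    """Per-timepoint lateral shifts (y, x, px) and the corrected stack."""

    shifts_px: np.ndarray  # (n_t, 2), shift of each timepoint relative to t=0
    registered: VolumeStack


def register_timelapse(stack: VolumeStack, upsample_factor: int = 10) -> RegistrationResult:
    """Estimate and correct lateral drift against the first timepoint.

    Translation is estimated by phase correlation of maximum-intensity
    z-projections against timepoint 0, refined to sub-pixel precision by
    local Fourier upsampling, and corrected by sub-pixel interpolation with
    replicated edges.  A zero-variance frame gets shift (0, 0) with a
    warning.
    """
    data = stack.voxels.astype(np.float32)
    n_t = stack.n_t
    shifts = np.zeros((n_t, 2))
    ref = data[0].max(axis=0)
    registered = np.empty_like(data)
    registered[0] = data[0]
    for t in range(1, n_t):
        mov = data[t].max(axis=0)
        if ref.std() == 0 or mov.std() == 0:
            logger.warning("constant frame at t=%d; assuming zero drift", t)
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(
                ref, mov, upsample_factor=upsample_factor
            )
        shifts[t] = -shift  # drift of the frame; correction applies +shift
        for z in range(stack.n_z):
            registered[t, z] = ndi.shift(
                data[t, z], shift, order=1, mode="nearest"
            )
    if stack.is_8bit:
        registered = np.clip(np.rint(registered), 0, 255).astype(np.uint8)
    out = VolumeStack(registered, stack.geometry, stack.timestamps_min.copy())
    return RegistrationResult(shifts_px=shifts, registered=out)


def select_timepoints(
    timestamps_min,
    targets_min=DEFAULT_TIMEPOINT_TARGETS_MIN,
) -> list[int]:
    """Index of the closest available timestamp for each analysis target.

    Ties break toward the earlier timestamp; duplicate selections are
    permitted (logged).
    """
    ts = np.asarray(list(timestamps_min), dtype=float)
    if ts.size == 0:
        raise ValueError("timestamps must be non-empty")
    indices = [int(np.argmin(np.abs(ts - target))) for target in targets_min]
    if len(set(indices)) < len(indices):
        logger.info("duplicate timepoint selections: %s", indices)
    return indices


def invert(volume: np.ndarray) -> np.ndarray:
    """Invert intensities to highlight non-myelin: 255−v (8-bit) or 1−v (float)."""
    volume = np.asarray(volume)
    if volume.dtype == np.uint8:
        return (255 - volume.astype(np.int16)).astype(np.uint8)
    return 1.0 - volume


def median_filter_2px(volume: np.ndarray, footprint_3d: bool = False) -> np.ndarray:
    """Median filter with a radius-2 disk, per z-slice, reflected borders.

    ``footprint_3d`` switches to a radius-2 ball applied in 3D.
    """
    volume = np.asarray(volume)
    if volume.shape[-2] < 5 or volume.shape[-1] < 5:
        raise ValueError("volume must have at least 5×5 lateral extent")
    if footprint_3d:
        from skimage.morphology import ball

        return ndi.median_filter(volume, footprint=ball(2), mode="reflect")
    footprint = disk(2)[np.newaxis]
    return ndi.median_filter(volume, footprint=footprint, mode="reflect")


# ---------------------------------------------------------------------------
# CLAHE


def clahe(
    volume: np.ndarray,
    tile_px: int = 64,
    clip_limit: float = 0.01,
    nbins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, per z-slice.

    Each slice is divided into ``tile_px`` × ``tile_px`` tiles; per-tile
    histograms (``nbins`` bins over the declared input range) are clipped at
    ``clip_limit`` × (tile pixel count / bin count) with the excess
    redistributed uniformly, turned into equalization mappings, and blended
    by bilinear interpolation between tile centers.  Output is rescaled to
    the input's declared range and dtype.

    A tile larger than the slice falls back to a single global clipped
    equalization (warning logged).
    """
    if tile_px < 8:
        raise ValueError("tile_px must be >= 8")
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must lie in (0, 1]")
    volume = np.asarray(volume)
    is_8bit = volume.dtype == np.uint8
    vmax = 255.0 if is_8bit else 1.0
    work = volume.astype(np.float64) / vmax
    out = np.empty_like(work)
    if volume.ndim == 2:
        out = _clahe_slice(work, tile_px, clip_limit, nbins)
    else:
        for z in range(work.shape[0]):
            out[z] = _clahe_slice(work[z], tile_px, clip_limit, nbins)
    out = np.clip(out, 0.0, 1.0)
    if is_8bit:
        return np.rint(out * 255.0).astype(np.uint8)
    return out


def _tile_mapping(tile: np.ndarray, clip_limit: float, nbins: int) -> np.ndarray:
    """Clipped-histogram equalization mapping (bin index -> [0, 1])."""
    hist, _ = np.histogram(tile, bins=nbins, range=(0.0, 1.0))
    clip = max(clip_limit * tile.size / nbins, 1.0)
    excess = np.sum(np.maximum(hist - clip, 0))
    hist = np.minimum(hist, clip) + excess / nbins
    cdf = np.cumsum(hist)
    cdf = cdf / cdf[-1]
    return cdf


def _clahe_slice(img: np.ndarray, tile_px: int, clip_limit: float, nbins: int):
    h, w = img.shape
    if img.max() == img.min():
        return img.copy()
    bin_idx = np.minimum((img * nbins).astype(np.intp), nbins - 1)
    if tile_px > h or tile_px > w:
        logger.warning(
            "tile (%d px) larger than slice (%d×%d): global clipped equalization",
            tile_px, h, w,
        )
        mapping = _tile_mapping(img, clip_limit, nbins)
        return mapping[bin_idx]

    n_ty = int(np.ceil(h / tile_px))
    n_tx = int(np.ceil(w / tile_px))
    edges_y = np.linspace(0, h, n_ty + 1).astype(int)
    edges_x = np.linspace(0, w, n_tx + 1).astype(int)
    mappings = np.empty((n_ty, n_tx, nbins))
    centers_y = np.empty(n_ty)
    centers_x = np.empty(n_tx)
    for i in range(n_ty):
        for j in range(n_tx):
            tile = img[edges_y[i]:edges_y[i + 1], edges_x[j]:edges_x[j + 1]]
            mappings[i, j] = _tile_mapping(tile, clip_limit, nbins)
            centers_y[i] = (edges_y[i] + edges_y[i + 1] - 1) / 2.0
            centers_x[j] = (edges_x[j] + edges_x[j + 1] - 1) / 2.0

    # bilinear blend of the four surrounding tile mappings per pixel
    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    iy = np.clip(np.searchsorted(centers_y, yy) - 1, 0, max(n_ty - 2, 0))
    ix = np.clip(np.searchsorted(centers_x, xx) - 1, 0, max(n_tx - 2, 0))
    if n_ty > 1:
        wy = (yy - centers_y[iy]) / (centers_y[iy + 1] - centers_y[iy])
        wy = np.clip(wy, 0.0, 1.0)
    else:
        wy = np.zeros(h)
    if n_tx > 1:
        wx = (xx - centers_x[ix]) / (centers_x[ix + 1] - centers_x[ix])
        wx = np.clip(wx, 0.0, 1.0)
    else:
        wx = np.zeros(w)

    iy2 = np.minimum(iy + 1, n_ty - 1)
    ix2 = np.minimum(ix + 1, n_tx - 1)
    IY, IX = np.meshgrid(iy, ix, indexing="ij")
    IY2, IX2 = np.meshgrid(iy2, ix2, indexing="ij")
    WY, WX = np.meshgrid(wy, wx, indexing="ij")
    m00 = mappings[IY, IX, bin_idx]
    m01 = mappings[IY, IX2, bin_idx]
    m10 = mappings[IY2, IX, bin_idx]
    m11 = mappings[IY2, IX2, bin_idx]
    return (
        (1 - WY) * ((1 - WX) * m00 + WX * m01)
        + WY * ((1 - WX) * m10 + WX * m11)
    )
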
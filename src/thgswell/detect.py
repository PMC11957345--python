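"""Swelling detection: probability map → counted objects → density per mm³.

Candidate voxels come from hysteresis thresholding of the non-myelin
probability map (26-connected components of p ≥ final that contain a core
voxel with p ≥ core; defaults core 0.85, final 0.5).  Components are
measured geometrically (volume, equivalent diameter, mesh sphericity) and
classified: sufficiently round objects within the size window are accepted
as myelin swellings, elongated or sprawling components (extracellular
space, lumens) are rejected.  Density is the accepted count over the imaged
volume in mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .io import AcquisitionGeometry, ProbabilityMap

__all__ = [
    "SwellingObject",
    "SwellingSet",
    "hysteresis_threshold",
    "label_objects",
    "size_filter",
    "classify_objects",
    "swelling_density",
    "DEFAULT_CORE",
    "DEFAULT_FINAL",
    "DEFAULT_MIN_DIAMETER_UM",
    "DEFAULT_MAX_DIAMETER_UM",
    "DEFAULT_SPHERICITY",
]

DEFAULT_CORE = 0.85
DEFAULT_FINAL = 0.5
DEFAULT_MIN_DIAMETER_UM = 1.0
DEFAULT_MAX_DIAMETER_UM = 15.0
DEFAULT_SPHERICITY = 0.6

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SwellingObject:
    """One connected candidate object with its 3D geometry."""

    id: int
    timepoint: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    voxel_count: int
    volume_um3: float
    equivalent_diameter_um: float
    sphericity: float
    accepted: bool = False


@dataclass
class SwellingSet:
    """Detected objects of one volume plus the density of accepted ones."""

    objects: list
    imaged_volume_mm3: float

    @property
    def accepted(self) -> list:
        return [o for o in self.objects if o.accepted]

    @property
    def density_per_mm3(self) -> float:
        return len(self.accepted) / self.imaged_volume_mm3


def hysteresis_threshold(
    prob: ProbabilityMap | np.ndarray,
    core: float = DEFAULT_CORE,
    final: float = DEFAULT_FINAL,
    exclude_border_px: int = 0,
) -> np.ndarray:
    """Binary mask of 26-connected {p ≥ final} components holding a core voxel.

    ``exclude_border_px`` optionally ignores core voxels within that lateral
    border so drift-induced edge artifacts cannot seed objects; the
    components themselves may still extend into the border.
    """
    values = prob.values if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    if not 0 < final <= core <= 1:
        raise ValueError(f"need 0 < final <= core <= 1; got final={final}, core={core}")
    low = values >= final
    high = values >= core
    if exclude_border_px > 0:
        b = exclude_border_px
        keep = np.zeros_like(high)
        keep[:, b:-b or None, b:-b or None] = True
        high = high & keep
    labels, n = ndi.label(low, structure=_CONNECTIVITY_26)
    if n == 0 or not high.any():
        return np.zeros_like(low)
    seeded = np.unique(labels[high])
    seeded = seeded[seeded != 0]
    return np.isin(labels, seeded)


def _mesh_sphericity(mask: np.ndarray, spacing, volume_um3: float) -> float:
    """Sphericity π^(1/3)(6V)^(2/3)/A with A from a marching-cubes mesh."""
    padded = np.pad(mask, 1).astype(np.float32)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    except (ValueError, RuntimeError):
        return 0.0
    area = measure.mesh_surface_area(verts, faces)
    if area <= 0:
        return 0.0
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0) / area)


def label_objects(
    mask: np.ndarray,
    geometry: AcquisitionGeometry,
    timepoint: int = 0,
) -> list[SwellingObject]:
    """Measure 26-connected components of a binary mask in physical units.

    Volume is voxel count × voxel volume; surface area comes from a
    marching-cubes mesh of the component at the 0.5 isolevel with the
    acquisition's voxel spacing, yielding mesh sphericity
    π^(1/3)(6V)^(2/3)/A.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_CONNECTIVITY_26)
    if n == 0:
        return []
    py, px = geometry.pixel_size_um
    spacing = (geometry.z_step_um, py, px)
    voxel_vol = geometry.voxel_volume_um3
    objects = []
    slices = ndi.find_objects(labels)
    for i, slc in enumerate(slices, start=1):
        sub = labels[slc] == i
        count = int(sub.sum())
        volume_um3 = count * voxel_vol
        zc, yc, xc = ndi.center_of_mass(sub)
        centroid = (
            (slc[0].start + zc + 0.5) * spacing[0],
            (slc[1].start + yc + 0.5) * spacing[1],
            (slc[2].start + xc + 0.5) * spacing[2],
        )
        eq_diam = (6.0 * volume_um3 / np.pi) ** (1.0 / 3.0)
        sphericity = _mesh_sphericity(sub, spacing, volume_um3)
        objects.append(
            SwellingObject(
                id=i,
                timepoint=timepoint,
                centroid_um=centroid,
                voxel_count=count,
                volume_um3=volume_um3,
                equivalent_diameter_um=eq_diam,
                sphericity=sphericity,
            )
        )
    return objects


def size_filter(
    objects: list[SwellingObject],
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM,
) -> list[SwellingObject]:
    """Retain objects whose equivalent diameter lies in [min, max] µm."""
    return [
        o for o in objects
        if min_diameter_um <= o.equivalent_diameter_um <= max_diameter_um
    ]


def classify_objects(
    objects: list[SwellingObject],
    geometry: AcquisitionGeometry,
    n_z: int,
    sphericity_threshold: float = DEFAULT_SPHERICITY,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM,
) -> SwellingSet:
    """Mark sufficiently round, size-passing objects as myelin swellings.

    Rejected objects (elongated lumens, sprawling extracellular space) stay
    in the set with ``accepted=False``.
    """
    in_size = set(
        id(o) for o in size_filter(objects, min_diameter_um, max_diameter_um)
    )
    for o in objects:
        o.accepted = id(o) in in_size and o.sphericity >= sphericity_threshold
    return SwellingSet(
        objects=list(objects),
        imaged_volume_mm3=geometry.imaged_volume_mm3(n_z),
    )


def swelling_density(
    swelling_set: SwellingSet,
    geometry: AcquisitionGeometry | None = None,
    n_z: int | None = None,
) -> float:
    """Accepted-object density per mm³ of imaged volume.

    The denominator is fov_y × fov_x × n_z × Δz converted to mm³; if
    geometry and n_z are given they override the volume stored in the set.
    """
    volume = swelling_set.imaged_volume_mm3
    if geometry is not None and n_z is not None:
        volume = geometry.imaged_volume_mm3(n_z)
    if volume <= 0:
        raise ValueError("imaged volume must be positive")
    return len(swelling_set.accepted) / volume


def detect_swellings(
    prob: ProbabilityMap,
    geometry: AcquisitionGeometry,
    timepoint: int = 0,
    core: float = DEFAULT_CORE,
    final: float = DEFAULT_FINAL,
    sphericity_threshold: float = DEFAULT_SPHERICITY,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM,
    exclude_border_px: int = 0,
) -> SwellingSet:
    """Full detection chain on one probability map."""
    mask = hysteresis_threshold(prob, core=core, final=final,
                                exclude_border_px=exclude_border_px)
    objects = label_objects(mask, geometry, timepoint=timepoint)
    return classify_objects(
        objects, geometry, n_z=mask.shape[0],
        sphericity_threshold=sphericity_threshold,
        min_diameter_um=min_diameter_um, max_diameter_um=max_diameter_um,
    )
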
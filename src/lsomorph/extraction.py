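"""Cross-sectional area measurement from binary canal-lumen volumes.

Emulates, on synthetic voxel phantoms, the manual measurement applied to
µ-CT scans: take a section image orthogonal to the canal's long axis, close
small boundary gaps left by the spinal nerve-root foramina, flood-fill the
lumen and count pixels.  Sections here are taken orthogonal to the
longitudinal grid axis (the third array index); the oblique per-canal
alignment of the manual protocol has no quantitative definition and the
phantoms place their recesses orthogonally, so nothing is lost.

Coordinate convention: 0-based indices, anterior = longitudinal index 0,
isotropic voxel pitch in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _morph_closing
from skimage.morphology import disk

from .errors import InvalidInputError, OpenContourError
from .metrics import AreaSeries

#: default morphological closing radius (voxels); must exceed the phantom
#: notch half-width without bridging adjacent recesses
DEFAULT_CLOSING_RADIUS = 3

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LumenVolume:
    """Binary voxel grid of a canal lumen (lumen=1), isotropic pitch in mm.

    The longitudinal (anterior→posterior) axis is the third array index.
    """

    voxels: np.ndarray
    pitch: float

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=bool)
        if vox.ndim != 3:
            raise InvalidInputError("lumen volume must be a 3-D grid")
        if self.pitch <= 0:
            raise InvalidInputError("voxel pitch must be positive")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[2]

    def section(self, plane_index: int) -> "SectionMask":
        if not 0 <= plane_index < self.n_planes:
            raise InvalidInputError(
                f"plane index {plane_index} outside volume with {self.n_planes} planes"
            )
        return SectionMask(self.voxels[:, :, plane_index], self.pitch, plane_index)


@dataclass(frozen=True)
class SectionMask:
    """One binary section image at a given longitudinal plane."""

    pixels: np.ndarray
    pitch: float
    plane_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise InvalidInputError("section mask must be 2-D")
        if self.pitch <= 0:
            raise InvalidInputError("pixel pitch must be positive")
        object.__setattr__(self, "pixels", px)


def close_boundary_gaps(section: SectionMask, radius_voxels: int = DEFAULT_CLOSING_RADIUS) -> SectionMask:
    """Morphologically close small gaps in the lumen boundary.

    Plays the role of manually bridging the openings the nerve-root foramina
    cut into the section outline.  Closing (dilate then erode with a disk) is
    extensive — the output contains the input — and idempotent at fixed
    radius.  An empty mask is returned unchanged with a warning.
    """
    if radius_voxels < 1:
        raise InvalidInputError("closing radius must be >= 1 voxel")
    if not section.pixels.any():
        warnings.warn(
            f"empty section mask at plane {section.plane_index}; closing is a no-op",
            stacklevel=2,
        )
        return section
    closed = _morph_closing(section.pixels, disk(radius_voxels)).astype(bool)
    # closing is extensive on the unpadded grid; keep original pixels regardless
    closed |= section.pixels
    return SectionMask(closed, section.pitch, section.plane_index)


def _seed_pixel(mask: np.ndarray) -> tuple[int, int]:
    """Centroid of the lumen, falling back to the deepest interior pixel.

    Crescent-shaped sections can put the centroid outside the lumen; the
    fallback takes the pixel maximising the Euclidean distance transform
    (the largest inscribed pixel), which is deterministic.
    """
    ci, cj = (int(round(c)) for c in ndimage.center_of_mass(mask))
    if 0 <= ci < mask.shape[0] and 0 <= cj < mask.shape[1] and mask[ci, cj]:
        return ci, cj
    dist = ndimage.distance_transform_edt(mask)
    return tuple(int(v) for v in np.unravel_index(np.argmax(dist), mask.shape))


def section_area(section: SectionMask) -> float:
    """Fill the lumen from an interior seed and return its area in mm².

    The connected component containing the seed is flood-filled (interior
    holes included) and its pixel count converted by ``pitch²``.  A lumen
    that reaches the image border is treated as an open contour — the fill
    would escape — and raises :class:`OpenContourError` naming the plane.
    """
    mask = section.pixels
    if not mask.any():
        raise OpenContourError(
            section.plane_index,
            f"empty section at plane index {section.plane_index}: nothing to fill",
        )
    labels, _ = ndimage.label(mask, structure=_CONN8)
    comp = labels == labels[_seed_pixel(mask)]
    filled = ndimage.binary_fill_holes(comp)
    border = np.zeros_like(filled)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (filled & border).any():
        raise OpenContourError(section.plane_index)
    return float(filled.sum()) * section.pitch**2


def extract_area_profile(
    volume: LumenVolume,
    plane_indices,
    labels,
    *,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    specimen_id: str = "phantom",
    species_id: str = "phantom",
) -> AreaSeries:
    """Measure a cross-sectional area series at the given longitudinal planes.

    Applies gap closing then :func:`section_area` at each plane, anterior
    first.  ``labels`` gives the canal/intercanal tag of each plane and is
    carried through as metadata only.
    """
    idx = [int(i) for i in plane_indices]
    if not idx:
        raise InvalidInputError("no plane indices given")
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise InvalidInputError("plane indices must be strictly increasing")
    if idx[0] < 0 or idx[-1] >= volume.n_planes:
        raise InvalidInputError(
            f"plane indices must lie in [0, {volume.n_planes}); got {idx[0]}..{idx[-1]}"
        )
    labels = tuple(labels)
    if len(labels) != len(idx):
        raise InvalidInputError(f"{len(labels)} labels for {len(idx)} planes")
    areas = [
        section_area(close_boundary_gaps(volume.section(i), closing_radius)) for i in idx
    ]
    return AreaSeries(
        specimen_id=specimen_id,
        species_id=species_id,
        areas=np.array(areas),
        section_labels=labels,
        source="phantom",
    )
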
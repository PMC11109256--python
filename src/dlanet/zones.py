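"""Six-zone partitioning of segmented lung fields.

A frontal chest radiograph shows two lung fields. Each field is divided
vertically into upper / middle / lower thirds between the lung apex (topmost
lung row) and the dome of the diaphragm (bottommost lung row), giving six
zones named RUZ, RMZ, RLZ, LUZ, LMZ, LLZ. Laterality follows the standard
PA-film convention: the component on the *image left* is the patient's
anatomical RIGHT lung.

Coordinates are 0-based and row-major. Per lung, the three row intervals are
half-open, ``[apex, b1)``, ``[b1, b2)``, ``[b2, dome]`` (the last interval is
closed at the dome row), so the intervals tile ``[apex, dome]`` exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from skimage import measure

from .errors import GeometryError, ParameterError

logger = logging.getLogger(__name__)

#: Canonical zone order: right lung top-to-bottom, then left lung.
ZONE_NAMES: Tuple[str, ...] = ("RUZ", "RMZ", "RLZ", "LUZ", "LMZ", "LLZ")

_RIGHT_ZONES = ("RUZ", "RMZ", "RLZ")
_LEFT_ZONES = ("LUZ", "LMZ", "LLZ")


@dataclass(frozen=True)
class LungGeometry:
    """Vertical partition of one lung field into thirds.

    ``boundary1_row``/``boundary2_row`` are ``apex + floor(span/3)`` and
    ``apex + floor(2*span/3)`` with ``span = dome - apex``; the remainder is
    absorbed by the lower zones.
    """

    side: str  # "right" or "left" (anatomical)
    apex_row: int
    dome_row: int
    col_min: int
    col_max: int
    boundary1_row: int
    boundary2_row: int

    def row_bands(self) -> Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]:
        """Half-open row intervals (upper, middle, lower); lower includes the dome."""
        return (
            (self.apex_row, self.boundary1_row),
            (self.boundary1_row, self.boundary2_row),
            (self.boundary2_row, self.dome_row + 1),
        )

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "apex_row": self.apex_row,
            "dome_row": self.dome_row,
            "col_min": self.col_min,
            "col_max": self.col_max,
            "boundary1_row": self.boundary1_row,
            "boundary2_row": self.boundary2_row,
        }


@dataclass
class ZoneCrop:
    """One labelled zone crop.

    ``pixels`` is the grayscale crop with non-lung pixels zeroed; ``mask`` is
    the corresponding binary lung mask of the crop; ``origin`` is the (row,
    col) of the crop's top-left corner in the source image.
    """

    zone_name: str
    pixels: np.ndarray
    origin: Tuple[int, int]
    mask_fraction: float
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class ZoneSet:
    """The six zone crops of one radiograph plus per-lung geometry."""

    crops: Dict[str, ZoneCrop]
    geometry: Dict[str, LungGeometry]

    def __getitem__(self, zone_name: str) -> ZoneCrop:
        return self.crops[zone_name]

    def geometry_json(self) -> str:
        return json.dumps({s: g.to_dict() for s, g in self.geometry.items()}, indent=2)


def split_lungs(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split a binary lung-field mask into (right, left) lung masks.

    The two largest 4-connected components are kept; smaller spurious
    components are discarded with a warning. The component with the smaller
    column centroid (image left) is the anatomical RIGHT lung.

    Raises
    ------
    GeometryError
        If fewer than two components are present, or the two largest
        components overlap in more than 50% of their column ranges
        (fused lungs).
    """
    mask = np.asarray(mask) > 0
    labels = measure.label(mask, connectivity=1)
    n = int(labels.max())
    if n < 2:
        raise GeometryError(f"expected >= 2 lung components, found {n}")
    areas = np.bincount(labels.ravel())[1:]
    keep = np.argsort(areas)[::-1][:2] + 1
    if n > 2:
        logger.warning("discarding %d spurious mask component(s) beyond the largest two", n - 2)

    comps = [labels == k for k in keep]
    ranges = []
    for comp in comps:
        cols = np.where(comp.any(axis=0))[0]
        ranges.append((int(cols[0]), int(cols[-1])))
    overlap = min(ranges[0][1], ranges[1][1]) - max(ranges[0][0], ranges[1][0]) + 1
    min_width = min(r[1] - r[0] + 1 for r in ranges)
    if overlap > 0.5 * min_width:
        raise GeometryError("the two largest components overlap in > 50% of their column ranges (fused lungs)")

    centroids = [np.argwhere(c)[:, 1].mean() for c in comps]
    right, left = (comps[0], comps[1]) if centroids[0] < centroids[1] else (comps[1], comps[0])
    return right, left


def compute_geometry(lung_mask: np.ndarray, side: str) -> LungGeometry:
    """Locate apex, diaphragm dome and the two third-boundaries of one lung."""
    if side not in ("right", "left"):
        raise ParameterError(f"side must be 'right' or 'left', got {side!r}")
    lung_mask = np.asarray(lung_mask) > 0
    rows = np.where(lung_mask.any(axis=1))[0]
    if rows.size == 0:
        raise GeometryError("empty lung mask")
    apex, dome = int(rows[0]), int(rows[-1])
    span = dome - apex
    if span < 3:
        raise GeometryError(f"degenerate lung: only {span + 1} row(s) tall, cannot form three zones")
    cols = np.where(lung_mask.any(axis=0))[0]
    return LungGeometry(
        side=side,
        apex_row=apex,
        dome_row=dome,
        col_min=int(cols[0]),
        col_max=int(cols[-1]),
        boundary1_row=apex + span // 3,
        boundary2_row=apex + (2 * span) // 3,
    )


def extract_zones(image: np.ndarray, mask: np.ndarray) -> ZoneSet:
    """Cut the six zone crops out of ``image`` using the lung mask.

    Each crop spans one lung's row band and the lung's column bounding box;
    pixels outside that lung are zeroed. Raises :class:`ParameterError` on a
    dimension mismatch and propagates :class:`GeometryError` from the split.
    """
    image = np.asarray(image)
    mask = np.asarray(mask) > 0
    if image.shape != mask.shape:
        raise ParameterError(f"image shape {image.shape} != mask shape {mask.shape}")

    right, left = split_lungs(mask)
    crops: Dict[str, ZoneCrop] = {}
    geometry: Dict[str, LungGeometry] = {}
    for side, lung, names in (("right", right, _RIGHT_ZONES), ("left", left, _LEFT_ZONES)):
        geom = compute_geometry(lung, side)
        geometry[side] = geom
        c0, c1 = geom.col_min, geom.col_max + 1
        for name, (r0, r1) in zip(names, geom.row_bands()):
            zmask = lung[r0:r1, c0:c1]
            if not zmask.any():
                raise GeometryError(f"zone {name} contains no lung pixels")
            pixels = np.where(zmask, image[r0:r1, c0:c1], 0)
            crops[name] = ZoneCrop(
                zone_name=name,
                pixels=pixels,
                origin=(r0, c0),
                mask_fraction=float(zmask.mean()),
                mask=zmask,
            )
    return ZoneSet(crops=crops, geometry=geometry)
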
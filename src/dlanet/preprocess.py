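"""Intensity harmonisation and zone resizing.

Radiographs pooled from several sources differ in exposure and contrast, so
all images are passed through histogram matching against a common reference
before classification. Zone crops are then resized to a fixed height
(default 256) with a per-zone average aspect ratio measured on the training
split, so that every crop of a given zone has identical dimensions and can
be batched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import yaml
from scipy import ndimage
from skimage import transform

from .errors import CoverageError, DegenerateReferenceError, ParameterError
from .zones import ZONE_NAMES, ZoneSet

_INTERP_ORDER = {"bilinear": 1, "nearest": 0}


@dataclass
class ZoneResizePolicy:
    """Fixed-height resize policy.

    ``aspect_by_zone[z]`` is the width per unit height (the ``w`` of an
    aspect written ``1:w``); output width is ``round(target_height * w)``
    with round-half-away-from-zero.
    """

    target_height: int = 256
    aspect_by_zone: Dict[str, float] = field(default_factory=dict)
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if self.target_height <= 0:
            raise ParameterError("target_height must be positive")
        if self.interpolation not in _INTERP_ORDER:
            raise ParameterError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
        for zone, ratio in self.aspect_by_zone.items():
            if ratio <= 0:
                raise ParameterError(f"aspect ratio for {zone} must be > 0")

    def output_shape(self, zone_name: str) -> Tuple[int, int]:
        if zone_name not in self.aspect_by_zone:
            raise ParameterError(f"unknown zone name {zone_name!r}")
        width = int(math.floor(self.target_height * self.aspect_by_zone[zone_name] + 0.5))
        return self.target_height, max(width, 1)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "target_height": self.target_height,
            "interpolation": self.interpolation,
            "aspect_by_zone": {k: float(v) for k, v in self.aspect_by_zone.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ZoneResizePolicy":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def match_histogram(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Exact empirical quantile mapping of ``image`` onto the reference histogram.

    Each pixel value v is replaced by the reference quantile at the image's
    empirical CDF of v, so the output takes only values present in the
    reference, matching an image to itself is the identity, and (for equal
    pixel counts with distinct image values) the output's sorted values equal
    the reference's sorted values. Output shape and dtype equal the input's.

    Raises :class:`DegenerateReferenceError` if the reference is constant
    (its CDF has no spread to match against).
    """
    image = np.asarray(image)
    reference = np.asarray(reference)
    if image.size == 0 or reference.size == 0:
        raise ParameterError("images must be nonempty")
    if np.ptp(reference) == 0:
        raise DegenerateReferenceError("reference image is constant")
    src_values, src_counts = np.unique(image, return_counts=True)
    src_cum = np.cumsum(src_counts)  # integer CDF numerator over image.size
    ref_sorted = np.sort(reference, axis=None)
    # idx = ceil(cdf * m) - 1 in exact integer arithmetic
    m = reference.size
    idx = np.clip((src_cum * m + image.size - 1) // image.size - 1, 0, m - 1)
    mapped = ref_sorted[idx]
    matched = mapped[np.searchsorted(src_values, image)]
    return matched.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else matched.astype(float)


def compute_zone_aspects(
    zone_shapes: Mapping[str, Sequence[Tuple[int, int]]],
    target_height: int = 256,
    interpolation: str = "bilinear",
) -> ZoneResizePolicy:
    """Average per-zone aspect ratio from (height, width) crop shapes.

    For each zone the aspect is ``1 : mean(width)/mean(height)`` over the
    supplied (training-split) crops. Every one of the six zone names must be
    present with at least one shape, else :class:`CoverageError`.
    """
    aspects: Dict[str, float] = {}
    for zone in ZONE_NAMES:
        shapes = list(zone_shapes.get(zone, ()))
        if not shapes:
            raise CoverageError(f"no crops supplied for zone {zone}")
        mean_h = float(np.mean([s[0] for s in shapes]))
        mean_w = float(np.mean([s[1] for s in shapes]))
        aspects[zone] = mean_w / mean_h
    return ZoneResizePolicy(target_height=target_height, aspect_by_zone=aspects, interpolation=interpolation)


def zone_shapes_from_sets(zone_sets: Iterable[ZoneSet]) -> Dict[str, list]:
    """Collect (height, width) per zone from a collection of ZoneSets."""
    shapes: Dict[str, list] = {z: [] for z in ZONE_NAMES}
    for zs in zone_sets:
        for zone, crop in zs.crops.items():
            shapes[zone].append((crop.height, crop.width))
    return shapes


def resize_zone(crop: np.ndarray, zone_name: str, policy: ZoneResizePolicy) -> np.ndarray:
    """Resize a zone crop to the policy's fixed output shape for that zone."""
    crop = np.asarray(crop, dtype=float)
    if crop.size == 0:
        raise ParameterError("crop must be nonempty")
    shape = policy.output_shape(zone_name)
    return transform.resize(
        crop,
        shape,
        order=_INTERP_ORDER[policy.interpolation],
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def augment_zone(
    image: np.ndarray,
    rng: np.random.Generator,
    max_rotation_deg: float = 7.0,
    max_translate_frac: float = 0.05,
    max_brightness_frac: float = 0.10,
    allow_flip: bool = False,
) -> np.ndarray:
    """Light training-time augmentation: small rotation, shift, brightness.

    Horizontal flips are off by default because they swap anatomical
    laterality between the left- and right-lung zones.
    """
    out = np.asarray(image, dtype=float)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    h, w = out.shape[:2]
    dr = rng.uniform(-max_translate_frac, max_translate_frac) * h
    dc = rng.uniform(-max_translate_frac, max_translate_frac) * w
    shift = (dr, dc) if out.ndim == 2 else (dr, dc, 0)
    out = ndimage.shift(out, shift, order=1, mode="nearest")
    out = out * (1.0 + rng.uniform(-max_brightness_frac, max_brightness_frac))
    if allow_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    return out
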
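"""Level-one analysis: per-channel grayscale spot detection and measurement.

Detection is strictly intensity-based.  Color in a fluorescence well
image is presentation only — each fluorophore is imaged through its own
filter and evaluated on gray values, so any hue substitution at constant
luminance leaves every result bit-identical.

Pipeline (:func:`detect_spots`)::

    to_grayscale -> estimate_background -> segment_candidates
        -> separate_touching -> measure_spot (per region) -> filter_spots

All stages are deterministic; the output spot list is sorted by
(row, col) of the subpixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import ChannelImage, DetectionParams, Spot

__all__ = [
    "to_grayscale",
    "estimate_background",
    "segment_candidates",
    "separate_touching",
    "measure_spot",
    "filter_spots",
    "detect_spots",
    "FilterTally",
]

# ITU-R 709 luminance weights, as used by scikit-image's rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an image to a single gray channel.

    Single-channel input is returned unchanged (identity).  3-channel
    color input is collapsed with fixed ITU-R 709 luminance weights on the
    native intensity scale, so the output stays within the input range.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr.astype(float) @ _LUMA
    raise ValueError(
        f"unsupported image shape {arr.shape}; expected 2-D gray or H x W x 3"
    )


def estimate_background(gray: np.ndarray) -> tuple[float, float]:
    """Robust background level and scale of a well image.

    Level is the median; scale is the normalized median absolute
    deviation (MAD × 1.4826, consistent for a Gaussian σ).  Both are
    robust to the small fraction of pixels covered by spots.
    """
    g = np.asarray(gray, dtype=float)
    if g.size == 0:
        raise ValueError("empty image")
    level = float(np.median(g))
    scale = float(1.4826 * np.median(np.abs(g - level)))
    return level, scale


def segment_candidates(gray: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Threshold and label candidate spot regions.

    The binary mask keeps pixels ``>= threshold`` where the threshold is
    ``intensity_threshold`` directly (absolute mode) or
    ``level + intensity_threshold * scale`` with the robust background
    estimate (background-relative mode).  Connected components use
    8-connectivity and are labeled in raster-scan order.  A threshold
    above the image maximum simply yields zero regions.
    """
    g = np.asarray(gray, dtype=float)
    if params.threshold_mode == "absolute":
        thresh = params.intensity_threshold
    else:
        level, scale = estimate_background(g)
        thresh = level + params.intensity_threshold * scale
    mask = g >= thresh
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    return labels


def _region_maxima(smoothed: np.ndarray, region_mask: np.ndarray,
                   min_distance: int) -> np.ndarray:
    """Local maxima of one region with deterministic tie-breaking.

    Candidate maxima come from ``peak_local_max``; among candidates
    closer than ``min_distance`` the one with higher intensity wins, ties
    going to the smaller (row, col) position.
    """
    coords = peak_local_max(
        smoothed, min_distance=1, labels=region_mask.astype(int),
        exclude_border=False,
    )
    if len(coords) <= 1:
        return coords
    vals = smoothed[coords[:, 0], coords[:, 1]]
    order = np.lexsort((coords[:, 1], coords[:, 0], -vals))
    kept: list[np.ndarray] = []
    for i in order:
        p = coords[i]
        if all(np.hypot(*(p - q)) >= min_distance for q in kept):
            kept.append(p)
    return np.array(kept)


def separate_touching(label_image: np.ndarray, gray: np.ndarray,
                      params: DetectionParams) -> np.ndarray:
    """Split regions that contain multiple well-separated intensity peaks.

    The image is Gaussian-smoothed (``smoothing_sigma_px``) before maxima
    detection; regions with two or more maxima at least
    ``separation_min_distance_px`` apart are split by marker-based
    watershed on the inverted smoothed intensity.  Regions with a single
    maximum pass through untouched, and total labeled area is conserved.
    """
    if not params.separation_enabled:
        return label_image
    g = np.asarray(gray, dtype=float)
    smoothed = (
        ndimage.gaussian_filter(g, params.smoothing_sigma_px)
        if params.smoothing_sigma_px > 0 else g
    )
    out = np.zeros_like(label_image)
    next_label = 1
    for sl, region_id in _iter_regions(label_image):
        mask = label_image[sl] == region_id
        peaks = _region_maxima(smoothed[sl], mask,
                               params.separation_min_distance_px)
        if len(peaks) <= 1:
            out[sl][mask] = next_label
            next_label += 1
            continue
        markers = np.zeros(mask.shape, dtype=int)
        for j, (pr, pc) in enumerate(peaks, start=1):
            markers[pr, pc] = j
        split = watershed(-smoothed[sl], markers=markers, mask=mask)
        for j in range(1, len(peaks) + 1):
            out[sl][split == j] = next_label
            next_label += 1
    return out


def _iter_regions(label_image: np.ndarray):
    for region_id, sl in enumerate(ndimage.find_objects(label_image), start=1):
        if sl is not None:
            yield sl, region_id


def measure_spot(region_pixels: np.ndarray, gray: np.ndarray,
                 pixel_size_um: float, channel_id: str = "") -> Spot:
    """Measure one labeled region into a :class:`~fluorospot.core.Spot`.

    * center: intensity-weighted centroid (subpixel)
    * gradient score: mean intensity of the core (radial distance
      ``<= R/2`` from the center) over the mean in the annulus
      ``R/2 < r <= R``, with ``R = sqrt(area/pi)`` the equivalent-disc
      radius; 1.0 by convention when either zone is empty (e.g. a
      single-pixel region)
    * radial CV: coefficient of variation of boundary-pixel distances to
      the center, boundary pixels being region members with at least one
      non-member 8-neighbor; 0.0 for a single pixel
    """
    pix = np.asarray(region_pixels, dtype=int)
    if pix.ndim != 2 or pix.shape[1] != 2 or len(pix) == 0:
        raise ValueError("region_pixels must be a non-empty (N, 2) array")
    g = np.asarray(gray, dtype=float)
    vals = g[pix[:, 0], pix[:, 1]]
    w = vals.sum()
    if w > 0:
        center = (pix * vals[:, None]).sum(axis=0) / w
    else:  # all-zero region: geometric centroid
        center = pix.mean(axis=0)
    center_rc = (float(center[0]), float(center[1]))
    area = len(pix)
    peak = float(vals.max())
    mean = float(vals.mean())

    r_equiv = np.sqrt(area / np.pi)
    dists = np.hypot(pix[:, 0] - center[0], pix[:, 1] - center[1])
    core = dists <= r_equiv / 2.0
    annulus = (dists > r_equiv / 2.0) & (dists <= r_equiv)
    if area == 1 or not core.any() or not annulus.any():
        gradient = 1.0
    else:
        ann_mean = vals[annulus].mean()
        gradient = float(vals[core].mean() / ann_mean) if ann_mean > 0 else 1.0

    boundary = _boundary_mask(pix, g.shape)
    bdists = dists[boundary]
    if area == 1 or len(bdists) == 0 or bdists.mean() == 0:
        radial_cv = 0.0
    else:
        radial_cv = float(bdists.std() / bdists.mean())

    return Spot(
        channel_id=channel_id, center_rc=center_rc, area_px=area,
        peak_intensity=peak, mean_intensity=mean,
        gradient_score=gradient, radial_cv=radial_cv, pixel_indices=pix,
    )


def _boundary_mask(pix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Flag region pixels with >= 1 non-member 8-neighbor (or image edge)."""
    members = set(map(tuple, pix))
    out = np.zeros(len(pix), dtype=bool)
    for i, (r, c) in enumerate(pix):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < shape[0] and 0 <= nc < shape[1]) \
                        or (nr, nc) not in members:
                    out[i] = True
                    break
            if out[i]:
                break
    return out


@dataclass
class FilterTally:
    """Per-filter rejection counts; filters apply in this fixed order."""

    area: int = 0
    peak: int = 0
    gradient: int = 0
    radial_cv: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"area": self.area, "peak": self.peak,
                "gradient": self.gradient, "radial_cv": self.radial_cv}

    @property
    def total(self) -> int:
        return self.area + self.peak + self.gradient + self.radial_cv


def filter_spots(spots: list[Spot], params: DetectionParams
                 ) -> tuple[list[Spot], FilterTally]:
    """Apply the size/intensity/gradient/circularity filters.

    A spot is retained iff it passes all four predicates; a rejected spot
    is tallied under the first failing filter in the fixed order area →
    peak → gradient → radial CV.
    """
    tally = FilterTally()
    kept: list[Spot] = []
    for s in spots:
        if not params.min_area_px <= s.area_px <= params.max_area_px:
            tally.area += 1
        elif s.peak_intensity < params.min_peak_intensity:
            tally.peak += 1
        elif s.gradient_score < params.min_gradient_score:
            tally.gradient += 1
        elif s.radial_cv > params.max_radial_cv:
            tally.radial_cv += 1
        else:
            kept.append(s)
    return kept, tally


def detect_spots(image: ChannelImage, params: DetectionParams,
                 ) -> tuple[list[Spot], FilterTally]:
    """Run the full level-one pipeline on one channel image.

    Returns the retained spots sorted by center (row, col) plus the
    rejection tally.  Deterministic: identical image and parameters give
    an identical spot list.
    """
    gray = to_grayscale(image.pixels).astype(float)
    labels = segment_candidates(gray, params)
    labels = separate_touching(labels, gray, params)
    spots: list[Spot] = []
    for sl, region_id in _iter_regions(labels):
        rows, cols = np.nonzero(labels[sl] == region_id)
        pix = np.column_stack([rows + sl[0].start, cols + sl[1].start])
        spots.append(measure_spot(pix, gray, image.pixel_size_um,
                                  channel_id=image.channel_id))
    kept, tally = filter_spots(spots, params)
    kept.sort(key=lambda s: s.center_rc)
    return kept, tally
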
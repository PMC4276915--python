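"""Shared domain types and conventions for multi-channel FluoroSpot analysis.

Coordinate convention
---------------------
All positions are ``(row, col)`` pairs, 0-based, with the origin at the
center of the top-left pixel.  Subpixel positions are real-valued in the
same frame.  Conversion to physical units happens only through
``pixel_size_um`` (microns per pixel edge).

Channel order is the order given in the plate configuration and is
preserved everywhere.  A secretion *pattern* is a tuple of channel labels
in that order; with ``k`` channels there are ``2**k - 1`` non-empty
patterns, one per detectable subpopulation of secreting cells.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChannelImage",
    "DetectionParams",
    "MatchParams",
    "Spot",
    "SpotGroup",
    "SubpopulationCounts",
    "WellRecord",
    "Pattern",
    "subpopulation_patterns",
]

#: A secretion pattern: tuple of channel labels in plate channel order.
Pattern = tuple[str, ...]


@dataclass
class ChannelImage:
    """One grayscale well image for a single fluorophore channel.

    ``pixels`` holds non-negative intensities; integer arrays straight off
    the camera, floats after internal processing.  Range validation is
    explicit (:meth:`validate`) rather than automatic because intermediate
    float images (e.g. unclipped simulator output) may legitimately sit
    outside the camera range.
    """

    channel_id: str
    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float = 3.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def validate(self) -> "ChannelImage":
        """Check camera-range invariants; returns self for chaining."""
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ValueError(
                f"channel {self.channel_id!r}: intensities outside "
                f"[0, {self.max_value}]"
            )
        return self


@dataclass
class Spot:
    """A single detected spot on one channel image.

    ``gradient_score`` is the center-to-periphery fade ratio (mean core
    intensity over mean annulus intensity; 1.0 for a flat disc, > 1 for a
    spot fading outward).  ``radial_cv`` is the coefficient of variation of
    boundary-pixel distances to the center — the radial-variability
    circularity measure (0 for a perfect disc).
    """

    channel_id: str
    center_rc: tuple[float, float]
    area_px: int
    peak_intensity: float
    mean_intensity: float
    gradient_score: float
    radial_cv: float
    pixel_indices: np.ndarray  # (N, 2) int array of (row, col) members

    def __post_init__(self) -> None:
        self.pixel_indices = np.asarray(self.pixel_indices, dtype=int)
        if self.pixel_indices.ndim != 2 or self.pixel_indices.shape[1] != 2:
            raise ValueError("pixel_indices must be an (N, 2) array")
        if self.area_px != len(self.pixel_indices) or self.area_px < 1:
            raise ValueError("area_px must equal |pixel_indices| >= 1")
        if self.peak_intensity < self.mean_intensity:
            raise ValueError("peak_intensity must be >= mean_intensity")
        r, c = self.center_rc
        rmin, cmin = self.pixel_indices.min(axis=0)
        rmax, cmax = self.pixel_indices.max(axis=0)
        if not (rmin - 0.5 <= r <= rmax + 0.5 and cmin - 0.5 <= c <= cmax + 0.5):
            raise ValueError("center_rc outside bounding box of pixel_indices")

    def distance_to(self, other: "Spot") -> float:
        return math.dist(self.center_rc, other.center_rc)


@dataclass
class DetectionParams:
    """Level-one detection parameters for one channel.

    ``threshold_mode`` is ``"absolute"`` (``intensity_threshold`` is a raw
    gray value) or ``"background_relative"`` (threshold = background level
    + ``intensity_threshold`` × robust background scale).  One instance is
    held per channel, mirroring per-filter camera/parameter tuning.
    """

    threshold_mode: str = "background_relative"
    intensity_threshold: float = 5.0
    min_area_px: int = 5
    max_area_px: int = 2000
    min_peak_intensity: float = 25.0
    min_gradient_score: float = 0.0
    max_radial_cv: float = 1.0
    smoothing_sigma_px: float = 1.0
    separation_enabled: bool = True
    separation_min_distance_px: int = 5

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("absolute", "background_relative"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must be <= max_area_px")
        for name in ("intensity_threshold", "min_peak_intensity",
                     "min_gradient_score", "max_radial_cv"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.min_gradient_score < 0:
            raise ValueError("min_gradient_score must be >= 0")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")
        if self.separation_min_distance_px < 1:
            raise ValueError("separation_min_distance_px must be >= 1")


@dataclass
class MatchParams:
    """Level-two matching tolerance.

    The default of 5 px at 3 µm/px corresponds to the empirical ~15 µm
    maximum acceptable spot-center shift between channels for medium-sized
    spots.
    """

    max_center_distance_px: float = 5.0
    pixel_size_um: float = 3.0

    def __post_init__(self) -> None:
        if not self.max_center_distance_px > 0:
            raise ValueError("max_center_distance_px must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def max_center_distance_um(self) -> float:
        return self.max_center_distance_px * self.pixel_size_um


@dataclass
class SpotGroup:
    """A set of co-located spots (at most one per channel) = one cell.

    Construction enforces per-channel uniqueness and, when ``tolerance``
    is given, that every pair of member centers lies within it.
    """

    members: dict[str, Spot]
    tolerance: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a SpotGroup needs at least one member")
        for ch, spot in self.members.items():
            if spot.channel_id != ch:
                raise ValueError(
                    f"member keyed {ch!r} has channel_id {spot.channel_id!r}"
                )
        if self.tolerance is not None:
            spots = list(self.members.values())
            for a, b in itertools.combinations(spots, 2):
                d = a.distance_to(b)
                if d > self.tolerance:
                    raise ValueError(
                        f"member centers {d:.3f} px apart exceed matching "
                        f"tolerance {self.tolerance}"
                    )

    def pattern(self, channels: Sequence[str]) -> Pattern:
        """Membership pattern as a tuple of labels in plate channel order."""
        return tuple(c for c in channels if c in self.members)

    @property
    def centroid_rc(self) -> tuple[float, float]:
        centers = np.array([s.center_rc for s in self.members.values()])
        r, c = centers.mean(axis=0)
        return (float(r), float(c))

    @property
    def max_pairwise_distance(self) -> float:
        spots = list(self.members.values())
        if len(spots) == 1:
            return 0.0
        return max(a.distance_to(b) for a, b in itertools.combinations(spots, 2))

    def __len__(self) -> int:
        return len(self.members)


def subpopulation_patterns(
    channels: int | Sequence[str],
) -> list[Pattern] | list[tuple[int, ...]]:
    """Enumerate the non-empty secretion patterns for ``k`` channels.

    With three analytes a well can reveal seven subpopulations (three
    single secretors, three dual combinations, one triple secretor); a
    fourth analyte brings the count to fifteen.  In general ``k`` channels
    give ``2**k - 1`` patterns, returned sorted by cardinality and then
    lexicographically by channel position.

    Parameters
    ----------
    channels:
        Either the number of channels ``k`` (patterns are index tuples) or
        the ordered channel labels (patterns are label tuples).
    """
    if isinstance(channels, int):
        k = channels
        labels: Sequence | None = None
    else:
        labels = list(channels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        k = len(labels)
    if not 1 <= k <= 8:
        raise ValueError(f"number of channels must be in 1..8, got {k}")
    patterns: list[tuple] = []
    for m in range(1, k + 1):
        for combo in itertools.combinations(range(k), m):
            patterns.append(
                combo if labels is None else tuple(labels[i] for i in combo)
            )
    return patterns


@dataclass
class SubpopulationCounts:
    """Counts over the ``2**k - 1`` secretion patterns of ``k`` channels."""

    channels: tuple[str, ...]
    counts: dict[Pattern, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        expected = subpopulation_patterns(self.channels)
        missing = [p for p in expected if p not in self.counts]
        for p in missing:
            self.counts[p] = 0
        extra = set(self.counts) - set(expected)
        if extra:
            raise ValueError(f"unknown patterns {sorted(extra)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        # keep canonical ordering (cardinality, then channel position)
        self.counts = {p: self.counts[p] for p in expected}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def marginal(self, channel: str) -> int:
        """Total spots in ``channel`` summed over all patterns containing it."""
        if channel not in self.channels:
            raise KeyError(channel)
        return sum(n for p, n in self.counts.items() if channel in p)

    def as_dict(self) -> dict[str, int]:
        """JSON-friendly mapping with '+'-joined pattern keys."""
        return {"+".join(p): n for p, n in self.counts.items()}


@dataclass
class WellRecord:
    """One assay well: plate coordinate, condition, and per-channel images."""

    well_id: str
    condition: str
    replicate: int
    images: dict[str, ChannelImage]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError(f"well {self.well_id}: no channel images")
        shapes = {im.shape for im in self.images.values()}
        sizes = {im.pixel_size_um for im in self.images.values()}
        if len(shapes) > 1:
            raise ValueError(
                f"well {self.well_id}: channel images differ in shape {shapes}"
            )
        if len(sizes) > 1:
            raise ValueError(
                f"well {self.well_id}: channel images differ in pixel size"
            )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape
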
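"""Synthetic multi-channel well simulator with known ground truth.

Emulates the statistical structure the two-level analysis assumes: a
membrane background with additive Gaussian noise, roughly circular spots
whose staining intensity fades from center to periphery, per-channel
spot-center jitter for multi-secreting cells (secretion kinetics and cell
movement shift centers by a few µm between analytes), per-channel
gain/exposure scaling with saturation clipping, and optional spectral
bleed-over between channels expressed as a mixing matrix.

Spot profile
------------
A spot of radius ``R``, peak ``p`` and fade exponent ``s`` is the radially
symmetric polynomial profile

    I(r) = p * (1 - r/R)**s   for r <= R,   0 otherwise,

evaluated at pixel centers (no per-pixel area integration).  Its
continuous integral has the closed form ``2*pi*p*R**2 / ((s+1)*(s+2))``
(:func:`spot_profile_integral`), used by the quadrature cross-checks.

Seed protocol
-------------
One master seed per well.  ``numpy.random.SeedSequence(seed)`` is spawned
into five child sequences, consumed in this fixed order:

    0. placement   — nominal cell centers (rejection sampling)
    1. patterns    — per-cell secretion pattern draw
    2. morphology  — per (cell, channel-in-pattern): radius, then peak
    3. jitter      — per (cell, channel-in-pattern): (d_row, d_col)
    4. noise       — per-channel additive Gaussian noise fields

Identical configs therefore produce bit-identical images and truth
tables, and any stage can be reproduced by an independent RNG following
the same derivation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import ChannelImage, Pattern, subpopulation_patterns

__all__ = [
    "SimulationConfig",
    "GroundTruthCell",
    "SimulatedWell",
    "PlacementError",
    "render_spot_profile",
    "spot_profile_integral",
    "simulate_well",
    "simulate_single_stain_panel",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested separation."""


def _per_channel(value, channels: Sequence[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(channels) - set(value)
        if missing:
            raise ValueError(f"{name}: missing channels {sorted(missing)}")
        return {c: float(value[c]) for c in channels}
    return {c: float(value) for c in channels}


def _per_channel_pair(value, channels, name) -> dict[str, tuple[float, float]]:
    if isinstance(value, Mapping):
        missing = set(channels) - set(value)
        if missing:
            raise ValueError(f"{name}: missing channels {sorted(missing)}")
        return {c: (float(value[c][0]), float(value[c][1])) for c in channels}
    m, s = value
    return {c: (float(m), float(s)) for c in channels}


@dataclass
class SimulationConfig:
    """Parameters of one simulated well.

    ``secretion_probs`` maps each non-empty channel subset (tuple of
    labels in channel order) to its probability; omitted patterns get
    probability 0.  If ``None``, all ``2**k - 1`` patterns are equally
    likely.  ``cell_patterns`` instead fixes the pattern of every cell
    explicitly.  Per-channel fields (background, noise, gain, exposure,
    peak, jitter) accept a scalar applied to all channels or a mapping.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 3.0
    channels: tuple[str, ...] = ("FITC", "Cy3", "Cy5")
    n_cells: int = 60
    secretion_probs: Mapping[Pattern, float] | None = None
    cell_patterns: Sequence[Pattern] | None = None
    spot_radius_px: tuple[float, float] = (5.0, 1.0)  # mean, spread
    peak_intensity: object = (160.0, 25.0)  # per-channel (mean, spread)
    gradient_shape: float = 2.0
    center_jitter_sigma_px: object = 1.0
    background_level: object = 12.0
    noise_sigma: object = 2.0
    gain: object = 1.0
    exposure_scale: object = 1.0
    bleedover_matrix: np.ndarray | None = None  # row = source, col = target
    min_cell_separation_px: float = 25.0
    bit_depth: int = 8
    clip: bool = True
    quantize: bool = True
    max_placement_tries: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        k = len(self.channels)
        if self.bleedover_matrix is not None:
            M = np.asarray(self.bleedover_matrix, dtype=float)
            if M.shape != (k, k):
                raise ValueError(f"bleedover_matrix must be {k}x{k}")
            if (M < 0).any() or (np.diag(M) <= 0).any():
                raise ValueError(
                    "bleedover_matrix must be non-negative with positive diagonal"
                )
            self.bleedover_matrix = M
        if self.cell_patterns is not None:
            if len(self.cell_patterns) != self.n_cells:
                raise ValueError("cell_patterns length must equal n_cells")
            for p in self.cell_patterns:
                if not p or not set(p) <= set(self.channels):
                    raise ValueError(f"invalid explicit pattern {p!r}")
        elif self.secretion_probs is not None:
            probs = np.array(list(self.secretion_probs.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("secretion_probs must be >= 0 and sum to 1")
            valid = set(map(tuple, subpopulation_patterns(self.channels)))
            bad = set(self.secretion_probs) - valid
            if bad:
                raise ValueError(f"unknown patterns {sorted(bad)}")

    # --- normalized per-channel views -----------------------------------
    @property
    def background(self) -> dict[str, float]:
        return _per_channel(self.background_level, self.channels, "background_level")

    @property
    def noise(self) -> dict[str, float]:
        return _per_channel(self.noise_sigma, self.channels, "noise_sigma")

    @property
    def gains(self) -> dict[str, float]:
        return _per_channel(self.gain, self.channels, "gain")

    @property
    def exposures(self) -> dict[str, float]:
        return _per_channel(self.exposure_scale, self.channels, "exposure_scale")

    @property
    def jitter(self) -> dict[str, float]:
        return _per_channel(
            self.center_jitter_sigma_px, self.channels, "center_jitter_sigma_px"
        )

    @property
    def peaks(self) -> dict[str, tuple[float, float]]:
        return _per_channel_pair(self.peak_intensity, self.channels, "peak_intensity")

    @property
    def mixing(self) -> np.ndarray:
        if self.bleedover_matrix is None:
            return np.eye(len(self.channels))
        return self.bleedover_matrix

    def pattern_distribution(self) -> tuple[list[Pattern], np.ndarray]:
        """Ordered pattern list and probability vector of the pattern draw."""
        patterns = [tuple(p) for p in subpopulation_patterns(self.channels)]
        if self.secretion_probs is None:
            probs = np.full(len(patterns), 1.0 / len(patterns))
        else:
            probs = np.array(
                [self.secretion_probs.get(p, 0.0) for p in patterns], dtype=float
            )
        return patterns, probs


@dataclass
class GroundTruthCell:
    cell_id: int
    true_pattern: Pattern
    nominal_center_rc: tuple[float, float]
    per_channel_center_rc: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_channel_radius_px: dict[str, float] = field(default_factory=dict)
    per_channel_peak: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.per_channel_center_rc, self.per_channel_radius_px,
                  self.per_channel_peak):
            if set(d) != set(self.true_pattern):
                raise ValueError(
                    f"cell {self.cell_id}: per-channel entries must match "
                    f"true_pattern {self.true_pattern}"
                )


@dataclass
class SimulatedWell:
    images: dict[str, ChannelImage]
    truth: list[GroundTruthCell]
    config: SimulationConfig

    def __post_init__(self) -> None:
        if set(self.images) != set(self.config.channels):
            raise ValueError("image set must match configured channels")


# ---------------------------------------------------------------------------
# Spot rendering
# ---------------------------------------------------------------------------

def render_spot_profile(
    radius_px: float, peak: float, gradient_shape: float = 2.0
) -> np.ndarray:
    """Render a centered fading spot as a square patch.

    The patch is ``(2*ceil(R)+3)`` pixels on a side with the profile
    center on the central pixel; intensity is maximal at the center,
    decreases monotonically with radius and vanishes for ``r >= R``.
    """
    if not radius_px >= 1:
        raise ValueError("radius_px must be >= 1")
    if not peak > 0:
        raise ValueError("peak must be positive")
    if not gradient_shape > 0:
        raise ValueError("gradient_shape must be positive")
    half = math.ceil(radius_px) + 1
    ax = np.arange(-half, half + 1, dtype=float)
    r = np.hypot(ax[:, None], ax[None, :])
    return _profile_values(r, radius_px, peak, gradient_shape)


def _profile_values(r: np.ndarray, radius: float, peak: float, shape: float):
    return peak * np.clip(1.0 - r / radius, 0.0, None) ** shape


def spot_profile_integral(radius_px: float, peak: float, gradient_shape: float):
    """Closed-form continuous integral of the spot profile over the plane.

    ``∫ 2πr · p(1 - r/R)^s dr = 2π p R² / ((s+1)(s+2))``.
    """
    s = gradient_shape
    return 2.0 * math.pi * peak * radius_px**2 / ((s + 1.0) * (s + 2.0))


def _add_spot(acc: np.ndarray, center: tuple[float, float], radius: float,
              peak: float, shape: float) -> None:
    """Accumulate one spot profile at a subpixel center, clipped to frame."""
    r0, c0 = center
    lo_r = max(0, math.floor(r0 - radius))
    hi_r = min(acc.shape[0], math.ceil(r0 + radius) + 1)
    lo_c = max(0, math.floor(c0 - radius))
    hi_c = min(acc.shape[1], math.ceil(c0 + radius) + 1)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rows = np.arange(lo_r, hi_r, dtype=float) - r0
    cols = np.arange(lo_c, hi_c, dtype=float) - c0
    d = np.hypot(rows[:, None], cols[None, :])
    acc[lo_r:hi_r, lo_c:hi_c] += _profile_values(d, radius, peak, shape)


def rendered_spot_sum(
    image_shape: tuple[int, int], center: tuple[float, float],
    radius: float, peak: float, shape: float,
) -> float:
    """Total intensity a spot contributes to an image of ``image_shape``."""
    acc = np.zeros(image_shape)
    _add_spot(acc, center, radius, peak, shape)
    return float(acc.sum())


# ---------------------------------------------------------------------------
# Well simulation
# ---------------------------------------------------------------------------

def _stage_rngs(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    return [np.random.default_rng(c) for c in children]


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample nominal centers with pairwise minimum separation."""
    mean_r, sd_r = cfg.spot_radius_px
    margin = mean_r + 3.0 * abs(sd_r) + 3.0
    nrows, ncols = cfg.image_shape
    if nrows - 2 * margin <= 0 or ncols - 2 * margin <= 0:
        raise PlacementError("image too small for spot margin")
    centers: list[tuple[float, float]] = []
    tries = 0
    min_sep2 = cfg.min_cell_separation_px**2
    while len(centers) < cfg.n_cells:
        if tries >= cfg.max_placement_tries:
            raise PlacementError(
                f"could not place {cfg.n_cells} cells at separation "
                f">= {cfg.min_cell_separation_px} px within "
                f"{cfg.max_placement_tries} tries"
            )
        tries += 1
        r = rng.uniform(margin, nrows - margin)
        c = rng.uniform(margin, ncols - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep2 for pr, pc in centers):
            centers.append((r, c))
    return centers


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   floor: float) -> float:
    """Normal draw truncated (by redraw) to values >= floor."""
    if sd == 0:
        if mean < floor:
            raise ValueError(f"degenerate draw: mean {mean} below floor {floor}")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return x
    raise ValueError("truncated normal rejection failed; check mean/spread")


def simulate_well(config: SimulationConfig) -> SimulatedWell:
    """Render one well: ground-truth cells plus per-channel images.

    Each cell renders one spot per channel of its secretion pattern, with
    the center jittered independently per channel.  Channel signals are
    mixed by the bleed-over matrix, offset by the background, scaled by
    gain·exposure, noise-corrupted, then clipped to the camera range and
    quantized (both optional via config flags).
    """
    cfg = config
    rng_place, rng_pat, rng_morph, rng_jit, rng_noise = _stage_rngs(cfg.seed)

    centers = _place_cells(cfg, rng_place)

    patterns_list, probs = cfg.pattern_distribution()
    if cfg.cell_patterns is not None:
        assigned = [tuple(p) for p in cfg.cell_patterns]
    else:
        idx = rng_pat.choice(len(patterns_list), size=cfg.n_cells, p=probs)
        assigned = [patterns_list[i] for i in idx]

    mean_r, sd_r = cfg.spot_radius_px
    peaks = cfg.peaks
    jitter = cfg.jitter

    truth: list[GroundTruthCell] = []
    for cell_id, (nom, pat) in enumerate(zip(centers, assigned)):
        radii: dict[str, float] = {}
        pk: dict[str, float] = {}
        for ch in cfg.channels:
            if ch not in pat:
                continue
            radii[ch] = _draw_positive(rng_morph, mean_r, sd_r, floor=1.0)
            m, s = peaks[ch]
            pk[ch] = _draw_positive(rng_morph, m, s, floor=1e-6)
        jittered: dict[str, tuple[float, float]] = {}
        for ch in cfg.channels:
            if ch not in pat:
                continue
            sig = jitter[ch]
            dr, dc = (rng_jit.normal(0.0, sig, size=2) if sig > 0 else (0.0, 0.0))
            jittered[ch] = (nom[0] + float(dr), nom[1] + float(dc))
        truth.append(GroundTruthCell(
            cell_id=cell_id, true_pattern=pat, nominal_center_rc=nom,
            per_channel_center_rc=jittered,
            per_channel_radius_px=radii, per_channel_peak=pk,
        ))

    # pure fluorophore signal, before optics/camera
    signal = {ch: np.zeros(cfg.image_shape) for ch in cfg.channels}
    for cell in truth:
        for ch in cell.true_pattern:
            _add_spot(signal[ch], cell.per_channel_center_rc[ch],
                      cell.per_channel_radius_px[ch],
                      cell.per_channel_peak[ch], cfg.gradient_shape)

    M = cfg.mixing
    bg = cfg.background
    gains, exposures, noise = cfg.gains, cfg.exposures, cfg.noise
    maxval = 2 ** cfg.bit_depth - 1
    images: dict[str, ChannelImage] = {}
    for j, ch in enumerate(cfg.channels):
        mixed = np.zeros(cfg.image_shape)
        for i, src in enumerate(cfg.channels):
            if M[i, j] != 0.0:
                mixed += M[i, j] * signal[src]
        img = (bg[ch] + mixed) * gains[ch] * exposures[ch]
        if noise[ch] > 0:
            img = img + rng_noise.normal(0.0, noise[ch], size=cfg.image_shape)
        else:
            rng_noise.normal(0.0, 1.0, size=cfg.image_shape)  # keep stream aligned
        if cfg.clip:
            img = np.clip(img, 0.0, maxval)
        if cfg.quantize:
            img = np.rint(img).astype(np.uint8 if cfg.bit_depth == 8 else np.uint16)
        images[ch] = ChannelImage(
            channel_id=ch, pixels=img, bit_depth=cfg.bit_depth,
            pixel_size_um=cfg.pixel_size_um,
        )

    return SimulatedWell(images=images, truth=truth, config=cfg)


def simulate_single_stain_panel(
    config: SimulationConfig, stained_channel: str
) -> SimulatedWell:
    """Simulate a single-fluorophore control well.

    Every cell secretes only the stained channel's analyte; the other
    channel images contain background (and whatever the bleed-over matrix
    injects).  With an identity matrix the off-target images are
    background plus noise only — the basis of the bleed-over system check.
    """
    if stained_channel not in config.channels:
        raise ValueError(
            f"unknown channel {stained_channel!r}; have {config.channels}"
        )
    cfg = dataclasses.replace(
        config,
        secretion_probs={(stained_channel,): 1.0},
        cell_patterns=None,
    )
    return simulate_well(cfg)
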
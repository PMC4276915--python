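"""Quality control: bleed-over validation and exposure sanity checks.

The bleed-over check implements the single-stain panel protocol: each
control well is stained with exactly one fluorophore but imaged through
every filter.  No signal should be detected with any filter other than
the one designated for that fluorophore; detected off-target spots mean
the optical filter set does not isolate the channels and the reader is
unsuitable for multi-color evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import ChannelImage, DetectionParams, WellRecord
from .detect import detect_spots

__all__ = [
    "bleedover_check",
    "BleedoverReport",
    "BleedoverEntry",
    "exposure_check",
    "ExposureWarning",
]

PASS = "PASS"
FAIL = "FAIL"
INDETERMINATE = "INDETERMINATE"


@dataclass
class BleedoverEntry:
    well_id: str
    stained_channel: str
    filter_channel: str
    n_spots: int
    on_target: bool
    ok: bool


@dataclass
class BleedoverReport:
    """Per-(well, filter) spot counts and verdicts of a single-stain panel.

    A stained well PASSes when its on-target filter sees at least one
    spot and every off-target filter sees at most ``tolerance_count``;
    it FAILs on any off-target excess, and is INDETERMINATE when the
    on-target channel itself is empty (bleed-over absence cannot be
    distinguished from assay failure).
    """

    tolerance_count: int
    entries: list[BleedoverEntry] = field(default_factory=list)
    well_verdicts: dict[str, str] = field(default_factory=dict)

    @property
    def verdict(self) -> str:
        if any(v == FAIL for v in self.well_verdicts.values()):
            return FAIL
        if any(v == INDETERMINATE for v in self.well_verdicts.values()):
            return INDETERMINATE
        return PASS

    @property
    def failing_pairs(self) -> list[tuple[str, str]]:
        """(well_id, filter_channel) pairs with off-target detections."""
        return [(e.well_id, e.filter_channel) for e in self.entries
                if not e.on_target and not e.ok]

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "tolerance_count": self.tolerance_count,
            "wells": self.well_verdicts,
            "entries": [vars(e) for e in self.entries],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"Bleed-over check: {self.verdict} "
                 f"(off-target tolerance {self.tolerance_count} spots)"]
        for e in self.entries:
            tag = "on-target " if e.on_target else "off-target"
            status = "ok" if e.ok else "EXCESS" if not e.on_target else "EMPTY"
            lines.append(
                f"  well {e.well_id} [{e.stained_channel} stain] "
                f"filter {e.filter_channel}: {e.n_spots} spots ({tag}, {status})"
            )
        return "\n".join(lines)


def bleedover_check(
    single_stain_wells: Mapping[str, WellRecord],
    det_params: Mapping[str, DetectionParams],
    tolerance_count: int = 0,
) -> BleedoverReport:
    """Run the single-stain panel bleed-over check.

    Parameters
    ----------
    single_stain_wells:
        Mapping stained channel → control well record; each record must
        carry images for *all* channels (the same well imaged through
        every filter).
    det_params:
        Per-channel level-one detection parameters.
    tolerance_count:
        Maximum acceptable off-target spot count.  The default of 0 takes
        "no signal should be detected" literally; a small nonzero value
        accommodates rare noise-induced false spots.
    """
    channels = list(det_params)
    report = BleedoverReport(tolerance_count=tolerance_count)
    for stained, well in single_stain_wells.items():
        missing = [c for c in channels if c not in well.images]
        if missing:
            raise ValueError(
                f"well {well.well_id}: missing channel image(s) {missing}"
            )
        counts: dict[str, int] = {}
        for ch in channels:
            spots, _ = detect_spots(well.images[ch], det_params[ch])
            counts[ch] = len(spots)
        on_ok = counts[stained] >= 1
        well_fail = False
        for ch in channels:
            on_target = ch == stained
            ok = on_ok if on_target else counts[ch] <= tolerance_count
            if not on_target and not ok:
                well_fail = True
            report.entries.append(BleedoverEntry(
                well_id=well.well_id, stained_channel=stained,
                filter_channel=ch, n_spots=counts[ch],
                on_target=on_target, ok=ok,
            ))
        if well_fail:
            report.well_verdicts[well.well_id] = FAIL
        elif not on_ok:
            report.well_verdicts[well.well_id] = INDETERMINATE
        else:
            report.well_verdicts[well.well_id] = PASS
    return report


@dataclass
class ExposureWarning:
    kind: str  # "overexposure" | "underexposure"
    channel_id: str
    value: float
    limit: float
    message: str


def exposure_check(
    image: ChannelImage,
    saturation_fraction_limit: float = 0.01,
    underexposure_quantile_limit: float = 0.05,
) -> list[ExposureWarning]:
    """Warn about saturated or dim channel images; never raises.

    Overexposure: the fraction of pixels pinned at full scale
    (``2**bit_depth - 1``) exceeds ``saturation_fraction_limit``.
    Underexposure: the 99.5th intensity percentile falls below
    ``underexposure_quantile_limit`` × full scale, i.e. even the bright
    tail of the image sits low in the camera range.  The default limit
    of 5% of full scale is deliberately lenient so that sparse but
    healthy wells (few spots over a dim membrane background) do not
    warn; tighten it per assay if desired.
    """
    px = np.asarray(image.pixels, dtype=float)
    full = image.max_value
    warnings: list[ExposureWarning] = []
    sat_frac = float((px >= full).mean())
    if sat_frac > saturation_fraction_limit:
        warnings.append(ExposureWarning(
            kind="overexposure", channel_id=image.channel_id,
            value=sat_frac, limit=saturation_fraction_limit,
            message=(f"channel {image.channel_id}: {sat_frac:.2%} of pixels "
                     f"saturated at {full}"),
        ))
    q995 = float(np.percentile(px, 99.5))
    if q995 < underexposure_quantile_limit * full:
        warnings.append(ExposureWarning(
            kind="underexposure", channel_id=image.channel_id,
            value=q995, limit=underexposure_quantile_limit * full,
            message=(f"channel {image.channel_id}: 99.5th percentile "
                     f"{q995:.1f} below {underexposure_quantile_limit:.0%} "
                     f"of full scale ({full})"),
        ))
    return warnings
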
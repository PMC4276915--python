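"""Plate-level orchestration and file I/O.

Reads plate layouts (YAML) pointing at single-channel TIFF/PNG well
images, runs the two-level analysis across wells, and writes CSV/JSON
result tables with a provenance block (config hash, seed, version).

Layout schema::

    plate_id: demo
    pixel_size_um: 3.0
    bit_depth: 8
    channels: [FITC, Cy3, Cy5]
    wells:
      - well_id: A1
        condition: CEF
        replicate: 1
        stained_channel: FITC      # optional; single-stain QC panels
        images: {FITC: A1_FITC.tif, Cy3: A1_Cy3.tif, Cy5: A1_Cy5.tif}

CSV dialect: UTF-8, comma-separated, one header row, '.' decimal; column
order is fixed and documented per table below.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .colocalize import (
    CoincidenceResult,
    classify_subpopulations,
    coincidence_limit,
    match_spots,
)
from .core import (
    ChannelImage,
    DetectionParams,
    MatchParams,
    SpotGroup,
    SubpopulationCounts,
    WellRecord,
)
from .detect import detect_spots
from .synth import SimulatedWell

__all__ = [
    "load_plate",
    "write_simulated_plate",
    "analyze_plate",
    "PlateResults",
    "WellResult",
    "load_params",
    "save_results",
]


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def load_plate(layout_file: str | Path,
               image_dir: str | Path | None = None) -> list[WellRecord]:
    """Load a plate layout and its channel images into WellRecords.

    ``image_dir`` defaults to the layout file's directory.  Missing
    files, inconsistent channel sets and geometry mismatches raise
    descriptive errors naming the offending well.
    """
    layout_file = Path(layout_file)
    layout = yaml.safe_load(layout_file.read_text())
    image_dir = Path(image_dir) if image_dir is not None else layout_file.parent
    channels = [str(c) for c in layout["channels"]]
    pixel_size = float(layout.get("pixel_size_um", 3.0))
    bit_depth = int(layout.get("bit_depth", 8))
    wells: list[WellRecord] = []
    for entry in layout["wells"]:
        wid = str(entry["well_id"])
        imgs = entry.get("images", {})
        if set(imgs) != set(channels):
            raise ValueError(
                f"well {wid}: channels {sorted(imgs)} do not match plate "
                f"channels {sorted(channels)}"
            )
        images: dict[str, ChannelImage] = {}
        for ch in channels:
            path = image_dir / imgs[ch]
            if not path.exists():
                raise FileNotFoundError(
                    f"well {wid}, channel {ch}: image file not found: {path}"
                )
            images[ch] = ChannelImage(
                channel_id=ch, pixels=_read_image(path),
                bit_depth=bit_depth, pixel_size_um=pixel_size,
            ).validate()
        wells.append(WellRecord(
            well_id=wid, condition=str(entry.get("condition", "")),
            replicate=int(entry.get("replicate", 1)), images=images,
        ))
    return wells


def write_simulated_plate(
    wells: Sequence[tuple[str, str, int, SimulatedWell]],
    out_dir: str | Path,
    plate_id: str = "simulated",
    extra_fields: Mapping[str, dict] | None = None,
) -> Path:
    """Write simulated wells as a loadable plate.

    ``wells`` is a sequence of (well_id, condition, replicate, simulated
    well).  Per channel one grayscale TIFF is written, plus a combined
    ground-truth CSV (one row per rendered spot) and the layout YAML.
    ``extra_fields`` maps well_id to additional layout entries (e.g.
    ``stained_channel`` for QC panels).  Returns the layout path;
    ``load_plate`` round-trips it losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    first_cfg = wells[0][3].config
    layout = {
        "plate_id": plate_id,
        "pixel_size_um": first_cfg.pixel_size_um,
        "bit_depth": first_cfg.bit_depth,
        "channels": list(first_cfg.channels),
        "wells": [],
    }
    truth_rows = []
    for well_id, condition, replicate, sim in wells:
        img_map = {}
        for ch, im in sim.images.items():
            fname = f"{well_id}_{ch}.tif"
            tifffile.imwrite(out_dir / fname, np.asarray(im.pixels))
            img_map[ch] = fname
        entry = {
            "well_id": well_id, "condition": condition,
            "replicate": replicate, "images": img_map,
        }
        if extra_fields and well_id in extra_fields:
            entry.update(extra_fields[well_id])
        layout["wells"].append(entry)
        for cell in sim.truth:
            for ch in cell.true_pattern:
                r, c = cell.per_channel_center_rc[ch]
                truth_rows.append({
                    "well_id": well_id, "cell_id": cell.cell_id,
                    "pattern": "+".join(cell.true_pattern), "channel": ch,
                    "center_row": r, "center_col": c,
                    "radius_px": cell.per_channel_radius_px[ch],
                    "peak": cell.per_channel_peak[ch],
                })
    pd.DataFrame(
        truth_rows,
        columns=["well_id", "cell_id", "pattern", "channel",
                 "center_row", "center_col", "radius_px", "peak"],
    ).to_csv(out_dir / "ground_truth.csv", index=False)
    layout_path = out_dir / "layout.yaml"
    layout_path.write_text(yaml.safe_dump(layout, sort_keys=False))
    return layout_path


@dataclass
class WellResult:
    well: WellRecord
    spots: dict[str, list]  # channel -> list[Spot]
    groups: list[SpotGroup]
    counts: SubpopulationCounts
    coincidence: CoincidenceResult | None = None


@dataclass
class PlateResults:
    """Result bundle of :func:`analyze_plate` with flat CSV-ready tables."""

    wells: list[WellResult] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)
    spots_df: pd.DataFrame | None = None
    groups_df: pd.DataFrame | None = None
    counts_df: pd.DataFrame | None = None
    condition_summary_df: pd.DataFrame | None = None


def analyze_plate(
    wells: Sequence[WellRecord],
    det_params: Mapping[str, DetectionParams],
    match_params: MatchParams,
    with_coincidence: bool = False,
    n_shuffles: int = 100,
    seed: int = 0,
) -> PlateResults:
    """Run the full two-level analysis over a plate.

    Level one runs per channel with that channel's parameters; level two
    matches centers within the shared tolerance and tallies the
    subpopulation counts.  A failure in one well is recorded in
    ``errors`` and does not stop the remaining wells.  Deterministic for
    fixed inputs and seed.
    """
    res = PlateResults()
    spot_rows, group_rows, count_rows = [], [], []
    for well in wells:
        try:
            wr = _analyze_well(well, det_params, match_params,
                               with_coincidence, n_shuffles, seed)
        except Exception as exc:  # isolate per-well failures
            res.errors[well.well_id] = str(exc)
            continue
        res.wells.append(wr)
        _tabulate(wr, spot_rows, group_rows, count_rows)
    res.spots_df = pd.DataFrame(spot_rows, columns=[
        "well_id", "condition", "replicate", "channel", "spot_id",
        "center_row", "center_col", "area_px", "peak", "mean",
        "gradient_score", "radial_cv"])
    res.groups_df = pd.DataFrame(group_rows, columns=[
        "well_id", "group_id", "pattern", "channel", "spot_id",
        "center_row", "center_col", "max_pairwise_distance"])
    res.counts_df = pd.DataFrame(count_rows, columns=[
        "well_id", "condition", "replicate", "pattern", "count",
        "coincidence_fraction", "coincidence_se"])
    if len(res.counts_df):
        res.condition_summary_df = (
            res.counts_df.groupby(["condition", "pattern"], sort=False)["count"]
            .agg(mean="mean", sd="std", n_replicates="count").reset_index()
        )
    else:
        res.condition_summary_df = pd.DataFrame(
            columns=["condition", "pattern", "mean", "sd", "n_replicates"])
    return res


def _analyze_well(well, det_params, match_params, with_coincidence,
                  n_shuffles, seed) -> WellResult:
    missing = [c for c in well.channels if c not in det_params]
    if missing:
        raise ValueError(f"no detection parameters for channels {missing}")
    spot_sets = {}
    for ch in well.channels:
        spots, _ = detect_spots(well.images[ch], det_params[ch])
        spot_sets[ch] = spots
    groups = match_spots(spot_sets, match_params)
    counts = classify_subpopulations(groups, well.channels)
    coin = None
    if with_coincidence and len(well.channels) >= 2:
        coin = coincidence_limit(spot_sets, match_params, well.shape,
                                 n_shuffles=n_shuffles, seed=seed)
    return WellResult(well=well, spots=spot_sets, groups=groups,
                      counts=counts, coincidence=coin)


def _tabulate(wr: WellResult, spot_rows, group_rows, count_rows) -> None:
    well = wr.well
    spot_ids = {}
    for ch, spots in wr.spots.items():
        for i, s in enumerate(spots):
            spot_ids[id(s)] = i
            spot_rows.append({
                "well_id": well.well_id, "condition": well.condition,
                "replicate": well.replicate, "channel": ch, "spot_id": i,
                "center_row": s.center_rc[0], "center_col": s.center_rc[1],
                "area_px": s.area_px, "peak": s.peak_intensity,
                "mean": s.mean_intensity, "gradient_score": s.gradient_score,
                "radial_cv": s.radial_cv})
    for gid, g in enumerate(wr.groups):
        pat = "+".join(g.pattern(well.channels))
        for ch in well.channels:
            if ch not in g.members:
                continue
            s = g.members[ch]
            group_rows.append({
                "well_id": well.well_id, "group_id": gid, "pattern": pat,
                "channel": ch, "spot_id": spot_ids[id(s)],
                "center_row": s.center_rc[0], "center_col": s.center_rc[1],
                "max_pairwise_distance": g.max_pairwise_distance})
    for pattern, n in wr.counts.counts.items():
        count_rows.append({
            "well_id": well.well_id, "condition": well.condition,
            "replicate": well.replicate, "pattern": "+".join(pattern),
            "count": n,
            "coincidence_fraction":
                wr.coincidence.fraction_mean if wr.coincidence else np.nan,
            "coincidence_se":
                wr.coincidence.fraction_se if wr.coincidence else np.nan})


# ---------------------------------------------------------------------------
# Parameter files and result persistence
# ---------------------------------------------------------------------------

def load_params(path: str | Path
                ) -> tuple[dict[str, DetectionParams], MatchParams]:
    """Read a YAML parameter file with per-channel detection and matching.

    Schema::

        detection:
          FITC: {intensity_threshold: 5.0, min_area_px: 5, ...}
          Cy3: {}               # empty mapping = defaults
        matching:
          max_center_distance_px: 5.0
          pixel_size_um: 3.0
    """
    data = yaml.safe_load(Path(path).read_text())
    det = {str(ch): DetectionParams(**(cfg or {}))
           for ch, cfg in data.get("detection", {}).items()}
    match = MatchParams(**data.get("matching", {}))
    return det, match


def _provenance(det_params, match_params, seed) -> dict:
    blob = json.dumps({
        "detection": {c: dataclasses.asdict(p) for c, p in det_params.items()},
        "matching": dataclasses.asdict(match_params),
    }, sort_keys=True)
    return {
        "fluorospot_version": __version__,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
    }


def save_results(results: PlateResults, out_dir: str | Path,
                 det_params: Mapping[str, DetectionParams] | None = None,
                 match_params: MatchParams | None = None,
                 seed: int = 0) -> Path:
    """Write the result tables and a provenance block to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.spots_df.to_csv(out_dir / "spots.csv", index=False)
    results.groups_df.to_csv(out_dir / "groups.csv", index=False)
    results.counts_df.to_csv(out_dir / "counts.csv", index=False)
    results.condition_summary_df.to_csv(
        out_dir / "condition_summary.csv", index=False)
    prov = {"errors": results.errors}
    if det_params is not None and match_params is not None:
        prov.update(_provenance(det_params, match_params, seed))
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
    return out_dir
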
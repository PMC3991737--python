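"""Table and image I/O: trait CSVs, per-root CSVs, masks, and sidecar dpi."""

from __future__ import annotations

import json
import os
import warnings

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .architecture import RootSystem
from .imaging import BinaryMask, GlobalTraits, RasterImage

TRAIT_FACTORS = ["plant_id", "genotype", "run", "scanner", "das"]


def read_image(path: str, dpi: float | None = None) -> RasterImage:
    """Read a PNG/TIFF scan; dpi from argument or a ``<path>.json`` sidecar.

    The sidecar is a JSON object with a ``dpi`` key. Falls back to 300 dpi
    with a warning when neither is given.
    """
    px = np.asarray(iio.imread(path))
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        px = np.clip(px.astype(float), 0, 255).astype(np.uint8)
    if dpi is None:
        sidecar = path + ".json"
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                dpi = float(json.load(fh)["dpi"])
        else:
            warnings.warn(f"no dpi given for {path}; assuming 300")
            dpi = 300.0
    return RasterImage(px, dpi)


def write_mask(mask: BinaryMask, path: str) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG with a dpi sidecar."""
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    with open(path + ".json", "w") as fh:
        json.dump({"dpi": mask.dpi}, fh)


def read_mask(path: str, dpi: float | None = None) -> BinaryMask:
    img = read_image(path, dpi=dpi)
    px = img.pixels if img.pixels.ndim == 2 else img.pixels[:, :, 0]
    return BinaryMask(px > 127, img.dpi)


def global_traits_row(plant_id: str, das: float, traits: GlobalTraits) -> dict:
    return {
        "plant_id": plant_id,
        "das": das,
        "length_cm": traits.total_root_length,
        "area_cm2": traits.total_area,
        "perimeter_cm": traits.perimeter,
        "hull_cm2": traits.convex_hull_area,
    }


def root_records(system: RootSystem, plant_id: str | None = None) -> pd.DataFrame:
    """Per-root CSV rows: primary first, laterals ordered by position."""
    pid = plant_id or system.plant_id
    rows = [
        dict(
            plant_id=pid, root_id="primary", order=0,
            length_cm=system.primary_length_cm, diameter_mm=system.primary_diameter_mm,
            insertion_deg=np.nan, position_cm=0.0, emergence_das=np.nan,
        )
    ]
    for i, lat in enumerate(system.laterals):
        rows.append(
            dict(
                plant_id=pid, root_id=f"lateral_{i}", order=1,
                length_cm=lat.length_cm, diameter_mm=lat.diameter_mm,
                insertion_deg=lat.insertion_angle_deg, position_cm=lat.position_cm,
                emergence_das=lat.emergence_das if lat.emergence_das is not None else np.nan,
            )
        )
    return pd.DataFrame(rows)


def read_trait_table(path: str) -> pd.DataFrame:
    """Read a trait CSV and validate its factor columns."""
    df = pd.read_csv(path)
    missing = [c for c in ("plant_id", "das") if c not in df.columns]
    if missing:
        raise ValueError(f"trait table {path} lacks required columns {missing}")
    if df.duplicated(subset=["plant_id", "das"]).any():
        raise ValueError(f"trait table {path} has duplicate (plant_id, das) rows")
    return df


def write_trait_table(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in TRAIT_FACTORS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.6g")
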
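"""End-to-end pipeline: images -> masks -> traits -> dynamics -> statistics."""

from __future__ import annotations

import glob
import json
import logging
import os
import re
import time
from dataclasses import dataclass, field

import pandas as pd

from . import architecture, dynamics, imaging, io, rsml, varstats

log = logging.getLogger("rootscan")

_IMAGE_RE = re.compile(r"^(?P<plant>.+)_(?P<das>\d+(?:\.\d+)?)\.(png|tif|tiff)$", re.IGNORECASE)


@dataclass
class PipelineConfig:
    dpi: float = 300.0
    median_radius: int = 1
    gaussian_sigma: float = 1.0
    window_radius: int = 25
    min_area: int = 50
    invert: bool = False
    seed_xy: tuple[int, int] | None = None  # (row, col); default top-centre
    prune_px: float = architecture.DEFAULT_PRUNE_PX
    min_lateral_cm: float = architecture.DEFAULT_MIN_LATERAL_CM
    fit_trait: str = "total_root_length"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        if cfg.seed_xy is not None:
            cfg.seed_xy = tuple(cfg.seed_xy)
        return cfg


def analyze_image(path: str, config: PipelineConfig, plant_id: str = "plant"):
    """One image through segmentation + architecture; returns (mask, system, global traits)."""
    image = io.read_image(path, dpi=config.dpi)
    mask = imaging.segment_pipeline(
        image,
        median_radius=config.median_radius,
        gaussian_sigma=config.gaussian_sigma,
        window_radius=config.window_radius,
        min_area=config.min_area,
        seed=config.seed_xy,
        invert=config.invert,
    )
    gtraits = imaging.measure_global_traits(mask)
    system = None
    if mask.pixels.any():
        system = architecture.extract_root_system(
            mask,
            seed=config.seed_xy,
            prune_px=config.prune_px,
            min_lateral_cm=config.min_lateral_cm,
            plant_id=plant_id,
        )
    return mask, system, gtraits


def run_pipeline(image_dir: str, metadata_csv: str, out_dir: str,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Process a directory of ``<plant_id>_<das>.png`` scans end to end.

    Writes per-image masks and RSML, a per-plant-per-day trait CSV, a
    logistic-fit JSON (when >= 4 days are available), and a
    variance-decomposition CSV (when the metadata provides factor levels).
    Images without metadata are skipped with a logged warning. Deterministic:
    identical inputs and config give byte-identical CSV outputs.
    """
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    meta = pd.read_csv(metadata_csv, dtype=str).set_index("plant_id")

    paths = sorted(
        p for p in glob.glob(os.path.join(image_dir, "*"))
        if _IMAGE_RE.match(os.path.basename(p))
    )
    if not paths:
        raise ValueError(f"no <plant_id>_<das>.png images found in {image_dir}")

    rows = []
    qc_flags = []
    for path in paths:
        m = _IMAGE_RE.match(os.path.basename(path))
        plant_id, das = m.group("plant"), float(m.group("das"))
        if plant_id not in meta.index:
            log.warning("no metadata for %s; skipping %s", plant_id, path)
            continue
        t0 = time.perf_counter()
        mask, system, gtraits = analyze_image(path, config, plant_id=plant_id)
        if not mask.pixels.any():
            qc_flags.append((plant_id, das, "empty_mask"))
            log.warning("empty mask for %s at %s DAS", plant_id, das)
            continue
        io.write_mask(mask, os.path.join(out_dir, f"{plant_id}_{das:g}_mask.png"))
        rec = dict(
            plant_id=plant_id,
            genotype=meta.loc[plant_id].get("genotype", "NA"),
            run=meta.loc[plant_id].get("run", "NA"),
            scanner=meta.loc[plant_id].get("scanner", "NA"),
            das=das,
            total_root_length=gtraits.total_root_length,
            total_area=gtraits.total_area,
            perimeter=gtraits.perimeter,
            convex_hull_area=gtraits.convex_hull_area,
        )
        if system is not None:
            local = architecture.measure_local_traits(system)
            rec.update(
                primary_root_length=local.primary_root_length,
                primary_root_diameter=local.primary_root_diameter,
                lateral_branching_density=local.lateral_branching_density,
                total_lateral_root_length=local.total_lateral_length,
            )
            rsml.write_rsml(system, os.path.join(out_dir, f"{plant_id}_{das:g}.rsml"))
        rows.append(rec)
        log.info("%s @ %g DAS: %.2f s, length %.2f cm", plant_id, das,
                 time.perf_counter() - t0, gtraits.total_root_length)

    if not rows:
        raise ValueError("no images could be processed")
    traits = pd.DataFrame(rows).sort_values(["plant_id", "das"]).reset_index(drop=True)
    io.write_trait_table(traits, os.path.join(out_dir, "traits.csv"))

    # growth fit, when the time axis supports it
    if traits.groupby("plant_id")["das"].nunique().min() >= 4:
        trajs = dynamics.assemble_trajectories(traits, config.fit_trait)
        fit = dynamics.fit_logistic(trajs, group_by_genotype=traits["genotype"].nunique() > 1)
        with open(os.path.join(out_dir, "fit.json"), "w") as fh:
            json.dump(
                dict(
                    model="logistic",
                    trait=config.fit_trait,
                    asymptote_by_genotype=fit.asymptote_by_genotype,
                    inflection=fit.inflection,
                    scale=fit.scale,
                    residual_sd=fit.residual_sd,
                    aic=fit.aic,
                    selected_model=fit.selected_model,
                ),
                fh,
                indent=2,
                sort_keys=True,
            )

    # variance decomposition at the final day, when the design supports it
    final = traits[traits["das"] == traits["das"].max()]
    if final["run"].nunique() >= 2 and final["scanner"].nunique() >= 2:
        try:
            decomp = varstats.fit_variance_components(final, config.fit_trait, "single")
            pd.DataFrame(
                [
                    dict(
                        trait=decomp.trait, mean=decomp.mean, cv=decomp.cv, n=decomp.n,
                        **{f"sd_{k}": v for k, v in decomp.effect_sds.items()},
                        **{f"pct_{k}": v for k, v in decomp.percentages.items()},
                    )
                ]
            ).to_csv(os.path.join(out_dir, "variance_components.csv"), index=False,
                     float_format="%.6g")
        except (RuntimeError, ValueError) as exc:
            log.warning("variance decomposition skipped: %s", exc)

    if qc_flags:
        pd.DataFrame(qc_flags, columns=["plant_id", "das", "flag"]).to_csv(
            os.path.join(out_dir, "qc_flags.csv"), index=False
        )
    return traits
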